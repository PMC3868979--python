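"""End-to-end orchestration: one species, or a batch, with reproducible outputs.

``run_species`` executes the full chain for each configured mask label —
pseudogene filter -> mask -> align -> distances -> neighbor-joining tree
(-> optional bootstrap supports) -> patristic distances -> switch calls ->
position attribution -> summary — and optionally writes a switch table
(TSV), the anticodon-mask tree (newick), the gapped alignment (FASTA) and a
JSON summary per species. ``run_batch`` maps this over many species and
aggregates the per-domain tallies. Stage logging records counts in and out
of every filter so the removed/evaluated/switched funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .detect import MaskAnalysis, SwitchCall, analyze_mask, control_comparison
from .io_formats import filter_pseudogenes, write_switch_table
from .mask_align import (
    ANTICODON_LABEL,
    AlignParams,
    MaskSpec,
    control_spec,
    default_control_offsets,
)
from .phylo import bootstrap_support, write_newick
from .records import SpeciesRepertoire

log = logging.getLogger(__name__)

MIN_RECORDS = 3  # species with fewer post-filter records are skipped


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one scan run."""

    cove_min: float = 40.0
    model: str = "jc"  # "p" | "jc"
    masks: str = "anticodon"  # "anticodon" | "controls" | "all"
    n_controls: int = 6
    align_params: AlignParams = AlignParams()
    aligner: str = "builtin"
    bootstrap_reps: int = 0
    seed: int | None = None
    same_aa_only: bool = False
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("seed is mandatory when bootstrap is enabled")
        if self.masks not in ("anticodon", "controls", "all"):
            raise ValueError(f"unknown masks setting {self.masks!r}")


@dataclass(frozen=True)
class SpeciesResult:
    species_id: str
    skipped: str | None
    analyses: dict[str, MaskAnalysis] = field(default_factory=dict)
    tree_with_support: object | None = None

    @property
    def calls(self) -> tuple[SwitchCall, ...]:
        a = self.analyses.get(ANTICODON_LABEL)
        return a.calls if a else ()


def _mask_specs(rep: SpeciesRepertoire, config: RunConfig) -> list[MaskSpec]:
    specs: list[MaskSpec] = []
    if config.masks in ("anticodon", "all"):
        specs.append(MaskSpec())
    if config.masks in ("controls", "all"):
        offsets = default_control_offsets(rep.records[0], config.n_controls)
        specs.extend(
            control_spec(o, f"ctrl_{chr(ord('A') + i)}")
            for i, o in enumerate(offsets)
        )
    return specs


def run_species(
    repertoire: SpeciesRepertoire, config: RunConfig
) -> SpeciesResult:
    """Analyze one species; returns a skipped result when it is too small."""
    kept = filter_pseudogenes(repertoire.records, config.cove_min)
    log.info(
        "%s: %d records, %d pass COVE >= %.1f",
        repertoire.species_id,
        len(repertoire.records),
        len(kept),
        config.cove_min,
    )
    if len(kept) < MIN_RECORDS:
        log.info("%s skipped: too few sequences", repertoire.species_id)
        return SpeciesResult(repertoire.species_id, skipped="too few sequences")
    filtered = SpeciesRepertoire(
        repertoire.species_id, kept, repertoire.domain_of_life
    )
    analyses: dict[str, MaskAnalysis] = {}
    for spec in _mask_specs(filtered, config):
        try:
            analyses[spec.label] = analyze_mask(
                kept,
                spec,
                config.align_params,
                config.model,
                config.same_aa_only,
            )
        except Exception as exc:
            raise RuntimeError(
                f"{repertoire.species_id}: mask {spec.label!r} failed: {exc}"
            ) from exc
        s = analyses[spec.label].summary
        log.info(
            "%s mask=%s: evaluated %d, switched %d",
            repertoire.species_id,
            spec.label,
            s.n_evaluated,
            s.n_switched,
        )
    tree_sup = None
    main = analyses.get(ANTICODON_LABEL)
    if main is not None and config.bootstrap_reps > 0:
        tree_sup = bootstrap_support(
            main.alignment, main.tree, config.bootstrap_reps, config.seed,
            model=config.model,
        )
    result = SpeciesResult(
        repertoire.species_id, None, analyses, tree_with_support=tree_sup
    )
    if config.out_dir is not None:
        _write_species_outputs(result, filtered, config)
    return result


def _write_species_outputs(
    result: SpeciesResult, rep: SpeciesRepertoire, config: RunConfig
) -> None:
    out = Path(config.out_dir) / result.species_id
    out.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for label, analysis in result.analyses.items():
        write_switch_table(analysis.calls, out / f"switch_table.{label}.tsv")
        analysis.alignment.to_fasta(out / f"alignment.{label}.fasta")
        s = analysis.summary
        summaries[label] = {
            "n_records": s.n_records,
            "n_evaluated": s.n_evaluated,
            "n_switched": s.n_switched,
            "proportion_switched": s.proportion_switched,
            "position_counts": {str(k): v for k, v in s.position_counts.items()},
        }
    main = result.analyses.get(ANTICODON_LABEL)
    if main is not None:
        tree = result.tree_with_support or main.tree
        write_newick(tree, out / "tree.anticodon.nwk")
    (out / "summary.json").write_text(
        json.dumps(
            {"species_id": result.species_id, "masks": summaries},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def run_batch(
    repertoires: Sequence[SpeciesRepertoire], config: RunConfig
) -> tuple[pd.DataFrame, dict[str, SpeciesResult]]:
    """Analyze many species; failures abort one species, not the batch.

    Returns the aggregate table (one row per species, sorted by species_id:
    species, domain_of_life, n_records, n_evaluated, n_switched, has_switch,
    skipped) and the per-species results.
    """
    if not repertoires:
        raise ValueError("empty input list")
    results: dict[str, SpeciesResult] = {}
    rows = []
    for rep in sorted(repertoires, key=lambda r: r.species_id):
        try:
            res = run_species(rep, config)
        except Exception as exc:
            log.error("%s failed: %s", rep.species_id, exc)
            res = SpeciesResult(rep.species_id, skipped=f"error: {exc}")
        results[rep.species_id] = res
        main = res.analyses.get(ANTICODON_LABEL)
        s = main.summary if main else None
        rows.append(
            {
                "species": rep.species_id,
                "domain_of_life": rep.domain_of_life,
                "n_records": s.n_records if s else len(rep.records),
                "n_evaluated": s.n_evaluated if s else 0,
                "n_switched": s.n_switched if s else 0,
                "has_switch": bool(s and s.n_switched >= 1),
                "skipped": res.skipped or "",
            }
        )
    table = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "batch_summary.tsv", sep="\t", index=False)
        manifest = {
            "trnaswitch_version": __version__,
            "config": _config_dict(config),
            "n_species": len(rows),
            "domain_tally": domain_tally(table),
        }
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return table, results


def domain_tally(table: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-domain counts of species analyzed and species with >= 1 switch."""
    tally: dict[str, dict[str, int]] = {}
    for domain, grp in table.groupby("domain_of_life"):
        tally[str(domain)] = {
            "n_species": int(len(grp)),
            "n_with_switch": int(grp["has_switch"].sum()),
        }
    return tally


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["align_params"] = dataclasses.asdict(config.align_params)
    if d["out_dir"] is not None:
        d["out_dir"] = str(d["out_dir"])
    return d
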