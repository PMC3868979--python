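"""Synthetic tRNA repertoires with known anticodon-switch events.

The generator emulates the structure the screen exploits: a species carries
several tRNA gene families, each defined by its anticodon; copies within a
family are nearly identical (concerted evolution keeps within-family
divergence far below between-family scaffold divergence); occasionally a
copy carries the scaffold of its own family but the anticodon of another
(a switch event); and a fraction of tRNA-like pseudogenes score below the
40-bit filter threshold.

Sequences evolve under a Jukes-Cantor substitution process along a two-level
star: root -> family ancestor (``delta_between`` substitutions/site) ->
copy (``delta_within``). Anticodon windows are *assigned*, not evolved, so
family identity and the ground-truth labels are unambiguous. Optional
per-window rate multipliers exist to build adversarial control-triplet
scenarios (a fast-evolving window under a control mask). No indels are
simulated: tRNA genes are near-constant length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import (
    SpeciesRepertoire,
    TRNAGeneRecord,
    anticodon_to_amino_acid,
    rna,
)

_BASES = np.array(list("ACGT"))

# distinct anticodons handed to families in order when the config gives none
DEFAULT_ANTICODONS = (
    "TCT", "CCT", "GAT", "TTC", "CAC", "AAC", "GCC", "TGG", "CAA", "GTA",
    "TAC", "CTC", "AGC", "GTT", "TGC", "CCG",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated species repertoire.

    Defaults model a small eukaryote-like repertoire: 3 families of 6
    near-identical copies of a 72-nt gene, family scaffolds 0.20
    substitutions/site from the root, copies 0.01 from their family
    ancestor, 2 injected switch events, and 10% extra pseudogene decoys.
    """

    seed: int
    n_families: int = 3
    copies_per_family: int | tuple[int, ...] = 6
    anticodons: tuple[str, ...] | None = None
    seq_length: int = 72
    anticodon_start: int = 33
    delta_between: float = 0.20
    delta_within: float = 0.01
    n_switches: int = 2
    pseudogene_rate: float = 0.1
    rate_multiplier_windows: Mapping[tuple[int, int], float] | None = None
    species_id: str | None = None
    domain_of_life: str = "unknown"

    def resolved_anticodons(self) -> tuple[str, ...]:
        acs = self.anticodons or DEFAULT_ANTICODONS[: self.n_families]
        if len(acs) != self.n_families or len(set(acs)) != len(acs):
            raise ValueError("need one distinct anticodon per family")
        return tuple(acs)

    def resolved_copies(self) -> tuple[int, ...]:
        if isinstance(self.copies_per_family, int):
            return (self.copies_per_family,) * self.n_families
        if len(self.copies_per_family) != self.n_families:
            raise ValueError("copies_per_family list must match n_families")
        return tuple(self.copies_per_family)

    def __post_init__(self) -> None:
        if self.seq_length < 60:
            raise ValueError("seq_length must be >= 60")
        if not self.delta_between > self.delta_within >= 0:
            raise ValueError("require delta_between > delta_within >= 0")
        if not 0 <= self.anticodon_start <= self.seq_length - 3:
            raise ValueError("anticodon_start out of bounds")
        if self.n_switches > 0 and self.n_families < 2:
            raise ValueError("switches need at least 2 families")
        self.resolved_anticodons()


@dataclass(frozen=True)
class SwitchEvent:
    recipient_gene_id: str
    recipient_family: str  # recipient family's anticodon
    donor_family: str  # donor family's anticodon
    changed_positions: frozenset[int]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth labels for one simulated repertoire."""

    switched_gene_ids: frozenset[str]
    events: tuple[SwitchEvent, ...]
    pseudogene_ids: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "switched_gene_ids": sorted(self.switched_gene_ids),
            "events": [
                {
                    "recipient_gene_id": e.recipient_gene_id,
                    "recipient_family": e.recipient_family,
                    "donor_family": e.donor_family,
                    "changed_positions": sorted(e.changed_positions),
                }
                for e in self.events
            ],
            "pseudogene_ids": sorted(self.pseudogene_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            frozenset(d["switched_gene_ids"]),
            tuple(
                SwitchEvent(
                    e["recipient_gene_id"],
                    e["recipient_family"],
                    e["donor_family"],
                    frozenset(e["changed_positions"]),
                )
                for e in d["events"]
            ),
            frozenset(d["pseudogene_ids"]),
        )


def _site_rates(config: SimConfig) -> np.ndarray:
    rates = np.ones(config.seq_length)
    if config.rate_multiplier_windows:
        for (start, end), mult in config.rate_multiplier_windows.items():
            rates[start:end] = mult
    return rates


def evolve_sequence(
    seq: str,
    distance: float,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
) -> str:
    """Evolve a DNA sequence by ``distance`` substitutions/site under JC.

    Each site substitutes independently with probability
    ``(3/4)(1 - exp(-(4/3) d))`` (``d`` scaled per site by ``site_rates``),
    uniformly among the three alternative bases.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    d = distance * (site_rates if site_rates is not None else 1.0)
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    hit = rng.random(len(seq)) < p
    idx = np.flatnonzero(hit)
    for i in idx:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def simulate_repertoire(config: SimConfig) -> tuple[SpeciesRepertoire, SimTruth]:
    """Generate one species repertoire plus its ground truth.

    Fully reproducible from ``config.seed``. Genuine genes get COVE scores
    Uniform(50, 90); pseudogene decoys Uniform(10, 39.5) — only the 40-bit
    threshold matters downstream.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species_id or f"Simulated_species_{config.seed}"
    anticodons = config.resolved_anticodons()
    copies = config.resolved_copies()
    total = sum(copies)
    if config.n_switches > total:
        raise ValueError("n_switches exceeds total copy count")
    rates = _site_rates(config)
    a0 = config.anticodon_start

    root = "".join(_BASES[rng.integers(0, 4, size=config.seq_length)])

    # (family_index, copy_index, sequence, anticodon)
    genes: list[dict] = []
    for f, (ac, n_copies) in enumerate(zip(anticodons, copies)):
        ancestor = evolve_sequence(root, config.delta_between, rng, rates)
        ancestor = ancestor[:a0] + ac + ancestor[a0 + 3 :]
        for c in range(n_copies):
            seq = evolve_sequence(ancestor, config.delta_within, rng, rates)
            seq = seq[:a0] + ac + seq[a0 + 3 :]
            genes.append(
                {"family": f, "copy": c, "sequence": seq, "anticodon": ac}
            )

    # inject switches: overwrite only the recipient's anticodon window
    events: list[SwitchEvent] = []
    recipients = rng.choice(total, size=config.n_switches, replace=False)
    recipient_idx = {int(r) for r in recipients}
    for r in sorted(recipient_idx):
        g = genes[r]
        donor_choices = [i for i in range(config.n_families) if i != g["family"]]
        donor = donor_choices[rng.integers(0, len(donor_choices))]
        donor_ac = anticodons[donor]
        recipient_ac = anticodons[g["family"]]
        g["sequence"] = g["sequence"][:a0] + donor_ac + g["sequence"][a0 + 3 :]
        g["anticodon"] = donor_ac
        g["switched"] = True
        events.append(
            SwitchEvent(
                recipient_gene_id="",  # filled once ids are assigned
                recipient_family=recipient_ac,
                donor_family=donor_ac,
                changed_positions=frozenset(
                    i + 1 for i in range(3) if recipient_ac[i] != donor_ac[i]
                ),
            )
        )

    # pseudogene decoys: extra degraded copies of random families
    n_pseudo = int(round(config.pseudogene_rate * total))
    pseudo_specs = []
    for _ in range(n_pseudo):
        f = int(rng.integers(0, config.n_families))
        seq = evolve_sequence(root, config.delta_between, rng, rates)
        seq = seq[:a0] + anticodons[f] + seq[a0 + 3 :]
        pseudo_specs.append({"family": f, "sequence": seq, "anticodon": anticodons[f]})

    # assign ids from final anticodons (the annotation a gene finder reports)
    records: list[TRNAGeneRecord] = []
    event_iter = iter(events)
    events_out: list[SwitchEvent] = []
    per_ac_counter: dict[str, int] = {}
    for g in genes:
        ac = g["anticodon"]
        per_ac_counter[ac] = per_ac_counter.get(ac, 0) + 1
        aa = anticodon_to_amino_acid(ac)
        gene_id = f"{species}_tRNA-{aa}-{ac}-{g['family'] + 1}-{per_ac_counter[ac]}"
        records.append(
            TRNAGeneRecord(
                gene_id=gene_id,
                species_id=species,
                amino_acid=aa,
                anticodon=ac,
                anticodon_start=a0,
                sequence=g["sequence"],
                cove_score=float(rng.uniform(50.0, 90.0)),
                domain_of_life=config.domain_of_life,
            )
        )
        if g.get("switched"):
            ev = next(event_iter)
            events_out.append(
                SwitchEvent(
                    gene_id, ev.recipient_family, ev.donor_family,
                    ev.changed_positions,
                )
            )
    pseudo_ids = []
    for k, ps in enumerate(pseudo_specs):
        ac = ps["anticodon"]
        aa = anticodon_to_amino_acid(ac)
        gene_id = f"{species}_tRNA-{aa}-{ac}-pseudo-{k + 1}"
        pseudo_ids.append(gene_id)
        records.append(
            TRNAGeneRecord(
                gene_id=gene_id,
                species_id=species,
                amino_acid=aa,
                anticodon=ac,
                anticodon_start=a0,
                sequence=ps["sequence"],
                cove_score=float(rng.uniform(10.0, 39.5)),
                domain_of_life=config.domain_of_life,
            )
        )

    truth = SimTruth(
        switched_gene_ids=frozenset(e.recipient_gene_id for e in events_out),
        events=tuple(events_out),
        pseudogene_ids=frozenset(pseudo_ids),
    )
    return SpeciesRepertoire(species, records, config.domain_of_life), truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well a set of calls recovers the simulated truth."""

    n_true: int
    n_called: int
    n_true_positive: int
    n_false_positive: int
    n_evaluated_negative: int
    recall: float | None
    false_positive_proportion: float | None
    attribution_accuracy: float | None


def score_calls(calls: Sequence, truth: SimTruth) -> RecoveryMetrics:
    """Score switch calls against simulated ground truth.

    recall = called true switches / all true switches;
    false-positive proportion = spurious calls / evaluated non-switched
    records; attribution accuracy = fraction of true positives whose
    changed positions exactly match the injected event. Undefined ratios
    (empty denominators) are ``None``.
    """
    call_ids = {c.gene_id for c in calls}
    missing = truth.switched_gene_ids - truth.pseudogene_ids - call_ids
    if missing:
        raise ValueError(f"calls lack truth genes: {sorted(missing)[:3]}")
    truth_pos = {e.recipient_gene_id: e.changed_positions for e in truth.events}
    called = [c for c in calls if c.switched]
    tp = [c for c in called if c.gene_id in truth.switched_gene_ids]
    fp = [c for c in called if c.gene_id not in truth.switched_gene_ids]
    eval_neg = [
        c
        for c in calls
        if c.evaluated and c.gene_id not in truth.switched_gene_ids
    ]
    n_true = len(truth.switched_gene_ids)
    recall = len(tp) / n_true if n_true else None
    fpp = len(fp) / len(eval_neg) if eval_neg else None
    attrib = (
        sum(c.changed_positions == truth_pos[c.gene_id] for c in tp) / len(tp)
        if tp
        else None
    )
    return RecoveryMetrics(
        n_true=n_true,
        n_called=len(called),
        n_true_positive=len(tp),
        n_false_positive=len(fp),
        n_evaluated_negative=len(eval_neg),
        recall=recall,
        false_positive_proportion=fpp,
        attribution_accuracy=attrib,
    )
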