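"""Anticodon-switch calling from patristic distances.

A tRNA is putatively *switched* when its scaffold sits closer, on the
per-species tree of anticodon-masked sequences, to a tRNA carrying a
different anticodon than to any tRNA carrying the same anticodon:
``d_diff < d_same`` (strict). Only tRNAs whose anticodon occurs at least
twice in the species, with at least one differently-labeled tRNA present,
are evaluated. The same machinery, applied to control triplets (grouping by
the control triplet's content instead of the anticodon), yields the control
comparison.

``d_diff`` minimizes over all other tRNAs of the species regardless of
amino acid; a ``same_aa_only`` flag restricts the comparison to tRNAs
decoding the same amino acid for downstream filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .mask_align import (
    AlignParams,
    Alignment,
    ANTICODON_LABEL,
    MaskSpec,
    MaskedRecord,
    align_repertoire,
    control_spec,
    default_control_offsets,
    mask_triplet,
)
from .phylo import PatristicTable, build_nj_tree, pairwise_distances, patristic_distances
from .records import SpeciesRepertoire, TRNAGeneRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwitchCall:
    """Per-tRNA nearest-neighbor result for one mask label."""

    gene_id: str
    species_id: str
    amino_acid: str
    group_key: str
    d_same: float | None = None
    d_diff: float | None = None
    nearest_same_id: str | None = None
    nearest_diff_id: str | None = None
    evaluated: bool = False
    switched: bool = False
    changed_positions: frozenset[int] = frozenset()


@dataclass(frozen=True)
class SpeciesSwitchSummary:
    """Per-species tally for one mask label."""

    species_id: str
    mask_label: str
    n_records: int
    n_evaluated: int
    n_switched: int
    proportion_switched: float | None
    position_counts: dict[int, int]


TIE_TOLERANCE = 1e-9  # path sums over equal-length zero branches differ by
# float rounding; mathematically equal distances must compare as ties


def call_switches(
    pt: PatristicTable,
    masked: Sequence[MaskedRecord],
    same_aa_only: bool = False,
    tie_tolerance: float = TIE_TOLERANCE,
) -> list[SwitchCall]:
    """Compute d_same/d_diff for every record and flag strict d_diff < d_same.

    ``d_same`` is the minimum patristic distance to another record with the
    same group key (anticodon, for the main analysis); ``d_diff`` the minimum
    to a record with a different group key. Nearest-neighbor ties break by
    lexicographic gene_id. Records whose group key is a singleton, or with
    no differently-keyed partner, are not evaluated. Equal distances
    (including d_same = d_diff = 0 for identical sequences) are not
    switches; equality is judged to ``tie_tolerance`` because patristic
    path sums of identical leaves can differ by float rounding.
    """
    ids = {m.gene_id for m in masked}
    if ids != set(pt.ids):
        raise ValueError("patristic table ids do not match masked records")
    by_id = {m.gene_id: m for m in masked}
    calls: list[SwitchCall] = []
    for m in masked:
        partners_same: list[str] = []
        partners_diff: list[str] = []
        for other in masked:
            if other.gene_id == m.gene_id:
                continue
            if same_aa_only and other.record.amino_acid != m.record.amino_acid:
                continue
            if other.group_key == m.group_key:
                partners_same.append(other.gene_id)
            else:
                partners_diff.append(other.gene_id)
        evaluated = bool(partners_same) and bool(partners_diff)
        d_same = d_diff = None
        near_same = near_diff = None
        if partners_same:
            near_same = min(partners_same, key=lambda g: (pt.get(m.gene_id, g), g))
            d_same = pt.get(m.gene_id, near_same)
        if partners_diff:
            near_diff = min(partners_diff, key=lambda g: (pt.get(m.gene_id, g), g))
            d_diff = pt.get(m.gene_id, near_diff)
        switched = bool(evaluated and (d_same - d_diff) > tie_tolerance)
        call = SwitchCall(
            gene_id=m.gene_id,
            species_id=m.record.species_id,
            amino_acid=m.record.amino_acid,
            group_key=m.group_key,
            d_same=d_same,
            d_diff=d_diff,
            nearest_same_id=near_same,
            nearest_diff_id=near_diff,
            evaluated=evaluated,
            switched=switched,
        )
        if switched:
            call = attribute_positions(call, masked)
        calls.append(call)
    return calls


def attribute_positions(
    call: SwitchCall, masked: Sequence[MaskedRecord]
) -> SwitchCall:
    """Record which triplet positions differ from the nearest different-key
    neighbor.

    Position 1 is the 5' position of the anticodon, the one that pairs with
    codon position 3. Only defined for switched calls (the partner is the
    leaf achieving d_diff).
    """
    if not call.switched or call.nearest_diff_id is None:
        raise ValueError(
            f"position attribution requires a switched call ({call.gene_id})"
        )
    partner = next(m for m in masked if m.gene_id == call.nearest_diff_id)
    changed = frozenset(
        i + 1 for i in range(3) if call.group_key[i] != partner.group_key[i]
    )
    if not changed:
        raise ValueError(
            f"{call.gene_id}: nearest different-key neighbor has identical "
            f"triplet; grouping is inconsistent"
        )
    return replace(call, changed_positions=changed)


def summarize_species(
    calls: Sequence[SwitchCall], mask_label: str = ANTICODON_LABEL
) -> SpeciesSwitchSummary:
    """Tally evaluated/switched counts and per-position contributions.

    A switched call contributes one count to *each* of its changed
    positions, so the position counts may sum to more than the number of
    switch events.
    """
    species = {c.species_id for c in calls}
    if len(species) > 1:
        raise ValueError(f"calls from multiple species: {sorted(species)}")
    n_eval = sum(c.evaluated for c in calls)
    switched = [c for c in calls if c.switched]
    pos_counts = {1: 0, 2: 0, 3: 0}
    for c in switched:
        for p in c.changed_positions:
            pos_counts[p] += 1
    return SpeciesSwitchSummary(
        species_id=next(iter(species)) if species else "",
        mask_label=mask_label,
        n_records=len(calls),
        n_evaluated=n_eval,
        n_switched=len(switched),
        proportion_switched=(len(switched) / n_eval) if n_eval else None,
        position_counts=pos_counts,
    )


@dataclass(frozen=True)
class MaskAnalysis:
    """Everything computed for one mask label on one species."""

    label: str
    masked: tuple[MaskedRecord, ...]
    alignment: Alignment
    patristic: PatristicTable
    calls: tuple[SwitchCall, ...]
    summary: SpeciesSwitchSummary
    tree: object  # skbio TreeNode


def analyze_mask(
    records: Sequence[TRNAGeneRecord],
    spec: MaskSpec,
    align_params: AlignParams = AlignParams(),
    model: str = "jc",
    same_aa_only: bool = False,
) -> MaskAnalysis:
    """Run mask -> align -> distances -> tree -> patristic -> calls for one
    mask label on an already pseudogene-filtered record set."""
    masked = [m for m in (mask_triplet(r, spec) for r in records) if m is not None]
    if len(masked) < 2:
        raise ValueError(
            f"mask {spec.label!r}: fewer than 2 maskable records; nothing to align"
        )
    alignment = align_repertoire(masked, align_params)
    dm = pairwise_distances(alignment, model=model)
    tree = build_nj_tree(dm)
    pt = patristic_distances(tree)
    calls = call_switches(pt, masked, same_aa_only=same_aa_only)
    summary = summarize_species(calls, spec.label)
    return MaskAnalysis(
        spec.label, tuple(masked), alignment, pt, tuple(calls), summary, tree
    )


def control_comparison(
    repertoire: SpeciesRepertoire,
    n_controls: int = 6,
    align_params: AlignParams = AlignParams(),
    model: str = "jc",
    same_aa_only: bool = False,
) -> dict[str, SpeciesSwitchSummary]:
    """Run the full chain with the anticodon mask and each control mask.

    Control offsets are taken from the first record's geometry (tRNA genes
    in one species have near-identical length); grouping in a control run
    uses the control triplet's original content as group key, so a flagged
    record is one clustering with tRNAs that carry a dissimilar triplet at
    the control window. Returns one summary per mask label, the anticodon
    mask first.
    """
    if not repertoire.records:
        raise ValueError("empty repertoire")
    offsets = default_control_offsets(repertoire.records[0], n_controls)
    specs = [MaskSpec()] + [
        control_spec(o, f"ctrl_{chr(ord('A') + i)}") for i, o in enumerate(offsets)
    ]
    out: dict[str, SpeciesSwitchSummary] = {}
    for spec in specs:
        try:
            out[spec.label] = analyze_mask(
                repertoire.records, spec, align_params, model, same_aa_only
            ).summary
        except Exception as exc:
            raise RuntimeError(f"mask {spec.label!r} failed: {exc}") from exc
    return out
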