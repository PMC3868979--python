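"""Triplet masking and per-species multiple alignment.

The screen masks the anticodon triplet of every tRNA as ``NNN`` *before*
alignment and tree inference, so the anticodon itself cannot influence
clustering; the original triplet content is kept aside as the ``group_key``
used later for same/different grouping. The same machinery masks control
triplets elsewhere in the molecule for the control comparison.

The built-in aligner is a deterministic progressive aligner: sequences are
clustered by 3-mer count distances (average linkage), then profiles are
merged along the cluster order with affine-gap pairwise alignment (Gotoh).
``N`` scores as neutral (0 against anything), so masked triplets neither
attract nor repel. An adapter contract allows substituting any external
aligner that maps a FASTA of masked sequences to a gapped FASTA with the
same ids.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist

from .records import TRNAGeneRecord

log = logging.getLogger(__name__)

ANTICODON_LABEL = "anticodon"


@dataclass(frozen=True)
class MaskSpec:
    """Which triplet to mask: the anticodon, or a fixed control offset."""

    kind: str = "anticodon"  # "anticodon" | "control"
    control_offsets: tuple[int, ...] | None = None
    label: str = ANTICODON_LABEL

    def __post_init__(self) -> None:
        if self.kind not in ("anticodon", "control"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if self.kind == "control":
            if not self.control_offsets or len(self.control_offsets) != 1:
                raise ValueError("control mask requires exactly one start offset")


def control_spec(offset: int, label: str | None = None) -> MaskSpec:
    return MaskSpec("control", (offset,), label or f"ctrl_{offset}")


@dataclass(frozen=True)
class MaskedRecord:
    """A record with exactly one NNN triplet; ``group_key`` is what was there."""

    record: TRNAGeneRecord
    masked_sequence: str
    mask_start: int
    group_key: str

    @property
    def gene_id(self) -> str:
        return self.record.gene_id

    def unmask(self) -> str:
        s = self.masked_sequence
        return s[: self.mask_start] + self.group_key + s[self.mask_start + 3 :]


def mask_triplet(record: TRNAGeneRecord, spec: MaskSpec) -> MaskedRecord | None:
    """Mask one triplet of ``record`` as NNN.

    For an anticodon mask, the window is the annotated anticodon. For a
    control mask, the window is the spec's offset; records where the control
    window would run out of bounds or overlap the anticodon triplet are
    skipped (``None``) with a warning, keeping the control honest.
    """
    seq = record.sequence
    if spec.kind == "anticodon":
        start = record.anticodon_start
        if start is None:
            raise ValueError(f"{record.gene_id}: anticodon_start not set")
    else:
        start = spec.control_offsets[0]
        if start < 0 or start + 3 > len(seq):
            log.warning(
                "%s: control offset %d out of bounds; record skipped",
                record.gene_id,
                start,
            )
            return None
        a = record.anticodon_start
        if a is not None and not (start + 3 <= a or start >= a + 3):
            log.warning(
                "%s: control offset %d overlaps anticodon at %d; record skipped",
                record.gene_id,
                start,
                a,
            )
            return None
    triplet = seq[start : start + 3]
    masked = seq[:start] + "NNN" + seq[start + 3 :]
    return MaskedRecord(record, masked, start, triplet)


def default_control_offsets(
    record: TRNAGeneRecord, n_controls: int = 6
) -> list[int]:
    """Evenly-spread non-overlapping control windows avoiding the anticodon.

    For a 72-nt gene the anchors are 0-based starts 2, 14, 26, 43, 54, 64
    (scaled proportionally for other lengths); any window that would overlap
    the anticodon triplet is shifted minimally. Deterministic; returns fewer
    windows when the sequence cannot host ``n_controls`` disjoint ones.
    """
    length = len(record.sequence)
    a = record.anticodon_start
    anchors = [2, 14, 26, 43, 54, 64][:n_controls]
    if n_controls > 6:
        anchors = [
            round(i * (length - 4) / max(n_controls - 1, 1)) for i in range(n_controls)
        ]
    placed: list[int] = []

    def ok(o: int) -> bool:
        if o < 0 or o + 3 > length:
            return False
        if a is not None and not (o + 3 <= a or o >= a + 3):
            return False
        return all(abs(o - p) >= 3 for p in placed)

    for anchor in anchors:
        o0 = round(anchor * length / 72)
        for delta in range(0, length):
            for cand in (o0 + delta, o0 - delta) if delta else (o0,):
                if ok(cand):
                    placed.append(cand)
                    break
            else:
                continue
            break
    if len(placed) < n_controls:
        log.info(
            "%s: only %d of %d control windows placeable",
            record.gene_id,
            len(placed),
            n_controls,
        )
    return placed


@dataclass(frozen=True)
class Alignment:
    """Per-species multiple alignment over ``{A,C,G,T,N,-}``."""

    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows are not equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.row_ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


_CODE = {c: i for i, c in enumerate("ACGTN-")}


def _encode(row: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in row), dtype=np.int8, count=len(row))


def _profile(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Base counts (L, 4) and per-column concrete-base totals (L,)."""
    arr = np.stack([_encode(r) for r in rows])
    counts = np.stack([(arr == b).sum(axis=0) for b in range(4)], axis=1).astype(
        float
    )
    return counts, counts.sum(axis=1)


def _pair_align(
    rows1: list[str], rows2: list[str], p: AlignParams
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles (Gotoh, full traceback).

    Column score is the expected pairwise score between a residue drawn from
    each column; N and gap characters contribute 0 (neutral).
    """
    c1, n1 = _profile(rows1)
    c2, n2 = _profile(rows2)
    L1, L2 = len(n1), len(n2)
    r1, r2 = len(rows1), len(rows2)
    matches = c1 @ c2.T
    S = (p.match * matches + p.mismatch * (np.outer(n1, n2) - matches)) / (r1 * r2)

    NEG = -1e30
    M = np.full((L1 + 1, L2 + 1), NEG)
    X = np.full((L1 + 1, L2 + 1), NEG)  # gap in rows2 (consume rows1)
    Y = np.full((L1 + 1, L2 + 1), NEG)  # gap in rows1 (consume rows2)
    M[0, 0] = 0.0
    go, ge = p.gap_open, p.gap_extend
    for i in range(1, L1 + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, L2 + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, L1 + 1):
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        best_prev = np.maximum(np.maximum(Mp[:-1], Xp[:-1]), Yp[:-1])
        M[i][1:] = best_prev + S[i - 1]
        X[i] = np.maximum(Mp + go, Xp + ge)
        Yrow = Y[i]  # depends on the same row: fill left-to-right
        Mi = M[i]
        for j in range(1, L2 + 1):
            Yrow[j] = max(Mi[j - 1] + go, Yrow[j - 1] + ge)
    # traceback
    ops: list[str] = []
    i, j = L1, L2
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                state = "X" if j == 0 else "Y"
                continue
            ops.append("M")
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = ("M", "X", "Y")[int(np.argmax(prev))]
        elif state == "X":
            ops.append("X")
            came_open = M[i - 1, j] + p.gap_open
            came_ext = X[i - 1, j] + p.gap_extend
            i -= 1
            state = "M" if came_open >= came_ext else "X"
        else:
            ops.append("Y")
            came_open = M[i, j - 1] + p.gap_open
            came_ext = Y[i, j - 1] + p.gap_extend
            j -= 1
            state = "M" if came_open >= came_ext else "Y"
    ops.reverse()
    out1 = ["" for _ in rows1]
    out2 = ["" for _ in rows2]
    i = j = 0
    for op in ops:
        if op in ("M", "X"):
            for k, r in enumerate(rows1):
                out1[k] += r[i]
            i += 1
        else:
            for k in range(len(rows1)):
                out1[k] += "-"
        if op in ("M", "Y"):
            for k, r in enumerate(rows2):
                out2[k] += r[j]
            j += 1
        else:
            for k in range(len(rows2)):
                out2[k] += "-"
    return out1, out2


def _kmer_vectors(seqs: list[str], k: int = 3) -> np.ndarray:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    vecs = np.zeros((len(seqs), 4**k))
    for s_i, s in enumerate(seqs):
        for pos in range(len(s) - k + 1):
            kmer = s[pos : pos + k]
            code = 0
            for ch in kmer:
                b = idx.get(ch)
                if b is None:
                    code = -1
                    break
                code = code * 4 + b
            if code >= 0:
                vecs[s_i, code] += 1
    return vecs


def align_repertoire(
    masked: Sequence[MaskedRecord],
    params: AlignParams = AlignParams(),
) -> Alignment:
    """Progressively align the masked sequences of one species.

    Deterministic: records are processed in lexicographic gene_id order
    (so the result is invariant to input ordering); the guide order is
    average-linkage clustering of 3-mer count distances. Output rows are
    returned in the input order. Degapping any row reproduces that record's
    masked sequence.
    """
    if len(masked) < 2:
        raise ValueError("nothing to align: need at least 2 sequences")
    species = {m.record.species_id for m in masked}
    if len(species) > 1:
        raise ValueError(f"records from multiple species: {sorted(species)}")
    ids_in_order = [m.gene_id for m in masked]
    if len(set(ids_in_order)) != len(ids_in_order):
        raise ValueError("duplicate gene ids")
    lengths = [len(m.masked_sequence) for m in masked]
    if max(lengths) / max(min(lengths), 1) > 3:
        log.warning("wildly discordant sequence lengths (ratio > 3); proceeding")

    order = sorted(range(len(masked)), key=lambda i: masked[i].gene_id)
    seqs = [masked[i].masked_sequence for i in order]
    ids = [masked[i].gene_id for i in order]

    if len(seqs) == 2:
        o1, o2 = _pair_align([seqs[0]], [seqs[1]], params)
        final_rows = o1 + o2
        final_members = [0, 1]
    else:
        vecs = _kmer_vectors(seqs)
        dists = pdist(vecs, metric="euclidean")
        Z = average(dists)
        aligned = {i: [s] for i, s in enumerate(seqs)}
        members = {i: [i] for i in range(len(seqs))}
        nxt = len(seqs)
        for a_id, b_id, _, _ in Z:
            a_id, b_id = int(a_id), int(b_id)
            o1, o2 = _pair_align(aligned[a_id], aligned[b_id], params)
            aligned[nxt] = o1 + o2
            members[nxt] = members[a_id] + members[b_id]
            del aligned[a_id], aligned[b_id], members[a_id], members[b_id]
            nxt += 1
        final_rows = aligned[nxt - 1]
        final_members = members[nxt - 1]

    by_id = {ids[m]: row for m, row in zip(final_members, final_rows)}
    rows_out = tuple(by_id[g] for g in ids_in_order)
    return Alignment(tuple(ids_in_order), rows_out)


class ExternalAligner:
    """Subprocess adapter: FASTA of masked sequences in, gapped FASTA out.

    ``argv`` is the command; the input path is appended (or substituted for
    a ``{in}`` placeholder). Output is read from stdout. The adapter checks
    the aligner contract: identical id set and rows that degap to their
    inputs.
    """

    def __init__(self, argv: Sequence[str]):
        if not argv:
            raise ValueError("empty aligner command")
        self.argv = list(argv)
        exe = shutil.which(self.argv[0])
        if exe is None:
            raise FileNotFoundError(f"aligner executable not found: {self.argv[0]}")

    def __call__(
        self, masked: Sequence[MaskedRecord], params: AlignParams = AlignParams()
    ) -> Alignment:
        if len(masked) < 2:
            raise ValueError("nothing to align: need at least 2 sequences")
        with tempfile.TemporaryDirectory() as tmp:
            in_path = Path(tmp) / "input.fasta"
            with open(in_path, "w") as fh:
                for m in masked:
                    fh.write(f">{m.gene_id}\n{m.masked_sequence}\n")
            argv = [
                a.replace("{in}", str(in_path)) for a in self.argv
            ]
            if "{in}" not in " ".join(self.argv):
                argv.append(str(in_path))
            proc = subprocess.run(
                argv, capture_output=True, text=True, check=True
            )
            out_path = Path(tmp) / "output.fasta"
            out_path.write_text(proc.stdout)
            aln = Alignment.from_fasta(out_path)
        expected = {m.gene_id: m.masked_sequence for m in masked}
        if set(aln.row_ids) != set(expected):
            raise ValueError("external aligner changed the id set")
        for rid, row in zip(aln.row_ids, aln.rows):
            if row.replace("-", "") != expected[rid]:
                raise ValueError(
                    f"external aligner violated contract: row {rid} does not "
                    f"degap to its input"
                )
        # restore input row order
        order = [aln.row_ids.index(m.gene_id) for m in masked]
        return Alignment(
            tuple(aln.row_ids[i] for i in order),
            tuple(aln.rows[i] for i in order),
        )
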