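"""Reading tRNA gene collections and writing result tables.

Two input routes are supported: FASTA with GtRNAdb-style headers (one record
per tRNA gene) and tRNAscan-SE tabular output with a companion genome FASTA.
Both yield :class:`~trnaswitch.records.SpeciesRepertoire` objects with
identical semantics. The pseudogene filter and the switch-table writer/reader
also live here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .records import (
    SpeciesRepertoire,
    TRNAGeneRecord,
    anticodon_to_amino_acid,
    locate_anticodon,
    rna,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file or header."""


@dataclass(frozen=True)
class HeaderDialect:
    """Regex-configurable FASTA header grammar.

    The default targets GtRNAdb-style names such as
    ``Saccharomyces_cerevisiae_tRNA-Arg-CCT-1-1``; named groups ``species``,
    ``aa`` and ``anticodon`` are required, ``start`` (0-based anticodon
    offset) is optional. COVE scores and domains are taken from ``key=value``
    pairs in the description (``cove=66.6 domain=eukaryota``) when present.
    """

    pattern: str = (
        r"^(?P<species>[A-Za-z0-9][A-Za-z0-9_.\-]*?)_tRNA-"
        r"(?P<aa>[A-Za-z]{3}|Und|SeC|iMet|fMet)-"
        r"(?P<anticodon>[ACGTUacgtu]{3})(?:-[\w.]+)*$"
    )

    def parse(self, header_id: str, description: str) -> dict:
        m = re.match(self.pattern, header_id)
        if m is None:
            raise FormatError(f"header does not match dialect: {header_id!r}")
        info = m.groupdict()
        info["anticodon"] = info["anticodon"].upper().replace("U", "T")
        for key, value in re.findall(r"(\w+)=([^\s]+)", description):
            info.setdefault(key, value)
        return info


DEFAULT_DIALECT = HeaderDialect()


def _normalize_seq(raw: str) -> str:
    return str(raw).upper().replace("U", "T")


def read_gtrnadb_fasta(
    path: str | Path,
    header_dialect: HeaderDialect = DEFAULT_DIALECT,
) -> list[SpeciesRepertoire]:
    """Read a FASTA of tRNA genes into per-species repertoires.

    Sequences are uppercased and U->T normalized. When the header does not
    carry an explicit anticodon offset, the offset is located as the
    occurrence of the annotated anticodon closest to the sequence midpoint;
    records whose sequence does not contain the annotated anticodon at all
    are excluded with a warning. Record order within a species follows file
    order; repertoires are returned in order of first appearance.
    """
    path = Path(path)
    by_species: dict[str, SpeciesRepertoire] = {}
    seen_ids: dict[str, set[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        info = header_dialect.parse(rec.id, rec.description)
        sequence = _normalize_seq(rec.seq)
        anticodon = info["anticodon"]
        if "start" in info and info["start"] is not None:
            start = int(info["start"])
        else:
            start = locate_anticodon(sequence, anticodon)
        if start is None:
            log.warning(
                "%s: anticodon %s not found in sequence of %s; record excluded",
                path,
                anticodon,
                rec.id,
            )
            continue
        species = info["species"]
        cove = float(info["cove"]) if "cove" in info else None
        domain = info.get("domain", "unknown")
        gene = TRNAGeneRecord(
            gene_id=rec.id,
            species_id=species,
            amino_acid=info.get("aa") or anticodon_to_amino_acid(anticodon),
            anticodon=anticodon,
            anticodon_start=start,
            sequence=sequence,
            cove_score=cove,
            domain_of_life=domain,
        )
        rep = by_species.get(species)
        if rep is None:
            rep = by_species[species] = SpeciesRepertoire(species, [], domain)
            seen_ids[species] = set()
        if gene.gene_id in seen_ids[species]:
            raise FormatError(f"duplicate gene_id {gene.gene_id!r} in {species}")
        seen_ids[species].add(gene.gene_id)
        rep.records.append(gene)
    return list(by_species.values())


_TRNASCAN_COLUMNS = [
    "seq_name",
    "trna_number",
    "begin",
    "end",
    "trna_type",
    "anticodon",
    "intron_begin",
    "intron_end",
    "cove_score",
]


def read_trnascan_tabular(
    path: str | Path,
    genome_fasta: str | Path,
    species_id: str | None = None,
    domain_of_life: str = "unknown",
) -> list[SpeciesRepertoire]:
    """Read tRNAscan-SE tabular output plus its companion genome FASTA.

    Columns are the standard nine: sequence name, tRNA number, begin, end,
    type, anticodon, intron begin/end, score (1-based, inclusive genomic
    coordinates). Minus-strand genes (begin > end) are reverse-complemented
    so the anticodon appears in sense orientation. Intron coordinates are
    recorded in the log but sequences are used as extracted (no splicing).
    Rows of type ``Pseudo`` are kept; the COVE-score filter handles them.
    """
    path = Path(path)
    genome = {
        rec.id: _normalize_seq(rec.seq)
        for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    records: list[TRNAGeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("Sequence", "Name", "----")):
                continue  # header block emitted by tRNAscan-SE
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < len(_TRNASCAN_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected >= {len(_TRNASCAN_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}"
                )
            row = dict(zip(_TRNASCAN_COLUMNS, fields))
            try:
                score = float(row["cove_score"])
            except ValueError:
                log.warning(
                    "%s:%d: non-numeric score %r; record rejected",
                    path,
                    lineno,
                    row["cove_score"],
                )
                continue
            begin, end = int(row["begin"]), int(row["end"])
            src = genome.get(row["seq_name"])
            if src is None:
                raise FormatError(
                    f"{path}:{lineno}: sequence {row['seq_name']!r} "
                    f"not in genome FASTA"
                )
            if begin <= end:
                seq = src[begin - 1 : end]
            else:
                seq = str(Seq(src[end - 1 : begin]).reverse_complement())
            anticodon = row["anticodon"].upper().replace("U", "T")
            start = locate_anticodon(seq, anticodon)
            if start is None:
                log.warning(
                    "%s:%d: anticodon %s not found in extracted sequence; "
                    "record excluded",
                    path,
                    lineno,
                    anticodon,
                )
                continue
            if row["intron_begin"] not in ("0", "", None) and int(row["intron_begin"]):
                log.info(
                    "%s:%d: intron at %s-%s recorded, sequence not spliced",
                    path,
                    lineno,
                    row["intron_begin"],
                    row["intron_end"],
                )
            sp = species_id or row["seq_name"]
            trna_type = row["trna_type"]
            records.append(
                TRNAGeneRecord(
                    gene_id=f"{sp}_tRNA-{trna_type}-{anticodon}-{row['trna_number']}",
                    species_id=sp,
                    amino_acid="Und" if trna_type == "Pseudo" else trna_type,
                    anticodon=anticodon,
                    anticodon_start=start,
                    sequence=seq,
                    cove_score=score,
                    domain_of_life=domain_of_life,
                )
            )
    by_species: dict[str, SpeciesRepertoire] = {}
    for gene in records:
        rep = by_species.setdefault(
            gene.species_id,
            SpeciesRepertoire(gene.species_id, [], domain_of_life),
        )
        rep.records.append(gene)
    return list(by_species.values())


def filter_pseudogenes(
    records: Iterable[TRNAGeneRecord], threshold: float = 40.0
) -> list[TRNAGeneRecord]:
    """Remove putative pseudogenes: records with COVE score < ``threshold``.

    Strictly-below removal: a record scoring exactly ``threshold`` bits is
    retained. Order is preserved. Records lacking a score raise.
    """
    kept = []
    for rec in records:
        if rec.cove_score is None:
            raise ValueError(f"record {rec.gene_id} has no cove_score")
        if rec.cove_score >= threshold:
            kept.append(rec)
    return kept


SWITCH_TABLE_COLUMNS = [
    "species",
    "gene_id",
    "amino_acid",
    "anticodon",
    "d_same",
    "d_diff",
    "switched",
    "nearest_same_id",
    "nearest_diff_id",
    "changed_positions",
]


def _fmt_float(x) -> str:
    return "NA" if x is None else f"{x:.6f}"


def write_switch_table(calls: Sequence, path: str | Path) -> None:
    """Write switch calls as a TSV (floats at 6 decimals, NA for undefined)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "species": c.species_id,
                "gene_id": c.gene_id,
                "amino_acid": c.amino_acid,
                "anticodon": rna(c.group_key),
                "d_same": _fmt_float(c.d_same),
                "d_diff": _fmt_float(c.d_diff),
                "switched": str(bool(c.switched)),
                "nearest_same_id": c.nearest_same_id or "NA",
                "nearest_diff_id": c.nearest_diff_id or "NA",
                "changed_positions": ",".join(map(str, sorted(c.changed_positions)))
                or "NA",
            }
        )
    df = pd.DataFrame(rows, columns=SWITCH_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_switch_table(path: str | Path) -> list:
    """Re-read a switch table written by :func:`write_switch_table`."""
    from .detect import SwitchCall

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for _, row in df.iterrows():
        d_same = None if row["d_same"] == "NA" else float(row["d_same"])
        d_diff = None if row["d_diff"] == "NA" else float(row["d_diff"])
        positions = (
            frozenset()
            if row["changed_positions"] == "NA"
            else frozenset(int(p) for p in row["changed_positions"].split(","))
        )
        calls.append(
            SwitchCall(
                gene_id=row["gene_id"],
                species_id=row["species"],
                amino_acid=row["amino_acid"],
                group_key=row["anticodon"].replace("U", "T"),
                d_same=d_same,
                d_diff=d_diff,
                nearest_same_id=None
                if row["nearest_same_id"] == "NA"
                else row["nearest_same_id"],
                nearest_diff_id=None
                if row["nearest_diff_id"] == "NA"
                else row["nearest_diff_id"],
                switched=row["switched"] == "True",
                evaluated=d_same is not None and d_diff is not None,
                changed_positions=positions,
            )
        )
    return calls


def write_repertoire_fasta(rep: SpeciesRepertoire, path: str | Path) -> None:
    """Write a repertoire as FASTA with the default header dialect.

    Headers look like ``Species_tRNA-Arg-CCT-1-1 cove=66.6 domain=eukaryota``
    and round-trip through :func:`read_gtrnadb_fasta`.
    """
    with open(path, "w") as fh:
        for rec in rep.records:
            desc = f" start={rec.anticodon_start} domain={rec.domain_of_life}"
            if rec.cove_score is not None:
                desc = f" cove={rec.cove_score:.1f}" + desc
            fh.write(f">{rec.gene_id}{desc}\n{rec.sequence}\n")
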