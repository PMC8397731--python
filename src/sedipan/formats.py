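"""Reading and writing FASTA files and tabular genome metadata.

Every other module works on the two container types defined here:
:class:`SequenceRecord` (a protein or nucleotide sequence with provenance)
and :class:`GenomeEntry` (a genome with its clade placement, habitat flags
and quality estimates).

Genome attribution follows a one-proteome-file-per-genome convention: the
``genome_id`` of every record read from ``proteins.faa`` defaults to the
file stem ``proteins``, and can be overridden per record with a
``genome=<id>`` token in the FASTA description.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SequenceRecord",
    "GenomeEntry",
    "ORDERS",
    "NP_SUBCLADES",
    "HABITAT_FLAGS",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_annotations",
]

#: The four major AOA orders plus the outgroup bucket.
#: NP Nitrosopumilales, NC Ca. Nitrosocaldales, NS Nitrososphaerales,
#: NT Ca. Nitrosotaleales.
ORDERS = ("NC", "NS", "NT", "NP", "OUTGROUP")

#: The seven amoA-defined Nitrosopumilales subclades modelled here;
#: theta, delta and iota are the deep-sediment clades.
NP_SUBCLADES = ("alpha", "gamma", "delta", "theta", "iota", "eta", "epsilon")

HABITAT_FLAGS = frozenset({"marine_sediment", "deep_ocean", "terrestrial", "pelagic"})

_PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")
_NUC_LETTERS = set("ACGTN")

_GENOME_TOKEN = re.compile(r"genome=(\S+)")


class FastaParseError(ValueError):
    """Raised when a FASTA file violates basic syntax."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with its provenance.

    ``residues`` are always uppercase; the alphabet is 20 amino acids plus X
    for proteins and ACGTN for nucleotides.
    """

    seq_id: str
    residues: str
    description: str = ""
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.seq_id}: residues must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeEntry:
    """A genome/MAG with clade placement, habitat and quality metadata.

    ``subclade`` is non-empty exactly for Nitrosopumilales (NP) genomes.
    ``completeness`` / ``contamination`` are percentages as estimated by an
    external quality audit (e.g. CheckM); they are consumed, never computed.
    """

    genome_id: str
    order: str
    subclade: str = ""
    habitat_flags: frozenset[str] = frozenset()
    completeness: float | None = None
    contamination: float | None = None

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValueError(f"{self.genome_id}: unknown order {self.order!r}")
        if (self.order == "NP") != bool(self.subclade):
            raise ValueError(
                f"{self.genome_id}: subclade must be set iff order is NP "
                f"(order={self.order!r}, subclade={self.subclade!r})"
            )
        bad = set(self.habitat_flags) - HABITAT_FLAGS
        if bad:
            raise ValueError(f"{self.genome_id}: unknown habitat flags {sorted(bad)}")
        if self.completeness is not None and not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.genome_id}: completeness out of [0,100]")
        if self.contamination is not None and self.contamination < 0:
            raise ValueError(f"{self.genome_id}: contamination must be >= 0")

    @property
    def clade(self) -> str:
        """Clade label used in queries: ``NP-theta`` for NP, else the order."""
        return f"NP-{self.subclade}" if self.order == "NP" else self.order


def _normalize(residues: str, alphabet: str, seq_id: str, line_no: int, permissive: bool) -> str:
    seq = residues.upper()
    letters = _PROTEIN_LETTERS if alphabet == "protein" else _NUC_LETTERS
    if set(seq) <= letters:
        return seq
    if not permissive:
        bad = sorted(set(seq) - letters)
        raise FastaParseError(
            f"illegal residues {bad} in record {seq_id!r} near line {line_no}"
        )
    wildcard = "X" if alphabet == "protein" else "N"
    return "".join(c if c in letters else wildcard for c in seq)


def read_fasta(
    path: str | Path,
    alphabet: str = "protein",
    genome_id: str | None = None,
    permissive: bool = True,
) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    alphabet:
        ``"protein"`` or ``"nucleotide"``; controls residue validation.
    genome_id:
        Genome to attribute records to. Defaults to the file stem; a
        ``genome=<id>`` token in a record's description overrides it.
    permissive:
        Map non-standard letters to X (protein) / N (nucleotide) instead of
        raising.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    default_genome = genome_id if genome_id is not None else path.stem
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: tuple[str, str, int] | None = None  # (seq_id, description, line_no)
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq_id, desc, line_no = header
        if not chunks:
            raise FastaParseError(f"record {seq_id!r} at line {line_no} has no sequence")
        m = _GENOME_TOKEN.search(desc)
        gid = m.group(1) if m else default_genome
        residues = _normalize("".join(chunks), alphabet, seq_id, line_no, permissive)
        records.append(SequenceRecord(seq_id, residues, desc, gid))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                body = line[1:].strip()
                if not body:
                    raise FastaParseError(f"malformed FASTA header at line {line_no}")
                parts = body.split(None, 1)
                seq_id = parts[0]
                if seq_id in seen:
                    raise FastaParseError(f"duplicate seq_id {seq_id!r} at line {line_no}")
                seen.add(seq_id)
                header = (seq_id, parts[1] if len(parts) > 1 else "", line_no)
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"sequence data before first header at line {line_no}")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; deterministic, lines <= ``width``."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.seq_id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _parse_optional(value: object) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan", "-"):
        return None
    return float(s)


def read_metadata(path: str | Path) -> list[GenomeEntry]:
    """Read the genome metadata TSV.

    Required columns: ``genome_id``, ``order``, ``subclade``,
    ``habitat_flags`` (semicolon-separated), ``completeness``,
    ``contamination``. Missing completeness/contamination are allowed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["genome_id", "order", "subclade", "habitat_flags", "completeness", "contamination"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    entries: list[GenomeEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gid = str(row["genome_id"]).strip()
        if gid in seen:
            raise ValueError(f"duplicate genome_id {gid!r} in metadata")
        seen.add(gid)
        sub = row["subclade"]
        sub = "" if (pd.isna(sub) or str(sub).strip() in ("", "-", "NA")) else str(sub).strip()
        flags_raw = row["habitat_flags"]
        flags = (
            frozenset(f for f in str(flags_raw).split(";") if f)
            if not pd.isna(flags_raw)
            else frozenset()
        )
        entries.append(
            GenomeEntry(
                genome_id=gid,
                order=str(row["order"]).strip(),
                subclade=sub,
                habitat_flags=flags,
                completeness=_parse_optional(row["completeness"]),
                contamination=_parse_optional(row["contamination"]),
            )
        )
    return entries


def write_metadata(entries: Iterable[GenomeEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "genome_id": e.genome_id,
                "order": e.order,
                "subclade": e.subclade,
                "habitat_flags": ";".join(sorted(e.habitat_flags)),
                "completeness": "" if e.completeness is None else e.completeness,
                "contamination": "" if e.contamination is None else e.contamination,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a per-protein annotation TSV (columns ``protein_id``, ``label``).

    Returns protein_id -> set of labels; proteins may carry several labels
    (one row each) and unannotated proteins are simply absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "protein_id" not in df.columns or "label" not in df.columns:
        raise ValueError("annotation table needs columns protein_id, label")
    labels: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        if pd.isna(row["label"]):
            continue
        labels.setdefault(str(row["protein_id"]), set()).add(str(row["label"]))
    return labels
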