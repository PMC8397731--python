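"""Single-copy marker selection and concatenated supermatrix assembly.

Markers are the widespread, essentially single-copy protein families of
the presence/absence matrix (the analog of selecting families present in
at least 70 of 85 genomes for a phylogenomic tree). The module consumes
*pre-aligned* per-marker FASTA blocks — multiple alignment itself is
delegated to external tools (or to the synthetic generator, whose
substitution-only families are born aligned) — trims alignment columns by
gap fraction, and concatenates the blocks into a supermatrix with
RAxML-style partition coordinates. Gap-fraction trimming is a simple
stand-in for entropy-based trimmers, so site counts are not comparable
with those tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .formats import SequenceRecord
from .pangenome import PresenceAbsenceMatrix

__all__ = [
    "MarkerSelectionParams",
    "Supermatrix",
    "select_markers",
    "resolve_paralogs",
    "trim_alignment",
    "build_supermatrix",
]

GAP = "-"


@dataclass(frozen=True)
class MarkerSelectionParams:
    """Marker selection and supermatrix construction knobs.

    ``min_genomes``: a family qualifies if present in at least this many
    genomes. ``max_multicopy_fraction``: among the genomes carrying the
    family, at most this fraction may carry it in >= 2 copies.
    ``trim_gap_fraction``: columns with gap fraction strictly greater than
    this are removed.
    """

    min_genomes: int
    max_multicopy_fraction: float = 0.05
    paralog_resolution: str = "keep_longest"  # or "drop_genome"
    trim_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_genomes < 1:
            raise ValueError("min_genomes must be >= 1")
        if self.paralog_resolution not in ("keep_longest", "drop_genome"):
            raise ValueError(f"unknown paralog_resolution {self.paralog_resolution!r}")
        if not 0 <= self.max_multicopy_fraction <= 1:
            raise ValueError("max_multicopy_fraction must be in [0,1]")
        if not 0 <= self.trim_gap_fraction <= 1:
            raise ValueError("trim_gap_fraction must be in [0,1]")


@dataclass
class Supermatrix:
    """Concatenated, trimmed marker alignment across genomes.

    ``blocks`` holds per-marker 1-based inclusive [start, end] coordinates;
    genomes missing a marker are padded with gap characters, so every row
    has the same length (== ``width``).
    """

    genomes: list[str]
    rows: dict[str, str]
    blocks: list[tuple[str, int, int]]  # (family_id, start, end)
    width: int

    def __post_init__(self) -> None:
        assert all(len(r) == self.width for r in self.rows.values()), "ragged rows"
        assert self.width == sum(e - s + 1 for _, s, e in self.blocks), "width mismatch"

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        from .formats import write_fasta

        recs = [SequenceRecord(g, self.rows[g] or GAP) for g in self.genomes]
        write_fasta(recs, path, width=width)

    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP (name, space, full row)."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.genomes)} {self.width}\n")
            for g in self.genomes:
                fh.write(f"{g}  {self.rows[g]}\n")

    def write_partitions(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for fam, start, end in self.blocks:
                fh.write(f"MARKER_{fam} = {start}-{end}\n")


def select_markers(
    matrix: PresenceAbsenceMatrix, params: MarkerSelectionParams
) -> list[str]:
    """Select widespread single-copy families as phylogenomic markers.

    Returns family_ids ordered by descending genome count, then family_id.
    """
    if params.min_genomes > len(matrix.genomes):
        raise ValueError(
            f"min_genomes={params.min_genomes} exceeds genome count {len(matrix.genomes)}"
        )
    pres = matrix.presence
    n_present = pres.sum(axis=1)
    multicopy = (matrix.counts >= 2).sum(axis=1)
    selected = []
    for fam in matrix.families:
        n = int(n_present[fam])
        if n < params.min_genomes:
            continue
        if n and multicopy[fam] / n > params.max_multicopy_fraction:
            continue
        selected.append((fam, n))
    selected.sort(key=lambda t: (-t[1], t[0]))
    return [fam for fam, _ in selected]


def resolve_paralogs(
    records: Sequence[SequenceRecord], mode: str = "keep_longest"
) -> list[SequenceRecord]:
    """Reduce a marker family to at most one sequence per genome.

    ``keep_longest`` keeps the longest sequence per genome (ties by
    smallest seq_id); ``drop_genome`` removes genomes with > 1 copy.
    """
    by_genome: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_genome.setdefault(r.genome_id, []).append(r)
    out: list[SequenceRecord] = []
    for gid, recs in by_genome.items():
        if len(recs) == 1:
            out.append(recs[0])
        elif mode == "keep_longest":
            out.append(min(recs, key=lambda r: (-len(r.residues), r.seq_id)))
        elif mode == "drop_genome":
            continue
        else:
            raise ValueError(f"unknown paralog resolution mode {mode!r}")
    return out


def trim_alignment(rows: Sequence[str], max_gap_fraction: float) -> tuple[list[str], list[int]]:
    """Remove columns whose gap fraction is strictly greater than the
    threshold. Returns (trimmed rows, retained 0-based column indices)."""
    if not rows:
        return [], []
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    n = len(rows)
    keep = [
        j
        for j in range(width)
        if sum(1 for r in rows if r[j] == GAP) / n <= max_gap_fraction
    ]
    return ["".join(r[j] for j in keep) for r in rows], keep


def build_supermatrix(
    marker_alignments: Mapping[str, Sequence[SequenceRecord]],
    genomes: Sequence[str],
    params: MarkerSelectionParams,
) -> Supermatrix:
    """Trim and concatenate per-marker alignments into a supermatrix.

    ``marker_alignments`` maps family_id -> aligned records (equal-length
    rows, at most one per genome — apply :func:`resolve_paralogs` first).
    Markers are concatenated in the mapping's iteration order; genomes
    missing a marker get a gap block.
    """
    genomes = list(genomes)
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for fam_id, records in marker_alignments.items():
        seen: set[str] = set()
        for r in records:
            if r.genome_id in seen:
                raise ValueError(f"marker {fam_id}: duplicate genome {r.genome_id}")
            seen.add(r.genome_id)
        rows = [r.residues for r in records]
        trimmed, _ = trim_alignment(rows, params.trim_gap_fraction)
        w = len(trimmed[0]) if trimmed else 0
        if w == 0:
            continue  # marker fully trimmed away
        by_genome = {r.genome_id: t for r, t in zip(records, trimmed)}
        for g in genomes:
            parts[g].append(by_genome.get(g, GAP * w))
        blocks.append((fam_id, pos + 1, pos + w))
        pos += w
    return Supermatrix(
        genomes=genomes,
        rows={g: "".join(parts[g]) for g in genomes},
        blocks=blocks,
        width=pos,
    )
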