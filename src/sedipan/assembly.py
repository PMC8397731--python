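"""Per-assembly statistics and MAG quality tiers.

Computes contig counts, total size, longest contig, N50 and GC from
nucleotide FASTA; summarizes tables of such statistics (means, sample
standard deviations, threshold counts); and classifies MAG quality from
externally estimated completeness/contamination percentages.

N50 is the length of the contig at which the cumulative sum of
descending-sorted contig lengths first reaches half the assembly size.
GC is computed over unambiguous bases only (Ns excluded from numerator
and denominator).

The packaged reference table (:func:`load_reference_mag_table`) holds the
published statistics of the 11 deep-sea sediment AOA MAGs this analysis
is modelled on; it is used for worked examples and desk-scale checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .formats import SequenceRecord

__all__ = [
    "AssemblyStats",
    "QualityThresholds",
    "contig_stats",
    "summarize_mag_table",
    "count_in_range",
    "classify_quality",
    "load_reference_mag_table",
]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    longest_bp: int
    n50_bp: int
    gc_percent: float

    def __post_init__(self) -> None:
        assert self.longest_bp <= self.total_bp
        assert self.n50_bp <= self.longest_bp
        assert 0.0 <= self.gc_percent <= 100.0


@dataclass(frozen=True)
class QualityThresholds:
    """MAG quality tier thresholds (percent).

    ``hq_max_contamination`` defaults to 5.5 so that an "about 5% or below"
    rule admits bins reported at 5.3-5.4% contamination.
    """

    hq_min_completeness: float = 80.0  # strict >
    hq_max_contamination: float = 5.5  # inclusive <=
    vq_min_completeness: float = 90.0  # strict >

    def __post_init__(self) -> None:
        if self.vq_min_completeness < self.hq_min_completeness:
            raise ValueError("very-high threshold must be >= high threshold")


def contig_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    """Compute assembly statistics from nucleotide contigs."""
    if not records:
        raise ValueError("empty assembly")
    lengths = sorted((len(r.residues) for r in records), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[-1]
    for L in lengths:
        cum += L
        if cum >= half:
            n50 = L
            break
    gc = at = 0
    for r in records:
        s = r.residues
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else 0.0
    return AssemblyStats(
        n_contigs=len(records),
        total_bp=total,
        longest_bp=lengths[0],
        n50_bp=n50,
        gc_percent=gc_percent,
    )


def summarize_mag_table(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-column mean, sample SD (n-1), min and max of numeric columns.

    Non-numeric cells in a requested column raise; ``NaN`` marks a missing
    value and is excluded column-wise.
    """
    if table.empty:
        raise ValueError("empty table")
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = {}
    for col in columns:
        series = pd.to_numeric(table[col], errors="raise").dropna()
        n = len(series)
        rows[col] = {
            "n": n,
            "mean": series.mean(),
            "sd": series.std(ddof=1) if n > 1 else 0.0,
            "min": series.min(),
            "max": series.max(),
        }
    return pd.DataFrame(rows).T


def count_in_range(
    table: pd.DataFrame,
    column: str,
    low: float | None = None,
    high: float | None = None,
    low_strict: bool = True,
    high_strict: bool = False,
) -> int:
    """Count rows with ``column`` in the given (half-)open interval.

    Defaults give the usual "strictly greater than low, at most high"
    reading, e.g. completeness in (80, 90].
    """
    series = pd.to_numeric(table[column], errors="raise").dropna()
    mask = pd.Series(True, index=series.index)
    if low is not None:
        mask &= series > low if low_strict else series >= low
    if high is not None:
        mask &= series < high if high_strict else series <= high
    return int(mask.sum())


def classify_quality(
    completeness: float,
    contamination: float,
    thresholds: QualityThresholds = QualityThresholds(),
) -> str:
    """Classify a MAG into very_high / high / medium / low quality.

    very_high: completeness > 90 and contamination <= 5.5 (defaults);
    high: completeness > 80 and contamination <= 5.5; medium:
    completeness >= 50; else low. Thresholds are configurable.
    """
    if completeness < 0 or contamination < 0:
        raise ValueError("completeness and contamination must be >= 0")
    if completeness > 100:
        raise ValueError("completeness must be <= 100")
    t = thresholds
    if completeness > t.vq_min_completeness and contamination <= t.hq_max_contamination:
        return "very_high"
    if completeness > t.hq_min_completeness and contamination <= t.hq_max_contamination:
        return "high"
    if completeness >= 50:
        return "medium"
    return "low"


def load_reference_mag_table() -> pd.DataFrame:
    """Published statistics of the 11 deep-sea sediment AOA MAGs.

    Columns mirror a typical MAG statistics table: contigs, genome size,
    protein count, longest contig, N50, GC%, completeness% and
    contamination%, with the MAG's NP subclade.
    """
    with resources.files("sedipan.data").joinpath("deep_sea_aoa_mags.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
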