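"""Presence/absence matrix and clade-quantified pangenome partitions.

The family-by-genome count matrix produced by clustering is the substrate
for all set-algebra questions of a clade-aware pangenome analysis:
which families form the core proteome of the four AOA orders, which are
specific to one order, which are shared only by the deep-sediment clades,
and so on. Queries are expressed as small expression trees over three
atoms (:class:`PresentIn`, :class:`PresentFraction`, :class:`AbsentIn`)
combined with AND/OR/NOT, and evaluated with exact set semantics.

Clade labels accepted everywhere: ``ALL``, an order name (``NC``, ``NS``,
``NT``, ``NP``, ``OUTGROUP``) or an NP subclade as ``NP-<subclade>``
(e.g. ``NP-theta``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ProteinFamily
from .formats import GenomeEntry, NP_SUBCLADES, ORDERS

__all__ = [
    "PresenceAbsenceMatrix",
    "build_matrix",
    "CladeQuery",
    "PresentIn",
    "PresentFraction",
    "AbsentIn",
    "And",
    "Or",
    "Not",
    "evaluate_query",
    "PartitionReport",
    "standard_partitions",
    "propagate_annotations",
    "order_families_for_display",
    "SEDIMENT_CLADES",
]

#: The three deep-sediment NP subclades of this analysis.
SEDIMENT_CLADES = ("NP-theta", "NP-delta", "NP-iota")


@dataclass
class PresenceAbsenceMatrix:
    """Family x genome copy-count matrix with attached genome metadata.

    ``counts`` has family_ids as index and genome_ids as columns; presence
    means count >= 1 (no copy-number weighting in any partition).
    """

    counts: pd.DataFrame
    entries: dict[str, GenomeEntry]

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    def genomes_of_clade(self, clade: str) -> list[str]:
        """Resolve a clade label to the genome ids it contains."""
        if clade == "ALL":
            return self.genomes
        if clade in ORDERS:
            return [g for g in self.genomes if self.entries[g].order == clade]
        if clade.startswith("NP-"):
            sub = clade[3:]
            if sub not in NP_SUBCLADES:
                raise KeyError(f"unknown NP subclade {sub!r}")
            return [
                g
                for g in self.genomes
                if self.entries[g].order == "NP" and self.entries[g].subclade == sub
            ]
        raise KeyError(f"unknown clade {clade!r}")

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family_id")

    def to_triplets(self, path: str | Path) -> None:
        """Sparse triplet export: family_id, genome_id, count (count > 0)."""
        with open(path, "w") as fh:
            fh.write("family_id\tgenome_id\tcount\n")
            arr = self.counts.to_numpy()
            fams, gens = self.families, self.genomes
            for i, j in zip(*np.nonzero(arr)):
                fh.write(f"{fams[i]}\t{gens[j]}\t{arr[i, j]}\n")


def build_matrix(
    families: Sequence[ProteinFamily], metadata: Sequence[GenomeEntry]
) -> PresenceAbsenceMatrix:
    """Count members of each family per genome.

    Every member's genome must appear in the metadata; genomes without any
    member still get an (all-zero) column.
    """
    entries = {e.genome_id: e for e in metadata}
    genome_ids = [e.genome_id for e in metadata]
    fam_ids = [f.family_id for f in families]
    counts = pd.DataFrame(
        0, index=pd.Index(fam_ids, name="family_id"), columns=genome_ids, dtype=int
    )
    for fam in families:
        for m in fam.members:
            if m.genome_id not in entries:
                raise KeyError(
                    f"genome {m.genome_id!r} (member {m.seq_id!r}) missing from metadata"
                )
            counts.loc[fam.family_id, m.genome_id] += 1
    return PresenceAbsenceMatrix(counts=counts, entries=entries)


# ---------------------------------------------------------------------------
# clade queries


class CladeQuery:
    """Base class of the query expression tree."""

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        raise NotImplementedError


def _nonempty(matrix: PresenceAbsenceMatrix) -> set[str]:
    pres = matrix.presence
    return set(pres.index[pres.any(axis=1)])


@dataclass(frozen=True)
class PresentIn(CladeQuery):
    """Families present (count >= 1) in at least ``min_genomes`` genomes of
    the clade."""

    clade: str
    min_genomes: int = 1

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        if self.min_genomes < 1:
            raise ValueError("min_genomes must be >= 1")
        cols = matrix.genomes_of_clade(self.clade)
        if not cols:
            return set()
        pres = matrix.presence[cols].sum(axis=1)
        return set(pres.index[pres >= self.min_genomes])


@dataclass(frozen=True)
class PresentFraction(CladeQuery):
    """Families present in >= (or, with ``strict``, >) ``min_fraction`` of
    the clade's genomes; ``strict=True`` encodes rules like '>50% of the
    genomes'."""

    clade: str
    min_fraction: float
    strict: bool = False

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        cols = matrix.genomes_of_clade(self.clade)
        if not cols:
            return set()
        frac = matrix.presence[cols].sum(axis=1) / len(cols)
        keep = frac > self.min_fraction if self.strict else frac >= self.min_fraction
        return set(frac.index[keep])


@dataclass(frozen=True)
class AbsentIn(CladeQuery):
    """Families absent from every genome of the clade."""

    clade: str

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        cols = matrix.genomes_of_clade(self.clade)
        if not cols:
            return _nonempty(matrix)
        pres = matrix.presence[cols].any(axis=1)
        return set(pres.index[~pres]) & _nonempty(matrix)


@dataclass(frozen=True)
class And(CladeQuery):
    parts: tuple[CladeQuery, ...]

    def __init__(self, *parts: CladeQuery):
        object.__setattr__(self, "parts", tuple(parts))

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        result = self.parts[0].evaluate(matrix)
        for p in self.parts[1:]:
            result &= p.evaluate(matrix)
        return result


@dataclass(frozen=True)
class Or(CladeQuery):
    parts: tuple[CladeQuery, ...]

    def __init__(self, *parts: CladeQuery):
        object.__setattr__(self, "parts", tuple(parts))

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        result: set[str] = set()
        for p in self.parts:
            result |= p.evaluate(matrix)
        return result


@dataclass(frozen=True)
class Not(CladeQuery):
    """Complement within the non-empty families of the matrix."""

    part: CladeQuery

    def evaluate(self, matrix: PresenceAbsenceMatrix) -> set[str]:
        return _nonempty(matrix) - self.part.evaluate(matrix)


def evaluate_query(matrix: PresenceAbsenceMatrix, query: CladeQuery) -> set[str]:
    """Evaluate a query tree to the set of matching family_ids."""
    return query.evaluate(matrix)


# ---------------------------------------------------------------------------
# the named partitions


@dataclass
class PartitionReport:
    """The nine named family sets of the clade-aware pangenome partition.

    Operationalizations (presence always means count >= 1):

    - ``shared2``: present in >= 2 genomes.
    - ``core_aoa``: >= 1 genome of each of the four AOA orders.
    - ``aoa_specific``: core_aoa and absent from all OUTGROUP genomes.
    - ``conserved_core``: aoa_specific and present in > 50% of the genomes
      of each order.
    - ``np_specific``: >= 2 genomes, all presences within NP.
    - ``np_all_subclades``: np_specific and >= 1 genome of each of the
      seven NP subclades.
    - ``sediment_specific``: >= 1 genome in each of >= 2 sediment clades
      and absent from every genome outside the sediment clades.
    - ``deep_ocean_shared``: >= 1 genome in each of >= 2 deep clades and
      absent from all non-deep NP subclades (presence outside NP is
      unconstrained).
    - ``sediment_ns_shared``: >= 1 sediment-clade genome and >= 1 NS genome,
      absent from all other genomes.
    """

    shared2: set[str]
    core_aoa: set[str]
    aoa_specific: set[str]
    conserved_core: set[str]
    np_specific: set[str]
    np_all_subclades: set[str]
    sediment_specific: set[str]
    deep_ocean_shared: set[str]
    sediment_ns_shared: set[str]
    parameters: dict = field(default_factory=dict)

    _SET_NAMES = (
        "shared2",
        "core_aoa",
        "aoa_specific",
        "conserved_core",
        "np_specific",
        "np_all_subclades",
        "sediment_specific",
        "deep_ocean_shared",
        "sediment_ns_shared",
    )

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in self._SET_NAMES}

    def check_nesting(self) -> None:
        """Assert the structural subset relations among the sets."""
        assert self.conserved_core <= self.aoa_specific <= self.core_aoa
        assert self.sediment_specific <= self.np_specific
        assert self.np_all_subclades <= self.np_specific
        for name in ("core_aoa", "np_specific", "sediment_specific", "deep_ocean_shared", "sediment_ns_shared"):
            assert getattr(self, name) <= self.shared2, name

    def to_json(self, path: str | Path) -> None:
        payload = {
            "parameters": self.parameters,
            "counts": self.counts(),
            "sets": {name: sorted(getattr(self, name)) for name in self._SET_NAMES},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def standard_partitions(
    matrix: PresenceAbsenceMatrix,
    sediment_clades: Sequence[str] = SEDIMENT_CLADES,
    deep_clades: Sequence[str] = (),
    min_sediment_clades: int = 2,
    min_deep_clades: int = 2,
) -> PartitionReport:
    """Compute the named partitions of the presence/absence matrix.

    ``deep_clades`` (the NP subclades with deep-ocean representatives) must
    be supplied by the caller — they reflect sampling provenance that cannot
    be inferred from the matrix. With an empty ``deep_clades`` the
    deep_ocean_shared set is empty.
    """
    for order in ("NC", "NS", "NT", "NP"):
        if not matrix.genomes_of_clade(order):
            raise ValueError(f"taxonomy has no genomes of order {order}")

    pres = matrix.presence
    nonempty = _nonempty(matrix)
    shared2 = set(pres.index[pres.sum(axis=1) >= 2])

    orders4 = ("NC", "NS", "NT", "NP")
    core_aoa = And(*(PresentIn(o, 1) for o in orders4)).evaluate(matrix)

    outgroup = matrix.genomes_of_clade("OUTGROUP")
    aoa_specific = core_aoa & AbsentIn("OUTGROUP").evaluate(matrix) if outgroup else set(core_aoa)

    conserved_core = aoa_specific & And(
        *(PresentFraction(o, 0.5, strict=True) for o in orders4)
    ).evaluate(matrix)

    np_genomes = matrix.genomes_of_clade("NP")
    non_np = [g for g in matrix.genomes if g not in set(np_genomes)]
    in_np = pres[np_genomes].sum(axis=1)
    out_np_any = pres[non_np].any(axis=1) if non_np else pd.Series(False, index=pres.index)
    np_specific = set(pres.index[(in_np >= 2) & ~out_np_any])

    np_all = np_specific & And(
        *(PresentIn(f"NP-{s}", 1) for s in NP_SUBCLADES)
    ).evaluate(matrix)

    def clade_hits(fid_pres: pd.DataFrame, clades: Sequence[str]) -> pd.Series:
        hits = pd.Series(0, index=fid_pres.index)
        for c in clades:
            cols = matrix.genomes_of_clade(c)
            if cols:
                hits += fid_pres[cols].any(axis=1).astype(int)
        return hits

    sed_hits = clade_hits(pres, sediment_clades)
    sed_genomes: set[str] = set()
    for c in sediment_clades:
        sed_genomes.update(matrix.genomes_of_clade(c))
    outside_sed = [g for g in matrix.genomes if g not in sed_genomes]
    out_sed_any = pres[outside_sed].any(axis=1) if outside_sed else pd.Series(False, index=pres.index)
    sediment_specific = set(pres.index[(sed_hits >= min_sediment_clades) & ~out_sed_any])

    if deep_clades:
        deep_hits = clade_hits(pres, deep_clades)
        deep_np: set[str] = set()
        for c in deep_clades:
            deep_np.update(matrix.genomes_of_clade(c))
        non_deep_np = [g for g in np_genomes if g not in deep_np]
        nd_any = pres[non_deep_np].any(axis=1) if non_deep_np else pd.Series(False, index=pres.index)
        deep_ocean_shared = set(pres.index[(deep_hits >= min_deep_clades) & ~nd_any])
    else:
        deep_ocean_shared = set()

    ns_genomes = matrix.genomes_of_clade("NS")
    others = [g for g in matrix.genomes if g not in sed_genomes and g not in set(ns_genomes)]
    other_any = pres[others].any(axis=1) if others else pd.Series(False, index=pres.index)
    sed_any = pres[sorted(sed_genomes)].any(axis=1) if sed_genomes else pd.Series(False, index=pres.index)
    ns_any = pres[ns_genomes].any(axis=1) if ns_genomes else pd.Series(False, index=pres.index)
    sediment_ns_shared = set(pres.index[sed_any & ns_any & ~other_any])

    report = PartitionReport(
        shared2=shared2 & nonempty,
        core_aoa=core_aoa,
        aoa_specific=aoa_specific,
        conserved_core=conserved_core,
        np_specific=np_specific,
        np_all_subclades=np_all,
        sediment_specific=sediment_specific,
        deep_ocean_shared=deep_ocean_shared,
        sediment_ns_shared=sediment_ns_shared,
        parameters={
            "sediment_clades": list(sediment_clades),
            "deep_clades": list(deep_clades),
            "min_sediment_clades": min_sediment_clades,
            "min_deep_clades": min_deep_clades,
            "deep_rule": "presence in >= min_deep_clades deep clades, absent from non-deep NP subclades",
        },
    )
    report.check_nesting()
    return report


def propagate_annotations(
    families: Sequence[ProteinFamily], labels: Mapping[str, set[str] | str]
) -> dict[str, tuple[set[str], bool]]:
    """Lift per-protein labels to families.

    A family is annotated iff at least one member carries a label; the
    family label set is the union of member labels.
    """
    out: dict[str, tuple[set[str], bool]] = {}
    for fam in families:
        fam_labels: set[str] = set()
        for m in fam.members:
            lab = labels.get(m.seq_id)
            if lab is None:
                continue
            if isinstance(lab, str):
                fam_labels.add(lab)
            else:
                fam_labels.update(lab)
        out[fam.family_id] = (fam_labels, bool(fam_labels))
    return out


def annotated_fraction(
    annotations: Mapping[str, tuple[set[str], bool]], family_set: Iterable[str]
) -> float:
    """Fraction of a family set that is annotated (0.0 on an empty set)."""
    fams = list(family_set)
    if not fams:
        return 0.0
    hits = sum(1 for f in fams if annotations.get(f, (set(), False))[1])
    return hits / len(fams)


def order_families_for_display(matrix: PresenceAbsenceMatrix) -> list[str]:
    """Order families from most widespread to most uncommon.

    Primary key: number of AOA orders (lineages) with presence (descending);
    secondary: number of genomes with presence (descending); tertiary:
    family_id (ascending).
    """
    pres = matrix.presence
    order_cols = {
        o: matrix.genomes_of_clade(o)
        for o in ("NC", "NS", "NT", "NP")
        if matrix.genomes_of_clade(o)
    }
    n_orders = pd.Series(0, index=pres.index)
    for cols in order_cols.values():
        n_orders += pres[cols].any(axis=1).astype(int)
    n_genomes = pres.sum(axis=1)
    key = pd.DataFrame({"norders": -n_orders, "ngenomes": -n_genomes, "fid": pres.index}, index=pres.index)
    return list(key.sort_values(["norders", "ngenomes", "fid"]).index)
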