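"""Synthetic genome collections with planted protein-family structure.

The generator emulates the statistical structure a clade-aware pangenome
analysis assumes: a four-order clade hierarchy (NC, NS, NT, NP, plus an
outgroup) with seven NP subclades, and planted protein families of known
category — core (one per AOA order at least), order-specific,
subclade-specific, sediment-specific (shared by >= 2 of the three
deep-sediment NP subclades to the exclusion of everything else),
deep-shared (shared by deep-ocean NP subclades only), singletons, and
contaminant families placed into a foreign genome. Genome incompleteness
is modelled as per-(family, genome) dropout.

Sequence evolution is substitution-only: each family has an i.i.d.
ancestor and one fixed alternate residue per position; a member genome's
copy substitutes each position with probability ``s`` where
``(1-s)^2 + s^2 = within_family_identity``, so the *pairwise* identity
between any two members is calibrated to the requested value (this
two-state scheme needs a target >= 0.5; below that, copies are mutated
away from the ancestor at rate ``1 - target`` and only the identity to
the ancestor is calibrated). In separable mode, ancestors are rejection
sampled until no cross-family pair exceeds ``cross_family_max_identity``
as measured by the package's own aligner.

Every generated protein appears in exactly one truth family; the
:class:`TruthTable` is the ground truth each downstream stage is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .align import global_align
from .formats import (
    GenomeEntry,
    NP_SUBCLADES,
    SequenceRecord,
    write_fasta,
    write_metadata,
)

__all__ = [
    "SyntheticBlueprint",
    "TruthTable",
    "default_taxonomy",
    "default_blueprint",
    "generate_collection",
    "generate_genome_pair",
    "write_collection",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_SEDIMENT_SUBCLADES = ("theta", "delta", "iota")


@dataclass(frozen=True)
class SyntheticBlueprint:
    """Planted family structure and evolutionary knobs of a collection.

    Counts are per category: ``n_core`` families span all four AOA orders;
    ``n_order_specific`` maps order -> number of families confined to it;
    ``n_subclade_specific`` maps NP subclade -> families confined to that
    subclade; ``n_sediment_specific`` families are shared by >= 2 sediment
    subclades only; ``n_deep_shared`` families are shared by the
    ``deep_subclades`` only; singletons sit in one genome each.
    ``contaminant_rate`` is the expected number of contaminant families per
    genome (each planted as a single foreign protein).
    """

    taxonomy: tuple[GenomeEntry, ...]
    n_core: int = 40
    n_order_specific: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 5, "NS": 5, "NT": 5, "NP": 5}
    )
    n_subclade_specific: Mapping[str, int] = field(
        default_factory=lambda: {
            "alpha": 2, "gamma": 2, "delta": 2, "theta": 3, "iota": 2, "eta": 2, "epsilon": 2,
        }
    )
    n_sediment_specific: int = 8
    n_deep_shared: int = 5
    n_singletons: int = 30
    sediment_subclades: tuple[str, ...] = _SEDIMENT_SUBCLADES
    deep_subclades: tuple[str, ...] = ("alpha", "gamma")
    family_length_range: tuple[int, int] = (80, 240)
    within_family_identity: float = 0.60
    cross_family_max_identity: float = 0.28
    dropout_prob: float = 0.0
    contaminant_rate: float = 0.0
    separable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_core, self.n_sediment_specific, self.n_deep_shared, self.n_singletons]
        counts += list(self.n_order_specific.values()) + list(self.n_subclade_specific.values())
        if any(c < 0 for c in counts):
            raise ValueError("family counts must be >= 0")
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0, 1]")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.separable and (
            self.within_family_identity - self.cross_family_max_identity < 0.15
        ):
            raise ValueError(
                "separable mode needs within_family_identity - "
                "cross_family_max_identity >= 0.15"
            )
        if self.family_length_range[0] < 10 or self.family_length_range[0] > self.family_length_range[1]:
            raise ValueError("bad family_length_range")


@dataclass
class TruthTable:
    """Ground truth of a generated collection.

    ``categories`` maps family_id to its planted category label
    (``core``, ``order_specific:<o>``, ``subclade_specific:<s>``,
    ``sediment_specific``, ``deep_shared``, ``singleton``,
    ``contaminant``); ``members`` maps family_id to realized
    (protein_id, genome_id) pairs after dropout.
    """

    categories: dict[str, str]
    members: dict[str, list[tuple[str, str]]]

    def partition(self) -> set[frozenset[str]]:
        """The truth partition of protein ids into families."""
        return {frozenset(pid for pid, _ in mem) for mem in self.members.values() if mem}

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fid, cat in self.categories.items():
            if self.members.get(fid):
                counts[cat] = counts.get(cat, 0) + 1
        return counts

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tcategory\tprotein_id\tgenome_id\n")
            for fid in sorted(self.members):
                for pid, gid in self.members[fid]:
                    fh.write(f"{fid}\t{self.categories[fid]}\t{pid}\t{gid}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        categories: dict[str, str] = {}
        members: dict[str, list[tuple[str, str]]] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                fid, cat, pid, gid = line.rstrip("\n").split("\t")
                categories[fid] = cat
                members.setdefault(fid, []).append((pid, gid))
        return cls(categories, members)


def default_taxonomy() -> tuple[GenomeEntry, ...]:
    """A 30-genome collection: 4 NC, 5 NS, 4 NT, 14 NP (2 per subclade)
    and 3 outgroup genomes, with field-typical habitat flags."""
    entries: list[GenomeEntry] = []
    for i in range(1, 5):
        entries.append(GenomeEntry(f"NC_g{i}", "NC", habitat_flags=frozenset({"terrestrial"})))
    for i in range(1, 6):
        entries.append(GenomeEntry(f"NS_g{i}", "NS", habitat_flags=frozenset({"terrestrial"})))
    for i in range(1, 5):
        entries.append(GenomeEntry(f"NT_g{i}", "NT", habitat_flags=frozenset({"terrestrial"})))
    flags = {
        "alpha": "deep_ocean",
        "gamma": "deep_ocean",
        "delta": "marine_sediment",
        "theta": "marine_sediment",
        "iota": "marine_sediment",
        "eta": "pelagic",
        "epsilon": "pelagic",
    }
    for sub in NP_SUBCLADES:
        for i in range(1, 3):
            entries.append(
                GenomeEntry(
                    f"NP_{sub}_g{i}", "NP", subclade=sub, habitat_flags=frozenset({flags[sub]})
                )
            )
    for i in range(1, 4):
        entries.append(GenomeEntry(f"OUT_g{i}", "OUTGROUP"))
    return tuple(entries)


def default_blueprint(seed: int = 0, **overrides) -> SyntheticBlueprint:
    """The standard separable study blueprint (30 genomes, 123 families)."""
    return replace(SyntheticBlueprint(taxonomy=default_taxonomy(), seed=seed), **overrides)


def _plan_families(bp: SyntheticBlueprint, rng: np.random.Generator) -> list[tuple[str, list[str]]]:
    """Deterministic (category, designated genome list) plan."""
    by_order: dict[str, list[str]] = {}
    by_subclade: dict[str, list[str]] = {}
    for e in bp.taxonomy:
        by_order.setdefault(e.order, []).append(e.genome_id)
        if e.order == "NP":
            by_subclade.setdefault(e.subclade, []).append(e.genome_id)

    plan: list[tuple[str, list[str]]] = []
    aoa = [g for o in ("NC", "NS", "NT", "NP") for g in by_order.get(o, [])]
    for _ in range(bp.n_core):
        plan.append(("core", list(aoa)))
    for order, n in sorted(bp.n_order_specific.items()):
        for _ in range(n):
            plan.append((f"order_specific:{order}", list(by_order.get(order, []))))
    for sub, n in sorted(bp.n_subclade_specific.items()):
        for _ in range(n):
            plan.append((f"subclade_specific:{sub}", list(by_subclade.get(sub, []))))
    sed = list(bp.sediment_subclades)
    for i in range(bp.n_sediment_specific):
        # alternate between pairs of sediment subclades and all of them
        if i % 2 == 0 and len(sed) >= 2:
            pair = [sed[i // 2 % len(sed)], sed[(i // 2 + 1) % len(sed)]]
            genomes = [g for s in pair for g in by_subclade.get(s, [])]
        else:
            genomes = [g for s in sed for g in by_subclade.get(s, [])]
        plan.append(("sediment_specific", genomes))
    deep = list(bp.deep_subclades)
    for _ in range(bp.n_deep_shared):
        plan.append(("deep_shared", [g for s in deep for g in by_subclade.get(s, [])]))
    all_genomes = [e.genome_id for e in bp.taxonomy]
    for _ in range(bp.n_singletons):
        plan.append(("singleton", [all_genomes[rng.integers(len(all_genomes))]]))
    n_cont = int(round(bp.contaminant_rate * len(all_genomes)))
    for _ in range(n_cont):
        plan.append(("contaminant", [all_genomes[rng.integers(len(all_genomes))]]))
    return plan


def _draw_ancestor(
    rng: np.random.Generator,
    length: int,
    accepted: list[str],
    bp: SyntheticBlueprint,
) -> str:
    """Draw an ancestor; in separable mode, rejection-sample against all
    previously accepted ancestors using the pipeline's own aligner."""
    for _ in range(60):
        seq = "".join(_AA[rng.integers(0, len(_AA), size=length)])
        if not bp.separable:
            return seq
        ok = True
        for other in accepted:
            if global_align(seq, other).identity_short > bp.cross_family_max_identity:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError(
        "separable mode violated: could not draw an ancestor below "
        f"cross_family_max_identity={bp.cross_family_max_identity} in 60 tries"
    )


def generate_collection(
    bp: SyntheticBlueprint,
) -> tuple[dict[str, list[SequenceRecord]], TruthTable]:
    """Generate per-genome proteomes and the matching truth table.

    Deterministic given ``bp.seed``: calling twice yields byte-identical
    records and truth.
    """
    rng = np.random.default_rng(bp.seed)
    plan = _plan_families(bp, rng)
    ident = bp.within_family_identity
    if ident >= 0.5:
        sub_rate = (1.0 - np.sqrt(2.0 * ident - 1.0)) / 2.0
        pairwise_calibrated = True
    else:
        sub_rate = 1.0 - ident
        pairwise_calibrated = False

    proteomes: dict[str, list[SequenceRecord]] = {e.genome_id: [] for e in bp.taxonomy}
    counters: dict[str, int] = {e.genome_id: 0 for e in bp.taxonomy}
    categories: dict[str, str] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    ancestors: list[str] = []

    lo, hi = bp.family_length_range
    for i, (category, genomes) in enumerate(plan):
        fam_id = f"T{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _draw_ancestor(rng, length, ancestors, bp)
        ancestors.append(ancestor)
        anc = np.array(list(ancestor))
        # one fixed alternate residue per position (two-state model)
        shift = rng.integers(1, len(_AA), size=length)
        anc_idx = np.searchsorted(_AA, anc)
        alt = _AA[(anc_idx + shift) % len(_AA)]

        categories[fam_id] = category
        members[fam_id] = []
        for gid in genomes:
            if bp.dropout_prob > 0 and rng.random() < bp.dropout_prob:
                continue
            if pairwise_calibrated:
                mask = rng.random(length) < sub_rate
                copy = np.where(mask, alt, anc)
            else:
                mask = rng.random(length) < sub_rate
                shift2 = rng.integers(1, len(_AA), size=length)
                rand_alt = _AA[(anc_idx + shift2) % len(_AA)]
                copy = np.where(mask, rand_alt, anc)
            counters[gid] += 1
            pid = f"{gid}_p{counters[gid]:04d}"
            proteomes[gid].append(
                SequenceRecord(pid, "".join(copy), description=f"genome={gid}", genome_id=gid)
            )
            members[fam_id].append((pid, gid))

    return proteomes, TruthTable(categories, members)


def generate_genome_pair(
    length_bp: int, substitution_rate: float, seed: int
) -> tuple[SequenceRecord, SequenceRecord]:
    """A nucleotide genome and a copy with i.i.d. substitutions at the
    given per-site rate (substitution-only: lengths are always equal)."""
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    idx = rng.integers(0, 4, size=length_bp)
    mask = rng.random(length_bp) < substitution_rate
    shift = rng.integers(1, 4, size=length_bp)
    idx2 = np.where(mask, (idx + shift) % 4, idx)
    a = SequenceRecord("genomeA", "".join(bases[idx]), genome_id="genomeA")
    b = SequenceRecord("genomeB", "".join(bases[idx2]), genome_id="genomeB")
    return a, b


def write_collection(
    proteomes: Mapping[str, list[SequenceRecord]],
    truth: TruthTable,
    taxonomy: Iterable[GenomeEntry],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write per-genome protein FASTA, metadata TSV and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for gid in sorted(proteomes):
        p = outdir / f"{gid}.faa"
        write_fasta(proteomes[gid], p)
        paths[gid] = p
    meta = outdir / "metadata.tsv"
    write_metadata(taxonomy, meta)
    paths["metadata"] = meta
    tt = outdir / "truth.tsv"
    truth.to_tsv(tt)
    paths["truth"] = tt
    return paths
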