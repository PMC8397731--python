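"""End-to-end pipeline: simulate -> cluster -> matrix -> partition ->
markers -> supermatrix -> ani -> stats, driven by one YAML config.

The pipeline is deterministic under a fixed seed: re-running the same
config reproduces byte-identical outputs, which the manifest records as
sha256 checksums. Each stage is re-runnable from its serialized inputs
(FASTA/TSV/JSON on disk).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .ani import AniParams, ani_matrix
from .assembly import contig_stats
from .cluster import ClusteringParams, cluster_proteins, write_clstr, write_families_tsv
from .formats import read_fasta, read_metadata
from .markers import MarkerSelectionParams, build_supermatrix, resolve_paralogs, select_markers
from .pangenome import SEDIMENT_CLADES, build_matrix, standard_partitions
from .simulate import (
    SyntheticBlueprint,
    default_blueprint,
    generate_collection,
    generate_genome_pair,
    write_collection,
)

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Built from a YAML file with optional sections ``blueprint`` (synthetic
    input; currently the only input mode), ``clustering``, ``markers``,
    ``partition`` (sediment/deep clade lists) and ``ani`` (simulated
    genome-pair substitution rates).
    """

    outdir: Path
    seed: int = 0
    blueprint_overrides: dict[str, Any] = field(default_factory=dict)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    min_genomes_fraction: float = 70 / 85
    trim_gap_fraction: float = 0.5
    sediment_clades: tuple[str, ...] = SEDIMENT_CLADES
    deep_clades: tuple[str, ...] = ("NP-alpha", "NP-gamma")
    ani_rates: tuple[float, ...] = (0.02, 0.05, 0.10)
    ani_length_bp: int = 100_000
    input_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if "outdir" not in raw:
            raise ConfigError("config must set 'outdir'")
        clustering = ClusteringParams(**raw.get("clustering", {}))
        part = raw.get("partition", {})
        ani = raw.get("ani", {})
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            blueprint_overrides=dict(raw.get("blueprint", {})),
            clustering=clustering,
            min_genomes_fraction=float(raw.get("markers", {}).get("min_genomes_fraction", 70 / 85)),
            trim_gap_fraction=float(raw.get("markers", {}).get("trim_gap_fraction", 0.5)),
            sediment_clades=tuple(part.get("sediment_clades", SEDIMENT_CLADES)),
            deep_clades=tuple(part.get("deep_clades", ("NP-alpha", "NP-gamma"))),
            ani_rates=tuple(ani.get("rates", (0.02, 0.05, 0.10))),
            ani_length_bp=int(ani.get("length_bp", 100_000)),
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_dir is not None and not self.input_dir.exists():
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")
        if not 0 < self.min_genomes_fraction <= 1:
            raise ConfigError("min_genomes_fraction must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages in dependency order; returns (and writes) the run
    manifest with per-file sha256 checksums and per-stage counts."""
    config.validate()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }

    def record(stage: str, info: dict[str, Any], *paths: Path) -> None:
        manifest["stages"][stage] = info
        for p in paths:
            manifest["checksums"][str(p.relative_to(out))] = _sha256(p)

    # -- simulate (or load) ------------------------------------------------
    if config.input_dir is None:
        bp = default_blueprint(seed=config.seed, **config.blueprint_overrides)
        proteomes, truth = generate_collection(bp)
        taxonomy = bp.taxonomy
        sim_dir = out / "collection"
        paths = write_collection(proteomes, truth, taxonomy, sim_dir)
        record(
            "simulate",
            {"genomes": len(proteomes), "families_planted": len(truth.categories)},
            *paths.values(),
        )
    else:
        meta_path = config.input_dir / "metadata.tsv"
        if not meta_path.exists():
            raise ConfigError(f"missing metadata: {meta_path}")
        taxonomy = tuple(read_metadata(meta_path))
        proteomes = {
            e.genome_id: read_fasta(config.input_dir / f"{e.genome_id}.faa", "protein")
            for e in taxonomy
        }
        truth = None
        manifest["stages"]["load"] = {"genomes": len(proteomes)}

    records = [r for gid in sorted(proteomes) for r in proteomes[gid]]

    # -- cluster -----------------------------------------------------------
    families = cluster_proteins(records, config.clustering)
    fam_tsv = out / "families.tsv"
    write_families_tsv(families, fam_tsv)
    clstr = out / "families.clstr"
    write_clstr(families, {r.seq_id: len(r.residues) for r in records}, clstr)
    record("cluster", {"proteins": len(records), "families": len(families)}, fam_tsv, clstr)

    # -- matrix ------------------------------------------------------------
    matrix = build_matrix(families, taxonomy)
    mat_tsv = out / "matrix.tsv"
    matrix.to_tsv(mat_tsv)
    trip = out / "matrix.triplets.tsv"
    matrix.to_triplets(trip)
    record("matrix", {"families": len(matrix.families), "genomes": len(matrix.genomes)}, mat_tsv, trip)

    # -- partition ---------------------------------------------------------
    report = standard_partitions(
        matrix, sediment_clades=config.sediment_clades, deep_clades=config.deep_clades
    )
    part_json = out / "partitions.json"
    report.to_json(part_json)
    record("partition", report.counts(), part_json)

    # -- markers + supermatrix --------------------------------------------
    min_genomes = max(1, int(round(config.min_genomes_fraction * len(matrix.genomes))))
    mp = MarkerSelectionParams(min_genomes=min_genomes, trim_gap_fraction=config.trim_gap_fraction)
    marker_ids = select_markers(matrix, mp)
    by_id = {f.family_id: f for f in families}
    rec_by_id = {r.seq_id: r for r in records}
    alignments = {}
    for fid in marker_ids:
        fam_records = [rec_by_id[m.seq_id] for m in by_id[fid].members]
        fam_records = resolve_paralogs(fam_records, mp.paralog_resolution)
        widths = {len(r.residues) for r in fam_records}
        if len(widths) != 1:
            continue  # unaligned family (unequal lengths) — needs external MSA
        alignments[fid] = fam_records
    sm = build_supermatrix(alignments, [e.genome_id for e in taxonomy], mp)
    sm_fa = out / "supermatrix.fasta"
    sm.to_fasta(sm_fa)
    sm_parts = out / "supermatrix.partitions.txt"
    sm.write_partitions(sm_parts)
    record(
        "supermatrix",
        {"markers_selected": len(marker_ids), "markers_concatenated": len(sm.blocks), "width": sm.width},
        sm_fa,
        sm_parts,
    )

    # -- ani (on simulated nucleotide pairs) -------------------------------
    if config.ani_rates:
        assemblies = {}
        base_seed = (config.seed * 1000003 + 17) % (2**31)
        # same seed for every rate -> identical reference genome, mutants
        # differ only by their substitution rate
        for rate in config.ani_rates:
            a, b = generate_genome_pair(config.ani_length_bp, rate, seed=base_seed)
            assemblies.setdefault("reference", [a])
            assemblies[f"mutant_rate{rate:g}"] = [b]
        am = ani_matrix(assemblies, AniParams(seed=config.seed))
        ani_tsv = out / "ani.tsv"
        am.to_tsv(ani_tsv)
        stats = {
            gid: contig_stats(recs).total_bp for gid, recs in assemblies.items()
        }
        record("ani", {"assemblies": len(assemblies), "total_bp": stats}, ani_tsv)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
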