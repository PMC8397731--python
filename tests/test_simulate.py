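import numpy as np
import pytest

from sedipan.align import global_align
from sedipan.formats import read_fasta, read_metadata
from sedipan.simulate import (
    SyntheticBlueprint,
    TruthTable,
    default_blueprint,
    default_taxonomy,
    generate_collection,
    generate_genome_pair,
    write_collection,
)


def _small_bp(seed=3, **over):
    defaults = dict(
        n_core=4,
        n_order_specific={"NP": 2},
        n_subclade_specific={"theta": 1},
        n_sediment_specific=2,
        n_deep_shared=1,
        n_singletons=5,
        family_length_range=(80, 160),
    )
    defaults.update(over)
    return default_blueprint(seed=seed, **defaults)


def test_same_seed_reproduces_byte_identical_output():
    p1, t1 = generate_collection(_small_bp())
    p2, t2 = generate_collection(_small_bp())
    assert p1 == p2
    assert t1.categories == t2.categories and t1.members == t2.members


def test_different_seed_changes_sequences():
    p1, _ = generate_collection(_small_bp(seed=3))
    p2, _ = generate_collection(_small_bp(seed=4))
    assert p1 != p2


def test_zero_dropout_plants_every_designated_genome():
    bp = _small_bp(dropout_prob=0.0)
    _, truth = generate_collection(bp)
    core_fams = [f for f, c in truth.categories.items() if c == "core"]
    assert len(core_fams) == bp.n_core
    aoa_genomes = {e.genome_id for e in bp.taxonomy if e.order != "OUTGROUP"}
    for f in core_fams:
        assert {g for _, g in truth.members[f]} == aoa_genomes


def test_core_families_span_every_order():
    bp = _small_bp()
    _, truth = generate_collection(bp)
    entries = {e.genome_id: e for e in bp.taxonomy}
    for fid, cat in truth.categories.items():
        if cat != "core":
            continue
        orders = {entries[g].order for _, g in truth.members[fid]}
        assert {"NC", "NS", "NT", "NP"} <= orders


def test_every_protein_in_exactly_one_truth_family():
    proteomes, truth = generate_collection(_small_bp(dropout_prob=0.2, seed=9))
    generated = [r.seq_id for g in proteomes.values() for r in g]
    in_truth = [pid for mem in truth.members.values() for pid, _ in mem]
    assert sorted(generated) == sorted(in_truth)
    assert len(set(in_truth)) == len(in_truth)


def test_dropout_removes_some_presences():
    bp0 = _small_bp(dropout_prob=0.0, n_singletons=0)
    bp4 = _small_bp(dropout_prob=0.4, n_singletons=0)
    _, t0 = generate_collection(bp0)
    _, t4 = generate_collection(bp4)
    n0 = sum(len(m) for m in t0.members.values())
    n4 = sum(len(m) for m in t4.members.values())
    assert n4 < n0


def test_within_family_pairwise_identity_is_calibrated():
    """Measured by the pipeline's own aligner, pairwise identity within a
    planted family lands within +/-5 points of the requested value."""
    bp = _small_bp(seed=12, family_length_range=(120, 200), within_family_identity=0.6)
    proteomes, truth = generate_collection(bp)
    recs = {r.seq_id: r for g in proteomes.values() for r in g}
    rng = np.random.default_rng(0)
    all_idents = []
    for fid, mem in truth.members.items():
        if len(mem) < 2:
            continue
        for _ in range(min(6, len(mem) * (len(mem) - 1) // 2)):
            i, j = rng.choice(len(mem), size=2, replace=False)
            ident = global_align(recs[mem[i][0]], recs[mem[j][0]]).identity_short
            # one pair at these lengths carries ~4.5 points of binomial noise
            assert abs(ident - 0.6) <= 0.15, (fid, ident)
            all_idents.append(ident)
    assert len(all_idents) >= 20
    assert abs(float(np.mean(all_idents)) - 0.6) <= 0.02


def test_cross_family_ancestor_separation():
    bp = _small_bp(seed=21, n_singletons=8)
    proteomes, truth = generate_collection(bp)
    recs = {r.seq_id: r for g in proteomes.values() for r in g}
    reps = []
    for fid, mem in truth.members.items():
        if mem:
            reps.append(recs[mem[0][0]])
    rng = np.random.default_rng(1)
    for _ in range(30):
        i, j = rng.choice(len(reps), size=2, replace=False)
        ident = global_align(reps[i], reps[j]).identity_short
        # members sit within ~(1-s) of their ancestors; separable ancestors
        # keep even member-member cross identities below the 0.35 threshold
        assert ident < 0.35


def test_separable_mode_margin_validation():
    with pytest.raises(ValueError, match="separable"):
        _small_bp(within_family_identity=0.4, cross_family_max_identity=0.3)


def test_contaminants_are_singletons_with_label():
    bp = _small_bp(contaminant_rate=0.2, n_singletons=0)
    _, truth = generate_collection(bp)
    cont = [f for f, c in truth.categories.items() if c == "contaminant"]
    assert len(cont) == round(0.2 * len(bp.taxonomy))
    for f in cont:
        assert len(truth.members[f]) == 1


def test_genome_pair_rate_zero_identical():
    a, b = generate_genome_pair(5000, 0.0, seed=1)
    assert a.residues == b.residues


def test_genome_pair_observed_rate_matches_binomial_expectation():
    a, b = generate_genome_pair(500_000, 0.05, seed=2)
    assert len(a.residues) == len(b.residues) == 500_000
    diff = sum(x != y for x, y in zip(a.residues, b.residues)) / 500_000
    assert abs(diff - 0.05) <= 0.003


def test_genome_pair_rejects_bad_rate():
    with pytest.raises(ValueError):
        generate_genome_pair(1000, 1.0, seed=0)
    with pytest.raises(ValueError):
        generate_genome_pair(1000, -0.1, seed=0)


def test_write_collection_roundtrip(tmp_path):
    bp = _small_bp()
    proteomes, truth = generate_collection(bp)
    paths = write_collection(proteomes, truth, bp.taxonomy, tmp_path)
    meta = read_metadata(paths["metadata"])
    assert [e.genome_id for e in meta] == [e.genome_id for e in bp.taxonomy]
    gid = sorted(proteomes)[0]
    back = read_fasta(paths[gid], "protein")
    assert [(r.seq_id, r.residues) for r in back] == [
        (r.seq_id, r.residues) for r in proteomes[gid]
    ]
    t2 = TruthTable.from_tsv(paths["truth"])
    assert t2.partition() == truth.partition()
    assert {f: c for f, c in t2.categories.items() if t2.members.get(f)} == {
        f: c for f, c in truth.categories.items() if truth.members.get(f)
    }


def test_default_taxonomy_shape():
    tax = default_taxonomy()
    assert len(tax) == 30
    orders = [e.order for e in tax]
    assert orders.count("NP") == 14 and orders.count("OUTGROUP") == 3
    subclades = {e.subclade for e in tax if e.order == "NP"}
    assert len(subclades) == 7
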