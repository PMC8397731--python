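import numpy as np
import pandas as pd
import pytest

from sedipan.cluster import FamilyMember, ProteinFamily
from sedipan.formats import GenomeEntry
from sedipan.pangenome import (
    AbsentIn,
    And,
    Not,
    Or,
    PresenceAbsenceMatrix,
    PresentFraction,
    PresentIn,
    annotated_fraction,
    build_matrix,
    evaluate_query,
    order_families_for_display,
    propagate_annotations,
    standard_partitions,
)


def _family(fid, members):
    """members: list of (seq_id, genome_id)"""
    return ProteinFamily(
        family_id=fid,
        representative_id=members[0][0],
        members=[FamilyMember(s, g, 1.0, 1.0, 1.0) for s, g in members],
    )


def _matrix_from_presence(presence: dict[str, list[str]], taxonomy):
    fams = [
        _family(fid, [(f"{fid}_{g}", g) for g in genomes])
        for fid, genomes in presence.items()
    ]
    return build_matrix(fams, taxonomy)


def test_empty_families_give_empty_matrix(tiny_taxonomy):
    m = build_matrix([], tiny_taxonomy)
    assert m.families == [] and len(m.genomes) == 7


def test_counts_are_copy_numbers(tiny_taxonomy):
    fam = _family("F0", [("a", "nc1"), ("b", "nc1"), ("c", "ns1")])
    m = build_matrix([fam], tiny_taxonomy)
    assert m.counts.loc["F0", "nc1"] == 2
    assert m.counts.loc["F0", "ns1"] == 1
    assert m.counts.loc["F0", "nt1"] == 0


def test_member_genome_missing_from_metadata(tiny_taxonomy):
    fam = _family("F0", [("a", "nowhere")])
    with pytest.raises(KeyError, match="nowhere"):
        build_matrix([fam], tiny_taxonomy)


def test_present_in_all_returns_nonempty_families(tiny_taxonomy):
    m = _matrix_from_presence({"F0": ["nc1"], "F1": ["ns1", "np_t1"]}, tiny_taxonomy)
    assert evaluate_query(m, PresentIn("ALL", 1)) == {"F0", "F1"}


def test_absent_in_all_is_empty(tiny_taxonomy):
    m = _matrix_from_presence({"F0": ["nc1"]}, tiny_taxonomy)
    assert evaluate_query(m, AbsentIn("ALL")) == set()


def test_core_query_equals_intersection(tiny_taxonomy):
    m = _matrix_from_presence(
        {
            "core": ["nc1", "ns1", "nt1", "np_t1"],
            "np_only": ["np_t1", "np_d1"],
        },
        tiny_taxonomy,
    )
    q = And(*(PresentIn(o, 1) for o in ("NC", "NS", "NT", "NP")))
    assert evaluate_query(m, q) == {"core"}


def test_query_algebra_distributes(tiny_taxonomy, rng):
    genomes = [e.genome_id for e in tiny_taxonomy]
    presence = {
        f"F{i}": [g for g in genomes if rng.random() < 0.5] or [genomes[0]]
        for i in range(12)
    }
    m = _matrix_from_presence(presence, tiny_taxonomy)
    a, b = PresentIn("NP", 1), AbsentIn("OUTGROUP")
    assert evaluate_query(m, And(a, b)) == evaluate_query(m, a) & evaluate_query(m, b)
    assert evaluate_query(m, Or(a, b)) == evaluate_query(m, a) | evaluate_query(m, b)
    nonempty = evaluate_query(m, PresentIn("ALL", 1))
    assert evaluate_query(m, Not(a)) == nonempty - evaluate_query(m, a)


def test_present_fraction_strict_majority(tiny_taxonomy):
    # NP has 3 genomes in the tiny taxonomy: >50% means >= 2 genomes
    m = _matrix_from_presence(
        {"one": ["np_t1"], "two": ["np_t1", "np_d1"]}, tiny_taxonomy
    )
    got = evaluate_query(m, PresentFraction("NP", 0.5, strict=True))
    assert got == {"two"}


def test_unknown_clade_raises(tiny_taxonomy):
    m = _matrix_from_presence({"F0": ["nc1"]}, tiny_taxonomy)
    with pytest.raises(KeyError):
        evaluate_query(m, PresentIn("NP-zeta", 1))


def test_degenerate_all_present_everywhere(tiny_taxonomy):
    genomes = [e.genome_id for e in tiny_taxonomy]
    m = _matrix_from_presence({f"F{i}": list(genomes) for i in range(4)}, tiny_taxonomy)
    rep = standard_partitions(m)
    assert rep.core_aoa == set(m.families)
    assert rep.aoa_specific == set()  # present in the outgroup too


def test_named_partitions_hand_built(tiny_taxonomy):
    m = _matrix_from_presence(
        {
            "core_all": ["nc1", "ns1", "nt1", "np_t1", "out1"],
            "core_aoa": ["nc1", "ns1", "nt1", "np_d1"],
            "sed": ["np_t1", "np_d1"],
            "np_pair": ["np_t1", "np_i1"],
            "ns_sed": ["ns1", "np_t1"],
            "lonely": ["np_t1"],
        },
        tiny_taxonomy,
    )
    rep = standard_partitions(m, deep_clades=("NP-theta", "NP-iota"))
    assert rep.core_aoa == {"core_all", "core_aoa"}
    assert rep.aoa_specific == {"core_aoa"}
    # core_aoa sits in 1 of the 3 NP genomes: 1/3 fails the strict >50% rule
    assert rep.conserved_core == set()
    assert rep.np_specific == {"sed", "np_pair"}
    assert rep.np_all_subclades == set()
    # np_pair touches theta+iota, which are two sediment clades as well
    assert rep.sediment_specific == {"sed", "np_pair"}
    # np_pair touches theta+iota (2 deep clades) and no non-deep NP genome
    assert rep.deep_ocean_shared == {"np_pair"}
    assert rep.sediment_ns_shared == {"ns_sed"}
    rep.check_nesting()


def test_nesting_invariants_on_random_matrices(tiny_taxonomy, rng):
    genomes = [e.genome_id for e in tiny_taxonomy]
    for _ in range(25):
        presence = {
            f"F{i}": [g for g in genomes if rng.random() < rng.uniform(0.1, 0.9)]
            or [genomes[int(rng.integers(len(genomes)))]]
            for i in range(30)
        }
        m = _matrix_from_presence(presence, tiny_taxonomy)
        rep = standard_partitions(m, deep_clades=("NP-theta", "NP-delta"))
        rep.check_nesting()  # raises on violation


def test_annotation_propagation_and_fraction():
    fams = [
        _family(f"F{i}", [(f"p{i}a", "g1"), (f"p{i}b", "g2")]) for i in range(72)
    ]
    labels = {f"p{i}a": {f"label{i}"} for i in range(18)}
    ann = propagate_annotations(fams, labels)
    assert ann["F0"] == ({"label0"}, True)
    assert ann["F30"] == (set(), False)
    frac = annotated_fraction(ann, [f.family_id for f in fams])
    assert frac == pytest.approx(0.25)
    assert annotated_fraction({}, []) == 0.0
    all_lab = propagate_annotations(fams, {f"p{i}{s}": "x" for i in range(72) for s in "ab"})
    assert annotated_fraction(all_lab, [f.family_id for f in fams]) == 1.0


def test_display_order_most_widespread_first(tiny_taxonomy, rng):
    m = _matrix_from_presence(
        {
            "everywhere": ["nc1", "ns1", "nt1", "np_t1"],
            "np_two": ["np_t1", "np_d1"],
            "np_one": ["np_t1"],
        },
        tiny_taxonomy,
    )
    assert order_families_for_display(m) == ["everywhere", "np_two", "np_one"]

    # brute-force comparison on a random matrix
    genomes = [e.genome_id for e in tiny_taxonomy]
    presence = {
        f"F{i:02d}": [g for g in genomes if rng.random() < 0.4] or [genomes[0]]
        for i in range(25)
    }
    m2 = _matrix_from_presence(presence, tiny_taxonomy)
    entries = {e.genome_id: e for e in tiny_taxonomy}

    def key(fid):
        gs = presence[fid]
        orders = {entries[g].order for g in gs if entries[g].order != "OUTGROUP"}
        return (-len(orders), -len(gs), fid)

    assert order_families_for_display(m2) == sorted(presence, key=key)
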