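"""Similarity kernels against hand values and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhrwr.containers import AssociationMatrix, OntologyDAG, SimilarityMatrix
from mhrwr.similarity import (
    disease_semantic_similarity,
    gip_bandwidth,
    gip_similarity,
    lncrna_functional_similarity,
    lncrna_set_similarity,
    semantic_contributions,
)

from conftest import random_ld


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain recursion / pair loops)


def oracle_contribution(dag, target, k, decay=0.5):
    """Contribution of ancestor k to target, by direct recursion on children."""
    if k == target:
        return 1.0
    closure = set(dag.ancestors(target)) | {target}
    children = [c for c in closure if k in dag.parents[c]]
    return max(decay * oracle_contribution(dag, target, c, decay) for c in children)


def oracle_dss(dag, t_i, t_j, decay=0.5):
    ci = {k: oracle_contribution(dag, t_i, k, decay) for k in dag.ancestors(t_i) | {t_i}}
    cj = {k: oracle_contribution(dag, t_j, k, decay) for k in dag.ancestors(t_j) | {t_j}}
    shared = ci.keys() & cj.keys()
    if not shared:
        return 0.0
    return sum(ci[k] + cj[k] for k in shared) / (sum(ci.values()) + sum(cj.values()))


def oracle_nfs(sets_i, sets_j, dss):
    """Best-match average of per-element max similarities, by explicit loops."""
    if not sets_i or not sets_j:
        return 0.0
    ss = lambda d, group: max(dss[d, x] for x in group)
    total = sum(ss(a, sets_j) for a in sets_i) + sum(ss(b, sets_i) for b in sets_j)
    return total / (len(sets_i) + len(sets_j))


def random_dag(n_terms, seed):
    rng = np.random.default_rng(seed)
    terms = [f"t{k}" for k in range(n_terms)]
    edges = {}
    for k in range(1, n_terms):
        n_parents = int(rng.integers(1, min(2, k) + 1))
        edges[terms[k]] = {terms[p] for p in rng.choice(k, n_parents, replace=False)}
    return OntologyDAG(edges, extra_terms=[terms[0]]), terms


# ---------------------------------------------------------------------------
# semantic contributions


def test_target_term_contributes_one(diamond_dag):
    assert semantic_contributions(diamond_dag, "c")["c"] == 1.0


def test_chain_contributions_decay_per_edge(chain_dag):
    assert semantic_contributions(chain_dag, "c") == {"c": 1.0, "b": 0.5, "a": 0.25}


def test_diamond_root_takes_max_over_children(diamond_dag):
    contrib = semantic_contributions(diamond_dag, "c")
    assert contrib == {"c": 1.0, "b1": 0.5, "b2": 0.5, "a": 0.25}


def test_contributions_reject_bad_inputs(chain_dag):
    with pytest.raises(KeyError, match="not in ontology"):
        semantic_contributions(chain_dag, "zzz")
    for decay in (0.0, 1.0, -0.5):
        with pytest.raises(ValueError):
            semantic_contributions(chain_dag, "c", decay=decay)


@pytest.mark.parametrize("depth", [1, 4, 9])
@pytest.mark.parametrize("decay", [0.3, 0.5, 0.8])
def test_pure_chain_equals_decay_power(depth, decay):
    terms = [f"n{i}" for i in range(depth + 1)]
    dag = OntologyDAG({terms[i]: {terms[i + 1]} for i in range(depth)})
    contrib = semantic_contributions(dag, terms[0], decay)
    for i, t in enumerate(terms):
        assert contrib[t] == pytest.approx(decay**i)


def test_contributions_non_increasing_toward_ancestors():
    dag, terms = random_dag(6, seed=11)
    contrib = semantic_contributions(dag, terms[-1])
    for k, v in contrib.items():
        for parent in dag.parents[k]:
            if parent in contrib:
                assert contrib[parent] <= v


@pytest.mark.parametrize("seed", range(5))
def test_contributions_match_recursive_oracle(seed):
    dag, terms = random_dag(6, seed)
    target = terms[-1]
    contrib = semantic_contributions(dag, target)
    for k in dag.ancestors(target) | {target}:
        assert contrib[k] == pytest.approx(oracle_contribution(dag, target, k), abs=1e-15)


# ---------------------------------------------------------------------------
# disease semantic similarity


def test_same_term_similarity_is_one(vee_dag):
    dss = disease_semantic_similarity(vee_dag, ["d1", "d2"], {"d1": "a", "d2": "a"})
    assert dss["d1", "d2"] == pytest.approx(1.0)


def test_sibling_terms_share_root_third(vee_dag):
    """Maps {a:1, r:0.5} and {b:1, r:0.5} share only r: (0.5+0.5)/(1.5+1.5)."""
    dss = disease_semantic_similarity(vee_dag, ["d1", "d2"], {"d1": "a", "d2": "b"})
    assert dss["d1", "d2"] == pytest.approx(1.0 / 3.0)


def test_disjoint_components_similarity_zero():
    dag = OntologyDAG({"a": {"ra"}, "b": {"rb"}})
    dss = disease_semantic_similarity(dag, ["d1", "d2"], {"d1": "a", "d2": "b"})
    assert dss["d1", "d2"] == 0.0


def test_unmapped_disease_zero_off_diagonal_one_on_diagonal(vee_dag):
    dss = disease_semantic_similarity(vee_dag, ["d1", "dx"], {"d1": "a"})
    assert dss["dx", "dx"] == 1.0
    assert dss["d1", "dx"] == 0.0


def test_empty_disease_list_rejected(vee_dag):
    with pytest.raises(ValueError):
        disease_semantic_similarity(vee_dag, [], {})


@pytest.mark.parametrize("seed", range(4))
def test_dss_matches_pairwise_oracle(seed):
    dag, terms = random_dag(6, seed + 20)
    rng = np.random.default_rng(seed)
    diseases = [f"d{i}" for i in range(5)]
    term_of = {d: terms[int(rng.integers(len(terms)))] for d in diseases}
    dss = disease_semantic_similarity(dag, diseases, term_of)
    for di, dj in itertools.combinations(diseases, 2):
        expected = oracle_dss(dag, term_of[di], term_of[dj])
        assert dss[di, dj] == pytest.approx(expected, abs=1e-14)


# ---------------------------------------------------------------------------
# GIP kernel


def test_bandwidth_examples():
    assert gip_bandwidth(np.eye(2)) == pytest.approx(1.0)
    assert gip_bandwidth(np.ones((2, 2))) == pytest.approx(0.5)
    profiles = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1]], dtype=float)
    assert gip_bandwidth(profiles) == pytest.approx(0.5)


def test_bandwidth_degenerate_profiles_rejected():
    with pytest.raises(ValueError, match="degenerate profiles"):
        gip_bandwidth(np.zeros((3, 2)))


def test_gip_identity_matrix_off_diagonal(identity_ld):
    """gamma = 1, squared distance between the two unit columns is 2."""
    sim = gip_similarity(identity_ld, "disease")
    assert sim["d1", "d2"] == pytest.approx(np.exp(-2.0))
    assert sim["d1", "d1"] == 1.0


def test_gip_identical_profiles_similarity_one():
    ld = AssociationMatrix(
        ["l1", "l2"], ["d1", "d2", "d3"], np.array([[1.0, 1, 0], [0, 1, 1]])
    )
    ld.values[:, 2] = ld.values[:, 1]
    sim = gip_similarity(ld, "disease")
    assert sim["d2", "d3"] == pytest.approx(1.0)


def test_gip_decreases_with_profile_distance():
    ld = random_ld(6, 8, seed=5)
    sim = gip_similarity(ld, "lncrna")
    gamma = gip_bandwidth(ld.values)
    d2 = ((ld.values[:, None, :] - ld.values[None, :, :]) ** 2).sum(-1)
    assert np.allclose(sim.values, np.exp(-gamma * d2), atol=1e-12)


# ---------------------------------------------------------------------------
# set and functional similarity


def test_set_similarity_examples(vee_dag):
    dss = SimilarityMatrix(
        ["d", "x", "y"],
        np.array([[1.0, 0.2, 0.7], [0.2, 1.0, 0.0], [0.7, 0.0, 1.0]]),
    )
    assert lncrna_set_similarity("d", ["x", "y"], dss) == pytest.approx(0.7)
    assert lncrna_set_similarity("d", ["d", "x"], dss) == 1.0
    assert lncrna_set_similarity("d", [], dss) == 0.0


def test_functional_similarity_singleton_sets(vee_dag):
    """D_i = {a-disease}, D_j = {b-disease}, DSS = 1/3 -> NFS = 1/3."""
    ld = AssociationMatrix(["l1", "l2"], ["da", "db"], np.eye(2))
    dss = disease_semantic_similarity(vee_dag, ["da", "db"], {"da": "a", "db": "b"})
    nfs = lncrna_functional_similarity(ld, dss)
    assert nfs["l1", "l2"] == pytest.approx(1.0 / 3.0)


def test_functional_similarity_identical_sets_is_one():
    ld = AssociationMatrix(
        ["l1", "l2"], ["d1", "d2"], np.array([[1.0, 1.0], [1.0, 1.0]])
    )
    dss = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.1], [0.1, 1.0]]))
    assert lncrna_functional_similarity(ld, dss)["l1", "l2"] == pytest.approx(1.0)


def test_functional_similarity_empty_set_is_zero():
    ld = AssociationMatrix(
        ["l1", "l2"], ["d1", "d2"], np.array([[0.0, 0.0], [1.0, 1.0]])
    )
    dss = SimilarityMatrix(["d1", "d2"], np.eye(2))
    nfs = lncrna_functional_similarity(ld, dss)
    assert nfs["l1", "l2"] == 0.0
    assert nfs["l1", "l1"] == 1.0


@pytest.mark.parametrize("seed", range(4))
def test_functional_similarity_matches_loop_oracle(seed):
    ld = random_ld(5, 6, seed)
    from conftest import random_similarity

    dss = random_similarity(ld.disease_ids, seed + 50)
    nfs = lncrna_functional_similarity(ld, dss)
    for li, lj in itertools.combinations(ld.lncrna_ids, 2):
        expected = oracle_nfs(ld.diseases_of(li), ld.diseases_of(lj), dss)
        assert nfs[li, lj] == pytest.approx(expected, abs=1e-14)


def test_functional_similarity_permutation_invariant():
    ld = random_ld(5, 6, seed=9)
    from conftest import random_similarity

    dss = random_similarity(ld.disease_ids, 99)
    nfs = lncrna_functional_similarity(ld, dss)
    perm = np.random.default_rng(0).permutation(ld.n_diseases)
    ld_p = AssociationMatrix(
        list(ld.lncrna_ids),
        [ld.disease_ids[j] for j in perm],
        ld.values[:, perm],
    )
    dss_p = SimilarityMatrix(
        [ld.disease_ids[j] for j in perm], dss.values[np.ix_(perm, perm)]
    )
    nfs_p = lncrna_functional_similarity(ld_p, dss_p)
    assert np.allclose(nfs.values, nfs_p.values, atol=1e-14)


# ---------------------------------------------------------------------------
# layer-wide invariants


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_all_layers_symmetric_unit_interval_unit_diagonal(seed):
    ld = random_ld(5, 5, seed)
    dag, terms = random_dag(6, seed)
    rng = np.random.default_rng(seed)
    term_of = {d: terms[int(rng.integers(len(terms)))] for d in ld.disease_ids}
    dss = disease_semantic_similarity(dag, ld.disease_ids, term_of)
    layers = [
        dss,
        gip_similarity(ld, "disease"),
        gip_similarity(ld, "lncrna"),
        lncrna_functional_similarity(ld, dss),
    ]
    for layer in layers:
        v = layer.values
        assert np.allclose(v, v.T, atol=1e-12)
        assert v.min() >= 0 and v.max() <= 1 + 1e-12
        assert np.allclose(np.diag(v), 1.0)
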