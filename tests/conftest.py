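import numpy as np
import pytest

from mhrwr.containers import AssociationMatrix, OntologyDAG, RWRParams, SimilarityMatrix


@pytest.fixture
def chain_dag():
    """c -> b -> a, with a the root."""
    return OntologyDAG({"c": {"b"}, "b": {"a"}})


@pytest.fixture
def diamond_dag():
    """c -> {b1, b2} -> a."""
    return OntologyDAG({"c": {"b1", "b2"}, "b1": {"a"}, "b2": {"a"}})


@pytest.fixture
def vee_dag():
    """Root r with children a and b."""
    return OntologyDAG({"a": {"r"}, "b": {"r"}})


@pytest.fixture
def identity_ld():
    return AssociationMatrix(["l1", "l2"], ["d1", "d2"], np.eye(2))


def random_ld(n, m, seed, density=0.4):
    """Random binary association matrix with no empty rows or columns."""
    rng = np.random.default_rng(seed)
    while True:
        values = (rng.random((n, m)) < density).astype(float)
        if values.sum(axis=1).min() > 0 and values.sum(axis=0).min() > 0:
            return AssociationMatrix(
                [f"l{i}" for i in range(n)], [f"d{j}" for j in range(m)], values
            )


def random_similarity(ids, seed):
    """Random symmetric similarity matrix with unit diagonal."""
    rng = np.random.default_rng(seed)
    k = len(ids)
    a = rng.random((k, k))
    values = (a + a.T) / 2
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), values)


@pytest.fixture
def two_layer_fixture():
    """4 lncRNAs x 3 diseases with L = K = 2 random similarity layers."""
    ld = random_ld(4, 3, seed=7)
    lnc_layers = [random_similarity(ld.lncrna_ids, s) for s in (1, 2)]
    dis_layers = [random_similarity(ld.disease_ids, s) for s in (3, 4)]
    return ld, lnc_layers, dis_layers


@pytest.fixture
def default_params():
    return RWRParams()
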