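import itertools
import string

import numpy as np
import pytest

from sitepart.alignment import Alignment, MISSING_CODE
from sitepart.properties import kidera_table
from sitepart.substitution import ExchangeabilityMatrix, build_rate_matrix
from sitepart.trees import PhyloTree, random_tree


@pytest.fixture(scope="session")
def kidera():
    return kidera_table()


def brute_force_log_likelihood(msa: Alignment, tree: PhyloTree, q, pi) -> float:
    """Independent likelihood oracle: full sum-product over node states.

    Builds the joint probability as one einsum contraction with an index
    per internal node (leaf factors are the per-site transition rows), so
    it shares no code path with the pruning engine.  Only practical for
    a handful of taxa.
    """
    from scipy.linalg import expm

    q = np.asarray(q, float)
    pi = np.asarray(pi, float)
    codes = msa.codes()
    rows = [msa.names.index(n) for n in tree.leaf_names]
    codes = codes[rows]
    n_sites = codes.shape[1]

    letters = string.ascii_lowercase
    idx = {node: letters[i] for i, node in enumerate(range(tree.n_nodes))}
    site_axis = "z"
    operands, subscripts = [], []
    subscripts.append(idx[tree.root])
    operands.append(pi)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        P = expm(q * tree.branch_lengths[v])
        par = idx[tree.parent[v]]
        if v < tree.n_leaves:
            obs = codes[v]
            factor = np.empty((20, n_sites))
            for s in range(n_sites):
                if obs[s] == MISSING_CODE:
                    factor[:, s] = P.sum(axis=1)  # marginalise missing leaf
                else:
                    factor[:, s] = P[:, obs[s]]
            operands.append(factor)
            subscripts.append(par + site_axis)
        else:
            operands.append(P)
            subscripts.append(par + idx[v])
    expr = ",".join(subscripts) + "->" + site_axis
    site_lik = np.einsum(expr, *operands, optimize=True)
    return float(np.log(site_lik).sum())


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_log_likelihood


def random_model(seed, sd=0.8, alpha=8.0):
    rng = np.random.default_rng(seed)
    R = ExchangeabilityMatrix.random(seed=seed, sd=sd)
    pi = rng.dirichlet(np.full(20, alpha))
    return R, pi


@pytest.fixture(scope="session")
def small_instance():
    """5-taxon tree with a simulated alignment and its generating model."""
    from sitepart.simulate import simulate_alignment

    R, pi = random_model(11)
    tree = random_tree(5, 0.2, seed=12)
    msa = simulate_alignment(tree, R, pi, 120, seed=13)
    return msa, tree, R, pi
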