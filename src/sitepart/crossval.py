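"""50% likelihood cross-validation of group-specific matrices.

Each site group is split at random into equally sized training and
validation halves.  A matrix is fitted to every training half, and every
validation half is scored under every training matrix and under the
joint (complete-data) matrix; group-specific matrices should win their
own validation set if the group structure is real.  Validation scoring
uses the validation subset's empirical frequencies and re-optimises
branch lengths under each candidate matrix, so only the exchangeabilities
are under test.  The site groups are fixed before training (they come
from clustering the complete data), which makes this a deliberately
non-standard cross-validation of the published-matrix use case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment
from .clustering import ClusterAssignment
from .likelihood import TreeLikelihood
from .model import fit_exchangeabilities
from .substitution import (
    PAIR_INDEX,
    ExchangeabilityMatrix,
    build_rate_matrix,
    empirical_frequencies,
)
from .trees import PhyloTree

__all__ = ["split_half", "cv_replicate", "cv_summary", "cross_validate", "CrossValReplicate"]


def split_half(group_sites, seed=None):
    """Uniform random 50/50 split; an odd site goes to the training half."""
    sites = np.asarray(group_sites)
    if sites.shape[0] < 2:
        raise ValueError("need at least two sites to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sites)
    n_train = (sites.shape[0] + 1) // 2
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class CrossValReplicate:
    """One replicate: splits, training matrices, validation logL table.

    ``loglik`` is a DataFrame with one row per candidate matrix
    ("R_T1".."R_Tk", "R_0") and one column per validation set
    ("V_1".."V_k").
    """

    training_sites: list
    validation_sites: list
    training_matrices: list
    loglik: pd.DataFrame

    @property
    def k(self) -> int:
        return len(self.training_sites)

    def winner_is_matched(self, i: int) -> bool:
        """Does V_i's own training matrix achieve the best score?"""
        col = self.loglik[f"V_{i}"]
        return col.idxmax() == f"R_T{i}"


def _validation_loglike(msa_subset, tree, R, reoptimize_branches=True):
    pi = empirical_frequencies(msa_subset)
    engine = TreeLikelihood(msa_subset, tree, pi=pi)
    Q = build_rate_matrix(R, pi)
    rho_pairs = (np.asarray(Q.q) / pi[None, :])[PAIR_INDEX]
    if not reoptimize_branches:
        return engine.loglike_q(np.asarray(Q.q))
    _, ll, _ = engine.optimize_branches_lbfgs(rho_pairs)
    return ll


def cv_replicate(
    msa: Alignment,
    assignment: ClusterAssignment,
    tree: PhyloTree,
    joint_R: ExchangeabilityMatrix,
    seed=None,
    fit_options: dict | None = None,
    reoptimize_branches: bool = True,
) -> CrossValReplicate:
    """One 50% cross-validation replicate.

    ``joint_R`` is the complete-data matrix (supplied, not refitted).
    """
    fit_options = dict(fit_options or {})
    rng = np.random.default_rng(seed)
    k = assignment.k

    T, V, R_T = [], [], []
    for g in range(1, k + 1):
        t_idx, v_idx = split_half(
            assignment.group_sites(g), seed=int(rng.integers(2**31))
        )
        T.append(t_idx)
        V.append(v_idx)
        res = fit_exchangeabilities(msa.subset_sites(t_idx), tree, **fit_options)
        R_T.append(res.rates)

    candidates = {f"R_T{i + 1}": R for i, R in enumerate(R_T)}
    candidates["R_0"] = joint_R
    table = pd.DataFrame(
        index=list(candidates), columns=[f"V_{i + 1}" for i in range(k)], dtype=float
    )
    for i in range(k):
        v_msa = msa.subset_sites(V[i])
        for name, R in candidates.items():
            table.loc[name, f"V_{i + 1}"] = _validation_loglike(
                v_msa, tree, R, reoptimize_branches
            )
    return CrossValReplicate(
        training_sites=T, validation_sites=V, training_matrices=R_T, loglik=table
    )


def cv_summary(replicates) -> pd.DataFrame:
    """Mean and SD of logL(V_i | R_Ti) - logL(V_i | alternative).

    One row per validation set, one (mean, sd) column pair per
    alternative matrix; the winner-vs-itself diagonal is omitted (NaN).
    """
    replicates = list(replicates)
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to summarise")
    k = replicates[0].k
    alternatives = ["R_0"] + [f"R_T{j + 1}" for j in range(k)]
    rows = []
    for i in range(1, k + 1):
        row = {"validation_set": f"V_{i}", "winner": f"R_T{i}"}
        for alt in alternatives:
            if alt == f"R_T{i}":
                row[f"delta_{alt}_mean"] = np.nan
                row[f"delta_{alt}_sd"] = np.nan
                continue
            deltas = np.array(
                [
                    rep.loglik.loc[f"R_T{i}", f"V_{i}"] - rep.loglik.loc[alt, f"V_{i}"]
                    for rep in replicates
                ]
            )
            row[f"delta_{alt}_mean"] = float(deltas.mean())
            row[f"delta_{alt}_sd"] = float(deltas.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def cross_validate(
    msa: Alignment,
    assignment: ClusterAssignment,
    tree: PhyloTree,
    joint_R: ExchangeabilityMatrix,
    n_replicates: int = 10,
    seed=None,
    fit_options: dict | None = None,
    reoptimize_branches: bool = True,
):
    """Run ``n_replicates`` cross-validation replicates; returns
    ``(replicates, summary_frame)``."""
    rng = np.random.default_rng(seed)
    reps = [
        cv_replicate(
            msa,
            assignment,
            tree,
            joint_R,
            seed=int(rng.integers(2**31)),
            fit_options=fit_options,
            reoptimize_branches=reoptimize_branches,
        )
        for _ in range(n_replicates)
    ]
    return reps, cv_summary(reps)
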