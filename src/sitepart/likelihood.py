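"""Pruning likelihood for the 20-state reversible model on a fixed tree.

The engine compresses alignment columns into unique site patterns,
computes the Felsenstein pruning likelihood by post-order accumulation of
partial likelihoods, and supplies analytic first derivatives with respect
to both branch lengths and the 190 exchangeability pairs.  Derivatives of
P(t) = exp(Qt) use the spectral (Frechet) form available from the
symmetric eigendecomposition of the reversible generator, so a full
gradient costs only a small multiple of one likelihood evaluation.

All internal computations use the *unnormalised* generator built from a
pair vector rho and frequencies pi (q_ij = rho_ij pi_j); the likelihood
is invariant to a joint rescaling of rho and branch lengths, and the
mean-rate-one convention is applied only when results are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .substitution import (
    N_STATES,
    PAIR_INDEX,
    RateMatrix,
    empirical_frequencies,
    _Eigensystem,
)
from .trees import MIN_BRANCH_LENGTH, PhyloTree

__all__ = [
    "TreeLikelihood",
    "log_likelihood",
    "optimize_branch_lengths",
    "fit_branch_scale",
    "LabelMismatchError",
]

# leaf conditional-likelihood rows: identity for observed states, ones for
# missing data
_LEAF_PARTIALS = np.vstack([np.eye(N_STATES), np.ones((1, N_STATES))])


class LabelMismatchError(ValueError):
    def __init__(self, missing_in_msa, missing_in_tree):
        self.missing_in_msa = sorted(missing_in_msa)
        self.missing_in_tree = sorted(missing_in_tree)
        parts = []
        if self.missing_in_msa:
            parts.append("absent from alignment: " + ", ".join(self.missing_in_msa))
        if self.missing_in_tree:
            parts.append("absent from tree: " + ", ".join(self.missing_in_tree))
        super().__init__("leaf/sequence labels do not match; " + "; ".join(parts))


class TreeLikelihood:
    """Pruning likelihood of one alignment on one (fixed) topology.

    Parameters
    ----------
    msa : Alignment
    tree : PhyloTree
        Supplies the topology and the initial branch lengths.
    pi : array, optional
        Equilibrium frequencies; empirical frequencies of ``msa`` (with
        ``pseudocount``) when omitted.
    """

    def __init__(self, msa: Alignment, tree: PhyloTree, pi=None, pseudocount=1e-6):
        tree_names = set(tree.leaf_names)
        msa_names = set(msa.names)
        if tree_names != msa_names:
            raise LabelMismatchError(tree_names - msa_names, msa_names - tree_names)
        self.tree = tree.copy()
        codes = msa.codes()
        rows = [msa.names.index(n) for n in tree.leaf_names]
        codes = codes[rows]  # leaf order of the tree
        patterns, weights = np.unique(codes.T, axis=0, return_counts=True)
        self.patterns = patterns.T  # (n_leaves, n_patterns)
        self.weights = weights.astype(float)
        self.n_sites = msa.n_sites
        self.n_patterns = self.patterns.shape[1]
        if pi is None:
            pi = empirical_frequencies(msa, pseudocount)
        self.pi = np.asarray(pi, dtype=float)
        if np.any(self.pi <= 0):
            raise ValueError("equilibrium frequencies must be strictly positive")
        self._leaf_down = [
            _LEAF_PARTIALS[self.patterns[i]] for i in range(tree.n_leaves)
        ]

    # -- generators ----------------------------------------------------

    def q_unnormalised(self, rho_pairs) -> np.ndarray:
        rho = np.zeros((N_STATES, N_STATES))
        rho[PAIR_INDEX] = rho_pairs
        rho = rho + rho.T
        q = rho * self.pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    # -- core passes ---------------------------------------------------

    def _transition_matrices(self, eig, t):
        P = [None] * self.tree.n_nodes
        for v in range(self.tree.n_nodes):
            if v != self.tree.root:
                P[v] = eig.expm(t[v])
        return P

    def _down_pass(self, P):
        """Post-order conditional likelihoods; returns (down, messages)."""
        tr = self.tree
        down = [None] * tr.n_nodes
        msg = [None] * tr.n_nodes  # message from node v to its parent
        for v in tr.postorder:
            if v < tr.n_leaves:
                down[v] = self._leaf_down[v]
            else:
                prod = None
                for c in tr.children[v]:
                    m = down[c] @ P[c].T
                    msg[c] = m
                    prod = m if prod is None else prod * m
                down[v] = prod
        return down, msg

    def _site_likelihoods(self, down):
        return down[self.tree.root] @ self.pi

    def loglike_q(self, q, t=None) -> float:
        """Log-likelihood under an arbitrary reversible generator ``q``."""
        t = self.tree.branch_lengths if t is None else np.asarray(t, float)
        eig = _Eigensystem(q, self.pi)
        P = self._transition_matrices(eig, t)
        down, _ = self._down_pass(P)
        L = self._site_likelihoods(down)
        if np.any(L <= 0):
            return -np.inf
        return float(self.weights @ np.log(L))

    def loglike(self, rho_pairs, t=None) -> float:
        return self.loglike_q(self.q_unnormalised(rho_pairs), t)

    def loglike_grad(self, rho_pairs, t):
        """(logL, d logL/d rho_pairs, d logL/d t) — all analytic.

        ``t`` is node-indexed (root entry ignored).  Gradients are with
        respect to the raw (not log) parameters.
        """
        tr = self.tree
        t = np.asarray(t, dtype=float)
        q = self.q_unnormalised(rho_pairs)
        eig = _Eigensystem(q, self.pi)
        P = self._transition_matrices(eig, t)
        down, msg = self._down_pass(P)
        L = self._site_likelihoods(down)
        if np.any(L <= 0):
            return -np.inf, np.zeros_like(rho_pairs), np.zeros_like(t)
        ll = float(self.weights @ np.log(L))
        wl = self.weights / L

        S, Sinv, lam = eig.S, eig.Sinv, eig.lam
        ST, SinvT = S.T, Sinv.T
        grad_t = np.zeros(tr.n_nodes)
        E = np.zeros((N_STATES, N_STATES))

        # pre-order sweep carrying the "rest of tree" partials O
        O = [None] * tr.n_nodes
        O[tr.root] = np.broadcast_to(self.pi, (self.n_patterns, N_STATES))
        for u in tr.preorder:
            if u < tr.n_leaves:
                continue
            cs = tr.children[u]
            msgs = [msg[c] for c in cs]
            # prefix/suffix products over sibling messages
            k = len(cs)
            prefix = [None] * (k + 1)
            prefix[0] = O[u]
            for i in range(k):
                prefix[i + 1] = prefix[i] * msgs[i]
            suffix = np.ones_like(msgs[0])
            for i in range(k - 1, -1, -1):
                v = cs[i]
                O_v = prefix[i] * suffix
                suffix = suffix * msgs[i]
                # branch gradient and exchangeability accumulation
                W = (O_v * wl[:, None]).T @ down[v]  # 20x20
                grad_t[v] = float(np.sum(W * (q @ P[v])))
                G = _frechet_weights(lam, t[v])
                K = (ST @ W @ SinvT) * G
                E += SinvT @ K @ ST
                if v >= tr.n_leaves:
                    O[v] = O_v @ P[v]

        ii, jj = PAIR_INDEX
        grad_pairs = self.pi[jj] * (E[ii, jj] - E[ii, ii]) + self.pi[ii] * (
            E[jj, ii] - E[jj, jj]
        )
        return ll, grad_pairs, grad_t

    # -- branch-length machinery ----------------------------------------

    def _branch_messages(self, eig, t, target):
        """O_v and down_v for branch ``target`` under current lengths."""
        tr = self.tree
        P = self._transition_matrices(eig, t)
        down, msg = self._down_pass(P)
        O = {tr.root: np.broadcast_to(self.pi, (self.n_patterns, N_STATES))}
        for u in tr.preorder:
            if u < tr.n_leaves:
                continue
            for c in tr.children[u]:
                prod = O[u]
                for w in tr.children[u]:
                    if w != c:
                        prod = prod * msg[w]
                if c == target:
                    return prod, down[c]
                if c >= tr.n_leaves:
                    O[c] = prod @ P[c]
        raise AssertionError("branch not found")  # pragma: no cover

    def optimize_branches_sweep(
        self, rho_pairs, t0=None, tol=1e-6, max_sweeps=20, t_max=50.0
    ):
        """Per-branch univariate (Brent) optimisation, iterated to tolerance.

        Messages are recomputed for every branch so each one-dimensional
        optimisation is exact given the other branches; the log-likelihood
        is therefore non-decreasing across updates.
        """
        tr = self.tree
        t = (tr.branch_lengths if t0 is None else np.asarray(t0, float)).copy()
        t = np.clip(t, MIN_BRANCH_LENGTH, t_max)
        t[tr.root] = 0.0
        q = self.q_unnormalised(rho_pairs)
        eig = _Eigensystem(q, self.pi)
        lam = eig.lam
        ll = self.loglike_q(q, t)
        converged = False
        for _ in range(max_sweeps):
            for v in tr.postorder:
                if v == tr.root:
                    continue
                O_v, down_v = self._branch_messages(eig, t, v)
                A = (O_v @ eig.S) * (down_v @ eig.Sinv.T)  # n_pat x 20
                Aw = A  # combine with exp(lam t) per trial

                def neg(tb):
                    site = Aw @ np.exp(lam * tb)
                    if np.any(site <= 0):
                        return np.inf
                    return -float(self.weights @ np.log(site))

                res = minimize_scalar(
                    neg, bounds=(MIN_BRANCH_LENGTH, t_max), method="bounded",
                    options={"xatol": 1e-10},
                )
                if -res.fun > -neg(t[v]):
                    t[v] = float(res.x)
            new_ll = self.loglike_q(q, t)
            if new_ll - ll < tol:
                ll = max(new_ll, ll)
                converged = True
                break
            ll = new_ll
        return t, ll, converged

    def optimize_branches_lbfgs(self, rho_pairs, t0=None, tol=1e-8, maxiter=200):
        """Joint quasi-Newton optimisation of all log branch lengths."""
        from scipy.optimize import minimize

        tr = self.tree
        t_init = (tr.branch_lengths if t0 is None else np.asarray(t0, float)).copy()
        t_init = np.clip(t_init, MIN_BRANCH_LENGTH, 50.0)
        free = np.array([v for v in range(tr.n_nodes) if v != tr.root])

        def unpack(x):
            t = np.zeros(tr.n_nodes)
            t[free] = np.exp(x)
            return t

        def fun(x):
            t = unpack(x)
            ll, _, gt = self.loglike_grad(np.asarray(rho_pairs), t)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(x)
            return -ll, -(gt[free] * t[free])

        x0 = np.log(t_init[free])
        bounds = [(np.log(MIN_BRANCH_LENGTH), np.log(50.0))] * len(free)
        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol},
        )
        t = unpack(res.x)
        return t, -float(res.fun), bool(res.success)


# -- public operations --------------------------------------------------


def log_likelihood(msa: Alignment, tree: PhyloTree, Q: RateMatrix, pi=None) -> float:
    """Pruning log-likelihood of ``msa`` on ``tree`` under a fixed ``Q``.

    ``pi`` defaults to the stationary frequencies carried by ``Q``; the
    value is invariant to root placement because the model is reversible.
    """
    pi = Q.pi if pi is None else np.asarray(pi, float)
    engine = TreeLikelihood(msa, tree, pi=pi)
    return engine.loglike_q(np.asarray(Q.q, float))


def optimize_branch_lengths(
    msa: Alignment,
    tree: PhyloTree,
    Q: RateMatrix,
    pi=None,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> PhyloTree:
    """ML branch lengths under a fixed rate matrix.

    Iterated per-branch Brent optimisation; the returned tree never has a
    lower likelihood than the input.  A warning is emitted when the sweep
    limit is reached before the per-sweep improvement falls below ``tol``.
    """
    pi = Q.pi if pi is None else np.asarray(pi, float)
    engine = TreeLikelihood(msa, tree, pi=pi)
    # express Q as pairs under engine.pi: rho_ij = q_ij / pi_j
    rho = np.asarray(Q.q, float) / pi[None, :]
    rho_pairs = rho[PAIR_INDEX]
    t, ll, converged = engine.optimize_branches_sweep(
        rho_pairs, tol=tol, max_sweeps=max_sweeps
    )
    if not converged:
        warnings.warn(
            f"branch-length optimisation did not converge in {max_sweeps} sweeps",
            RuntimeWarning,
        )
    return tree.with_branch_lengths(t)


def fit_branch_scale(
    msa_subset: Alignment,
    base_tree: PhyloTree,
    Q: RateMatrix,
    pi=None,
    bounds=(1e-3, 100.0),
):
    """ML estimate of a single branch-length multiplier for a data subset.

    All branch lengths of ``base_tree`` are stretched by one scale factor
    s; returns ``(s, logL)``.  A warning is emitted when the optimum sits
    on the search boundary.
    """
    pi = Q.pi if pi is None else np.asarray(pi, float)
    engine = TreeLikelihood(msa_subset, base_tree, pi=pi)
    q = np.asarray(Q.q, float)
    t0 = base_tree.branch_lengths

    def neg(log_s):
        return -engine.loglike_q(q, np.exp(log_s) * t0)

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    s = float(np.exp(res.x))
    if s <= bounds[0] * 1.01 or s >= bounds[1] * 0.99:
        warnings.warn(f"branch scale hit the search boundary: s={s:.4g}", RuntimeWarning)
    return s, -float(res.fun)


def _frechet_weights(lam, t):
    """G_kl = (e^{lam_k t} - e^{lam_l t}) / (lam_k - lam_l), diag t e^{lam t}."""
    e = np.exp(lam * t)
    dl = np.subtract.outer(lam, lam)
    de = np.subtract.outer(e, e)
    near = np.abs(dl) < 1e-9
    G = np.where(near, t * np.exp(np.add.outer(lam, lam) * t / 2.0), de / np.where(near, 1.0, dl))
    return G
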