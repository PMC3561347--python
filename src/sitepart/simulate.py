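"""Sequence simulation and group-structured synthetic fixtures.

`simulate_alignment` evolves sites independently down a tree under one
reversible model.  `make_fixture` concatenates per-group simulations that
differ in amino-acid frequency profile (and exchangeability matrix) and
shuffles the site order, mimicking an alignment whose sites fall into a
few physiochemically distinct classes: one class dominated by the bulky
hydrophobics (leucine/isoleucine), one by alanine/threonine, and one by
the small bend-formers (glycine, proline, serine, asparagine) --- the
signature composition of mitochondrial protein site classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .properties import AMINO_ACIDS
from .substitution import (
    ExchangeabilityMatrix,
    build_rate_matrix,
    validate_frequencies,
    _Eigensystem,
)
from .trees import PhyloTree, random_tree

__all__ = [
    "simulate_alignment",
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "group_frequency_profile",
    "DEFAULT_GROUP_RESIDUES",
]


def simulate_alignment(
    tree: PhyloTree, R: ExchangeabilityMatrix, pi, n_sites: int, seed=None
) -> Alignment:
    """Simulate ``n_sites`` i.i.d. columns on ``tree`` under Q = R*diag(pi).

    Root states are drawn from ``pi`` and evolved along each branch with
    the exact transition probabilities; deterministic given ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    pi = validate_frequencies(pi)
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(R, pi)
    eig = _Eigensystem(np.asarray(Q.q), pi)

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(20, size=n_sites, p=pi)
    for v in tree.preorder:
        if v == tree.root:
            continue
        P = eig.expm(tree.branch_lengths[v])
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n_sites)
        parent_states = states[tree.parent[v]]
        states[v] = (u[:, None] > cum[parent_states]).sum(axis=1)

    letters = np.array(list(AMINO_ACIDS))
    chars = letters[states[: tree.n_leaves]]
    return Alignment(list(tree.leaf_names), chars)


#: Dominant residues per default group, echoing the composition of the
#: three mitochondrial site classes (hydrophobic; alanine/threonine;
#: small bend-formers).
DEFAULT_GROUP_RESIDUES = (
    {"L": 0.30, "I": 0.22, "V": 0.12, "F": 0.10, "M": 0.08},
    {"A": 0.34, "T": 0.26, "S": 0.10, "M": 0.06, "L": 0.06},
    {"G": 0.28, "P": 0.22, "S": 0.22, "N": 0.14},
)


def group_frequency_profile(dominant: dict, background: float | None = None) -> np.ndarray:
    """Frequency vector concentrating mass on ``dominant`` residues.

    The remaining mass is spread evenly over the other residues so every
    frequency stays strictly positive.
    """
    pi = np.zeros(20)
    total = sum(dominant.values())
    if total >= 1.0:
        raise ValueError("dominant residue mass must be < 1")
    for res, f in dominant.items():
        pi[AMINO_ACIDS.index(res)] = f
    rest = np.nonzero(pi == 0)[0]
    pi[rest] = (1.0 - total) / len(rest)
    return pi


@dataclass
class FixtureSpec:
    """Recipe for a group-structured synthetic alignment.

    group_sizes : sites per group
    group_frequencies : one frequency vector per group (defaults to the
        three-class mitochondrial-like profiles)
    group_rates : one ExchangeabilityMatrix per group (defaults to
        well-separated random matrices derived from ``seed``)
    """

    n_taxa: int = 24
    mean_branch_length: float = 2.0
    group_sizes: tuple = (140, 130, 120)
    group_frequencies: list = None
    group_rates: list = None
    seed: int = 0

    def __post_init__(self):
        k = len(self.group_sizes)
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.group_frequencies is None:
            if k <= len(DEFAULT_GROUP_RESIDUES):
                self.group_frequencies = [
                    group_frequency_profile(DEFAULT_GROUP_RESIDUES[g]) for g in range(k)
                ]
            else:
                raise ValueError("supply group_frequencies for k > 3")
        if self.group_rates is None:
            self.group_rates = [
                ExchangeabilityMatrix.random(seed=int(self.seed) * 97 + 11 * g, sd=0.8)
                for g in range(k)
            ]
        if not (len(self.group_frequencies) == len(self.group_rates) == k):
            raise ValueError("per-group fields must match the number of groups")
        for pi in self.group_frequencies:
            validate_frequencies(pi)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class Fixture:
    """A synthetic alignment with its generating truth."""

    alignment: Alignment
    tree: PhyloTree
    labels: np.ndarray  # true group of each site, 1-based, post-shuffle
    spec: FixtureSpec


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Simulate, concatenate and shuffle the per-group alignments."""
    rng = np.random.default_rng(spec.seed)
    tree = random_tree(
        spec.n_taxa, spec.mean_branch_length, seed=int(rng.integers(2**31))
    )
    blocks, labels = [], []
    for g in range(spec.n_groups):
        aln = simulate_alignment(
            tree,
            spec.group_rates[g],
            spec.group_frequencies[g],
            spec.group_sizes[g],
            seed=int(rng.integers(2**31)),
        )
        blocks.append(aln)
        labels.extend([g + 1] * spec.group_sizes[g])
    full = blocks[0]
    for b in blocks[1:]:
        full = full.concatenate(b)
    labels = np.asarray(labels)
    perm = rng.permutation(full.n_sites)
    return Fixture(
        alignment=full.subset_sites(perm),
        tree=tree,
        labels=labels[perm],
        spec=spec,
    )
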