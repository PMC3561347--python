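"""Physiochemical site profiles.

An amino-acid alignment column is summarised by the mean of the Kidera
factors of its residues: nine near-orthogonal scales distilled from 188
physiochemical property measures.  The nine factors are, in order:

* P1 -- bulk
* P2, P3 -- hydrophobicity of the free amino acid
* P4 -- hydrophobicity in proteins
* P5, P6 -- beta-structure preference
* P7 -- alpha-helix preference
* P8, P9 -- bend-structure preference

All scales are (approximately) centred over the 20 canonical residues, so
profiles of different sites are directly comparable.  The per-site means
form an ``n x 9`` matrix (*n* alignment sites) that downstream code
clusters into physiochemical site classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "PROPERTY_NAMES",
    "AminoAcidPropertyTable",
    "SiteProfileMatrix",
    "kidera_table",
    "site_profile",
    "profile_matrix",
    "read_profile_tsv",
    "AllGapSiteError",
]

#: Canonical one-letter residue codes in the PAML matrix order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

PROPERTY_NAMES = tuple(f"P{i}" for i in range(1, 10))

# Kidera factors for the 20 canonical amino acids (rows in AMINO_ACIDS
# order, columns P1..P9).
_KIDERA = np.array(
    [
        # P1     P2     P3     P4     P5     P6     P7     P8     P9
        [-1.44, -0.47, 0.11, 0.32, -0.51, -0.86, 1.35, -1.29, -0.60],  # A
        [1.16, -0.57, -1.52, -1.07, -0.28, -0.13, -0.16, 0.28, -0.03],  # R
        [-0.34, -1.25, -0.60, -0.96, -1.00, -1.19, -0.97, 1.19, 1.27],  # N
        [-0.54, -0.75, -1.74, -1.07, -1.17, -1.72, -0.06, 0.74, 1.39],  # D
        [-0.75, 0.06, 0.63, 1.50, 0.60, 1.14, -0.53, 1.18, -0.19],  # C
        [0.22, -1.24, -0.46, -1.05, 0.19, -0.42, 0.57, -0.14, -0.12],  # Q
        [0.17, -0.62, -1.65, -1.03, -1.74, -1.78, 1.96, -1.21, -0.27],  # E
        [-2.16, -1.02, -0.19, -0.03, -0.84, -0.99, -1.72, 1.43, 1.73],  # G
        [0.52, -0.46, -0.18, -0.13, -0.56, -0.10, 0.59, -0.27, -0.27],  # H
        [0.21, 1.37, 0.97, 1.52, 1.91, 1.27, 0.06, -1.30, -1.49],  # I
        [0.25, 1.06, 1.01, 1.14, 0.69, 0.02, 0.93, -1.36, -1.14],  # L
        [0.68, -0.16, -1.62, -1.76, -0.86, -1.19, 0.71, 0.40, 0.15],  # K
        [0.44, 0.20, 0.72, 1.00, 0.45, 0.24, 1.39, -1.24, -1.29],  # M
        [1.09, 1.46, 1.24, 1.16, 0.88, 0.48, 0.37, -0.46, -0.75],  # F
        [-0.71, 0.90, 0.21, -0.72, -1.26, 0.86, -1.72, 1.03, 1.98],  # P
        [-1.21, -1.19, -0.33, -0.46, -0.54, 0.22, -0.99, 0.74, 1.02],  # S
        [-0.67, -0.97, 0.01, -0.36, 0.57, 0.86, -0.68, 0.11, 0.14],  # T
        [2.08, 2.06, 1.55, 0.67, 0.61, 0.42, 0.23, 0.83, -0.52],  # W
        [1.34, 1.16, 1.04, -0.07, 1.02, 1.21, -1.25, 0.94, 0.30],  # Y
        [-0.34, 0.42, 0.77, 1.38, 1.84, 1.66, -0.09, -1.63, -1.32],  # V
    ]
)

#: Symbols silently excluded from site means (gaps / missing / ambiguity).
EXCLUDED_SYMBOLS = frozenset("-.?XBZJ")

#: Symbols that are outright invalid in a curated protein alignment.
INVALID_SYMBOLS = frozenset("*")


class AllGapSiteError(ValueError):
    """A site (or set of sites) contains no canonical residue."""

    def __init__(self, sites):
        self.sites = list(sites)
        super().__init__(
            "site(s) with no canonical residue (1-based): "
            + ", ".join(str(s) for s in self.sites)
        )


@dataclass(frozen=True)
class AminoAcidPropertyTable:
    """20 x m table of per-residue physiochemical scale values.

    ``values`` maps one-letter residue codes to property vectors.  The
    shipped table is the 9-factor Kidera set; a user-supplied table with a
    different m is accepted everywhere a table argument exists.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.values) != 20:
            raise ValueError("property table must cover exactly 20 residues")
        widths = {len(v) for v in self.values.values()}
        if len(widths) != 1:
            raise ValueError("ragged property table")
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite property value")

    @property
    def n_properties(self) -> int:
        return len(next(iter(self.values.values())))

    @property
    def property_names(self):
        return tuple(f"P{i}" for i in range(1, self.n_properties + 1))

    def as_array(self) -> np.ndarray:
        """Rows in canonical ``AMINO_ACIDS`` order."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.as_array(), index=list(AMINO_ACIDS), columns=self.property_names
        )

    def __getitem__(self, residue: str) -> np.ndarray:
        return np.asarray(self.values[residue], dtype=float)


def kidera_table() -> AminoAcidPropertyTable:
    """The nine Kidera physiochemical factors for the 20 amino acids."""
    return AminoAcidPropertyTable(
        {a: tuple(row) for a, row in zip(AMINO_ACIDS, _KIDERA)}
    )


@dataclass(frozen=True)
class SiteProfileMatrix:
    """Per-site mean physiochemical property vectors.

    profiles : (n, m) array of site means
    site_ids : 1-based alignment column indices (length n)
    n_sequences_used : number of canonical residues contributing per site
    """

    profiles: np.ndarray
    site_ids: np.ndarray
    n_sequences_used: np.ndarray
    property_names: tuple = PROPERTY_NAMES

    def __post_init__(self):
        object.__setattr__(self, "profiles", np.asarray(self.profiles, dtype=float))
        object.__setattr__(self, "site_ids", np.asarray(self.site_ids, dtype=int))
        object.__setattr__(
            self, "n_sequences_used", np.asarray(self.n_sequences_used, dtype=int)
        )
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be 2-D")
        n = self.profiles.shape[0]
        if self.site_ids.shape != (n,) or self.n_sequences_used.shape != (n,):
            raise ValueError("inconsistent profile matrix fields")
        if not np.all(np.isfinite(self.profiles)):
            raise ValueError("non-finite profile entry")

    @property
    def n_sites(self) -> int:
        return self.profiles.shape[0]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.profiles, columns=list(self.property_names))
        df.insert(0, "site", self.site_ids)
        return df

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_profile_tsv(path) -> SiteProfileMatrix:
    df = pd.read_csv(path, sep="\t")
    props = [c for c in df.columns if c != "site"]
    return SiteProfileMatrix(
        profiles=df[props].to_numpy(float),
        site_ids=df["site"].to_numpy(int),
        n_sequences_used=np.full(len(df), -1),
        property_names=tuple(props),
    )


def _classify(symbols) -> tuple[list[str], int]:
    """Split a column into canonical residues; count exclusions."""
    canonical = []
    for s in symbols:
        u = str(s).upper()
        if u in EXCLUDED_SYMBOLS:
            continue
        if u in INVALID_SYMBOLS:
            raise ValueError(f"invalid residue symbol {s!r} (stop codon?)")
        if u not in AMINO_ACIDS:
            raise ValueError(f"unknown residue symbol {s!r}")
        canonical.append(u)
    return canonical, len(symbols) - len(canonical)


def site_profile(column, table: AminoAcidPropertyTable | None = None) -> np.ndarray:
    """Mean property vector of an alignment column.

    Gaps and ambiguity codes are excluded from both numerator and
    denominator; a column with no canonical residue raises
    :class:`AllGapSiteError`.
    """
    if table is None:
        table = kidera_table()
    if len(column) == 0:
        raise ValueError("empty column")
    canonical, _ = _classify(column)
    if not canonical:
        raise AllGapSiteError([1])
    rows = np.array([table[a] for a in canonical])
    return rows.mean(axis=0)


def profile_matrix(msa, table: AminoAcidPropertyTable | None = None) -> SiteProfileMatrix:
    """Transform an alignment into its n x m site-profile matrix.

    ``msa`` is an :class:`sitepart.alignment.Alignment` (or anything with a
    ``chars`` (n_taxa, n_sites) character array).
    """
    if table is None:
        table = kidera_table()
    chars = np.asarray(msa.chars)
    if chars.ndim != 2:
        raise ValueError("alignment character matrix must be 2-D")
    n_taxa, n_sites = chars.shape

    tab = table.as_array()
    m = tab.shape[1]
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    profiles = np.empty((n_sites, m))
    used = np.empty(n_sites, dtype=int)
    empty_sites = []
    for j in range(n_sites):
        canonical, _ = _classify(chars[:, j])
        if not canonical:
            empty_sites.append(j + 1)
            used[j] = 0
            profiles[j] = np.nan
            continue
        rows = tab[[index[a] for a in canonical]]
        profiles[j] = rows.mean(axis=0)
        used[j] = len(canonical)
    if empty_sites:
        raise AllGapSiteError(empty_sites)
    return SiteProfileMatrix(
        profiles=profiles,
        site_ids=np.arange(1, n_sites + 1),
        n_sequences_used=used,
        property_names=table.property_names,
    )
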