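"""Amino-acid alignment container and FASTA/PHYLIP input-output.

The container keeps the alignment as an (n_taxa, n_sites) character
matrix plus an integer encoding used by the likelihood engine: canonical
residues map to 0..19 in the PAML order, anything unobserved (gap,
ambiguity, unknown) maps to 20 and is treated as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import AMINO_ACIDS, EXCLUDED_SYMBOLS, INVALID_SYMBOLS

__all__ = [
    "Alignment",
    "AlignmentFormatError",
    "read_alignment",
    "write_alignment",
    "MISSING_CODE",
]

#: Integer code of a missing / non-canonical state.
MISSING_CODE = 20

_CODE = {a: i for i, a in enumerate(AMINO_ACIDS)}


class AlignmentFormatError(ValueError):
    pass


@dataclass
class Alignment:
    names: list
    chars: np.ndarray  # (n_taxa, n_sites) single characters

    def __post_init__(self):
        self.chars = np.asarray(self.chars, dtype="<U1")
        if self.chars.ndim != 2:
            raise AlignmentFormatError("ragged alignment: sequences differ in length")
        if len(self.names) != self.chars.shape[0]:
            raise AlignmentFormatError("name/sequence count mismatch")
        seen = set()
        for n in self.names:
            if n in seen:
                raise AlignmentFormatError(f"duplicated taxon name: {n!r}")
            seen.add(n)

    @classmethod
    def from_sequences(cls, names, sequences) -> "Alignment":
        seqs = [str(s).upper() for s in sequences]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        chars = np.array([list(s) for s in seqs], dtype="<U1")
        return cls(list(names), chars)

    @property
    def n_taxa(self) -> int:
        return self.chars.shape[0]

    @property
    def n_sites(self) -> int:
        return self.chars.shape[1]

    def sequence(self, name: str) -> str:
        return "".join(self.chars[self.names.index(name)])

    def codes(self) -> np.ndarray:
        """Integer encoding: 0..19 canonical, 20 missing; '*' is invalid."""
        flat = self.chars.ravel()
        out = np.empty(flat.shape, dtype=np.int8)
        for i, c in enumerate(flat):
            u = c.upper()
            code = _CODE.get(u)
            if code is not None:
                out[i] = code
            elif u in EXCLUDED_SYMBOLS:
                out[i] = MISSING_CODE
            elif u in INVALID_SYMBOLS:
                raise AlignmentFormatError(f"invalid residue symbol {c!r}")
            else:
                raise AlignmentFormatError(f"unknown residue symbol {c!r}")
        return out.reshape(self.chars.shape)

    def subset_sites(self, site_index) -> "Alignment":
        """New alignment keeping 0-based columns ``site_index`` (in order)."""
        idx = np.asarray(site_index, dtype=int)
        return Alignment(list(self.names), self.chars[:, idx])

    def subset_taxa(self, names) -> "Alignment":
        rows = [self.names.index(n) for n in names]
        return Alignment(list(names), self.chars[rows])

    def concatenate(self, other: "Alignment") -> "Alignment":
        if self.names != other.names:
            raise AlignmentFormatError("cannot concatenate: taxa differ")
        return Alignment(list(self.names), np.hstack([self.chars, other.chars]))

    def to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq("".join(row)), id=name, description="")
            for name, row in zip(self.names, self.chars)
        )

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.names == other.names
            and self.chars.shape == other.chars.shape
            and bool(np.all(self.chars == other.chars))
        )


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".faa", ".fas"}:
        return "fasta"
    if suffix in {".phy", ".phylip"}:
        return "phylip"
    with open(path) as fh:
        first = fh.readline()
    return "fasta" if first.startswith(">") else "phylip"


def read_alignment(path, format: str | None = None) -> Alignment:
    """Read a FASTA or (relaxed) PHYLIP amino-acid alignment."""
    path = Path(path)
    fmt = format or _detect_format(path)
    bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unsupported alignment format: {fmt}")
    try:
        bio = AlignIO.read(str(path), bio_fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    aln = Alignment.from_sequences([rec.id for rec in bio], [str(rec.seq) for rec in bio])
    aln.codes()  # validate alphabet eagerly so errors carry the file name
    return aln


def write_alignment(msa: Alignment, path, format: str = "fasta") -> None:
    bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if bio_fmt is None:
        raise ValueError(f"unsupported alignment format: {format}")
    handle = StringIO()
    AlignIO.write(msa.to_biopython(), handle, bio_fmt)
    Path(path).write_text(handle.getvalue())
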