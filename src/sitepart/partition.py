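"""Partition-map files: per-site group labels as TSV.

Columns ``site`` (1-based, contiguous) and ``group`` (1..k, 1 = largest
group); an optional ``# provenance:`` comment records where the
assignment came from (a clustering run id or "random").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment

__all__ = ["write_partition", "read_partition"]


def write_partition(assignment, path, provenance: str | None = None) -> None:
    labels = (
        assignment.labels if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    )
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        fh.write("site\tgroup\n")
        for site, g in enumerate(labels, start=1):
            fh.write(f"{site}\t{int(g)}\n")


def read_partition(path):
    """Returns ``(labels, provenance)``; labels is a 1-based group array."""
    provenance = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            import io

            df = pd.read_csv(io.StringIO(first + fh.read()), sep="\t")
    sites = df["site"].to_numpy(int)
    labels = df["group"].to_numpy(int)
    n = len(sites)
    if not np.array_equal(sites, np.arange(1, n + 1)):
        raise ValueError("partition map must cover sites 1..n contiguously")
    if labels.min() < 1:
        raise ValueError("group labels must be >= 1")
    return labels, provenance
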