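"""FPKM quantification from per-gene fragment counts.

FPKM (fragments per kilobase of transcript per million mapped fragments)
normalizes a fragment count for gene length and library size:

    fpkm = count * 1e9 / (length_nt * total_mapped_fragments)

Counts are expected to derive from uniquely mapped fragments with at most
1% mismatches; that filter belongs to the read mapping that produced the
count table and is recorded here as input provenance, not re-checked.
The library size defaults to the sum of counted fragments over all
annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fragment_count: int
    gene_length: int
    fpkm: float


def fpkm(count: float, length: int, total_mapped: float) -> float:
    """FPKM for one gene. Zero counts give exactly 0.0."""
    if length <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    return count * 1e9 / (length * total_mapped)


def fpkm_table(counts: pd.DataFrame, total_mapped: float | None = None) -> pd.DataFrame:
    """FPKM for every gene in a count table (gene_id, fragment_count, length).

    When ``total_mapped`` is not given, it is the sum of fragment counts in
    the table itself (gene-assigned fragments, not raw reads); the value
    used is stored in ``result.attrs['total_mapped']``.
    """
    required = {"gene_id", "fragment_count", "length"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    if total_mapped is None:
        total_mapped = float(counts["fragment_count"].sum())
    out = counts.copy()
    out["fpkm"] = [
        fpkm(c, l, total_mapped)
        for c, l in zip(out["fragment_count"], out["length"])
    ]
    out.attrs["total_mapped"] = total_mapped
    return out
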