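"""RPKM quantification and expression-class binning.

RPKM = raw reads x 10^9 / (gene length in bp x total mapped reads);
classes: high (RPKM > 50), medium (20 <= RPKM <= 50), low (RPKM < 20).
The published strict inequalities leave the boundary values unassigned; both
are binned as medium so the classes partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import ReadAlignment


@dataclass
class ExpressionRecord:
    gene_id: str
    length: int
    raw_reads: int
    rpkm: float
    expr_class: str | None = None


def count_mapped_reads(alignments: list[ReadAlignment]) -> dict[str, int]:
    """Raw read count per target (first reported alignment counts)."""
    return dict(Counter(a.target_id for a in alignments))


def compute_rpkm(counts: dict[str, int], lengths: dict[str, int],
                 total_mapped: int) -> list[ExpressionRecord]:
    """Length- and depth-normalized expression for every gene in ``lengths``.

    ``total_mapped`` is the number of mapped reads (records kept by the SAM
    reader), not raw sequencer output.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if sum(counts.values()) > total_mapped:
        raise ValueError("summed counts exceed total_mapped")
    records = []
    for gene in sorted(lengths):
        length = lengths[gene]
        if length <= 0:
            raise ValueError(f"non-positive length for gene {gene!r}")
        raw = counts.get(gene, 0)
        rpkm = raw * 1e9 / (length * total_mapped)
        records.append(ExpressionRecord(gene_id=gene, length=length,
                                        raw_reads=raw, rpkm=rpkm))
    return records


def bin_expression(records: list[ExpressionRecord],
                   low_cut: float = 20.0, high_cut: float = 50.0) -> list[ExpressionRecord]:
    """Assign each record its expression class in place (and return them)."""
    for r in records:
        if r.rpkm > high_cut:
            r.expr_class = "high"
        elif r.rpkm < low_cut:
            r.expr_class = "low"
        else:
            r.expr_class = "medium"
    return records


def read_share_by_class(records: list[ExpressionRecord]) -> dict[str, tuple[float, float]]:
    """Per class: (fraction of genes, fraction of mapped reads)."""
    if not records:
        raise ValueError("no expression records")
    total_genes = len(records)
    total_reads = sum(r.raw_reads for r in records)
    out = {}
    for cls in ("high", "medium", "low"):
        in_cls = [r for r in records if r.expr_class == cls]
        gene_frac = len(in_cls) / total_genes
        read_frac = (sum(r.raw_reads for r in in_cls) / total_reads
                     if total_reads else 0.0)
        out[cls] = (gene_frac, read_frac)
    return out
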