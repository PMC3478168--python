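"""Site-class-partitioned divergence between ortholog pairs.

For each aligned region the engine classifies every gapless column by codon
degeneracy (nondegenerate sites, where any base change replaces the amino
acid; fourfold-degenerate sites, where none does) and by CpG context (a base
participating in a CG dinucleotide in either sequence, evaluated on the full
original sequence), then tallies substitutions, transitions and
transversions per class.  Divergence is pooled across loci as total
substitutions over total compared base pairs; the reported standard error is
the across-locus standard error, with the binomial SE as a secondary column.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from .codons import degeneracy, is_transition
from .orthology import AlignedRegionPair

# (region, class) cells emitted for each region
REGION_CLASSES: dict[str, tuple[str, ...]] = {
    "utr5": ("all", "non_cpg", "cpg"),
    "cds": ("all", "non_cpg", "cpg", "nd_all", "nd_noncpg", "nd_cpg",
            "fourd_all", "fourd_noncpg", "fourd_cpg"),
    "utr3": ("all", "non_cpg", "cpg"),
}


@dataclass
class CellTally:
    substitutions: int = 0
    compared: int = 0
    ts: int = 0
    tv: int = 0
    cpg_sites: int = 0
    gc_sites_a: int = 0
    gc_sites_b: int = 0

    def add(self, other: "CellTally") -> None:
        for f in ("substitutions", "compared", "ts", "tv",
                  "cpg_sites", "gc_sites_a", "gc_sites_b"):
            setattr(self, f, getattr(self, f) + getattr(other, f))


@dataclass
class DivergenceSummary:
    """One pooled cell of the divergence report (a Table-5-shaped row)."""

    region: str
    cls: str
    loci: int
    substitutions: int
    compared_bp: int
    divergence_pct: float | None
    se_pct: float | None
    binomial_se_pct: float | None
    ts: int
    tv: int
    ts_tv: float | None
    pct_cpg: float | None
    pct_gc: float | None


def classify_degeneracy(codon_a: str, codon_b: str, position: int) -> str:
    """Degeneracy of one aligned codon position; both codons must agree.

    A column is nd or 4d only when both codons independently give that
    label; stop codons and codons containing N give 'other'.
    """
    la = degeneracy(codon_a, position)
    lb = degeneracy(codon_b, position)
    return la if la == lb else "other"


def cpg_flag(seq: str, i: int) -> bool:
    """Does base i participate in a CG dinucleotide of ``seq``?"""
    if seq[i] == "C":
        return i + 1 < len(seq) and seq[i + 1] == "G"
    if seq[i] == "G":
        return i > 0 and seq[i - 1] == "C"
    return False


def classify_cpg(seq_a: str, seq_b: str, columns) -> list[bool]:
    """Per-column CpG flag: union over the two full sequences (context may
    lie outside the aligned region)."""
    return [cpg_flag(seq_a, i) or cpg_flag(seq_b, j) for i, j in columns]


def count_substitutions(
    aligned: AlignedRegionPair, seq_a: str, seq_b: str,
) -> dict[tuple[str, str], CellTally]:
    """Per-(region, class) substitution tallies for one aligned region.

    Columns containing N in either sequence are excluded from every count.
    Columns whose codons disagree on degeneracy, or whose codon is partial,
    ambiguous or a stop, count in 'all' and the CpG split but in neither the
    nd nor the 4d subset.
    """
    region = aligned.region
    cells: dict[tuple[str, str], CellTally] = {
        (region, cls): CellTally() for cls in REGION_CLASSES[region]
    }
    cpg_flags = classify_cpg(seq_a, seq_b, aligned.columns)
    for k, (i, j) in enumerate(aligned.columns):
        ba, bb = seq_a[i], seq_b[j]
        if ba == "N" or bb == "N":
            continue
        labels = [(region, "all"), (region, "cpg" if cpg_flags[k] else "non_cpg")]
        if region == "cds":
            ph = aligned.phases[k]
            codon_a = seq_a[i - ph : i - ph + 3]
            codon_b = seq_b[j - ph : j - ph + 3]
            if len(codon_a) == 3 and len(codon_b) == 3:
                deg = classify_degeneracy(codon_a, codon_b, ph)
            else:
                deg = "other"
            if deg == "nd":
                labels += [("cds", "nd_all"),
                           ("cds", "nd_cpg" if cpg_flags[k] else "nd_noncpg")]
            elif deg == "4d":
                labels += [("cds", "fourd_all"),
                           ("cds", "fourd_cpg" if cpg_flags[k] else "fourd_noncpg")]
        sub = ba != bb
        ts = sub and is_transition(ba, bb)
        for key in labels:
            cell = cells[key]
            cell.compared += 1
            cell.cpg_sites += cpg_flags[k]
            cell.gc_sites_a += ba in "GC"
            cell.gc_sites_b += bb in "GC"
            if sub:
                cell.substitutions += 1
                cell.ts += ts
                cell.tv += not ts
    return cells


def tally_pair(aligned_regions: list[AlignedRegionPair], seq_a: str,
               seq_b: str) -> dict[tuple[str, str], CellTally]:
    """All cells for one ortholog pair (regions merged into one mapping)."""
    cells: dict[tuple[str, str], CellTally] = {}
    for aligned in aligned_regions:
        for key, tally in count_substitutions(aligned, seq_a, seq_b).items():
            cells.setdefault(key, CellTally()).add(tally)
    return cells


@dataclass
class PairHomology:
    pair_id: str
    compared_bp: int
    substitutions: int
    homology_pct: float


@dataclass
class HomologyStats:
    """Aggregate homology over the CDS of all pairs (a Table-4-shaped block).

    Both dispersion candidates are reported: the standard deviation of the
    per-pair divergence as a proportion and as a percentage.
    """

    n_pairs: int
    total_aligned_kb: float
    mean_aligned_bp: float
    longest_aligned_bp: int
    mean_homology_pct: float
    min_homology_pct: float
    max_homology_pct: float
    sd_divergence_proportion: float | None
    sd_divergence_pct: float | None


def _sd(values: list[float]) -> float | None:
    if len(values) < 2:
        return None
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def summarize_divergence(
    per_pair: list[tuple[str, dict[tuple[str, str], CellTally]]],
    gc_mode: str = "first",
) -> tuple[list[DivergenceSummary], list[PairHomology], HomologyStats | None]:
    """Pool per-pair tallies into the divergence report.

    Pooled divergence divides total substitutions by total compared bp.  The
    %GC column counts G/C bases of the first species by default
    (``gc_mode='mean'`` averages the two).  Cells with zero compared bp are
    emitted with divergence undefined.
    """
    if not per_pair:
        raise ValueError("summarize_divergence needs at least one pair")
    pooled: dict[tuple[str, str], CellTally] = defaultdict(CellTally)
    loci: dict[tuple[str, str], int] = defaultdict(int)
    per_locus_div: dict[tuple[str, str], list[float]] = defaultdict(list)
    for pair_id, cells in per_pair:
        for key, tally in cells.items():
            pooled[key].add(tally)
            if tally.compared > 0:
                loci[key] += 1
                per_locus_div[key].append(100.0 * tally.substitutions / tally.compared)

    rows: list[DivergenceSummary] = []
    for region, classes in REGION_CLASSES.items():
        for cls in classes:
            key = (region, cls)
            if key not in pooled:
                continue
            cell = pooled[key]
            n = cell.compared
            div = 100.0 * cell.substitutions / n if n else None
            sd = _sd(per_locus_div[key])
            se = sd / math.sqrt(loci[key]) if sd is not None else None
            bse = (100.0 * math.sqrt((cell.substitutions / n) * (1 - cell.substitutions / n) / n)
                   if n else None)
            if gc_mode == "mean":
                gc = 100.0 * (cell.gc_sites_a + cell.gc_sites_b) / (2 * n) if n else None
            else:
                gc = 100.0 * cell.gc_sites_a / n if n else None
            rows.append(DivergenceSummary(
                region=region, cls=cls, loci=loci[key],
                substitutions=cell.substitutions, compared_bp=n,
                divergence_pct=div, se_pct=se, binomial_se_pct=bse,
                ts=cell.ts, tv=cell.tv,
                ts_tv=(cell.ts / cell.tv) if cell.tv else None,
                pct_cpg=100.0 * cell.cpg_sites / n if n else None,
                pct_gc=gc,
            ))

    homology: list[PairHomology] = []
    for pair_id, cells in per_pair:
        cds = cells.get(("cds", "all"))
        if cds is None or cds.compared == 0:
            continue
        homology.append(PairHomology(
            pair_id=pair_id, compared_bp=cds.compared,
            substitutions=cds.substitutions,
            homology_pct=100.0 * (1.0 - cds.substitutions / cds.compared),
        ))
    stats = None
    if homology:
        lengths = [h.compared_bp for h in homology]
        hpcts = [h.homology_pct for h in homology]
        div_props = [1.0 - h / 100.0 for h in hpcts]
        stats = HomologyStats(
            n_pairs=len(homology),
            total_aligned_kb=sum(lengths) / 1000.0,
            mean_aligned_bp=sum(lengths) / len(lengths),
            longest_aligned_bp=max(lengths),
            mean_homology_pct=sum(hpcts) / len(hpcts),
            min_homology_pct=min(hpcts),
            max_homology_pct=max(hpcts),
            sd_divergence_proportion=_sd(div_props),
            sd_divergence_pct=_sd([100.0 * p for p in div_props]),
        )
    return rows, homology, stats


# ---------------------------------------------------------------------------
# derived report arithmetic
# ---------------------------------------------------------------------------

def summary_ratios(mean_by_cell: dict[tuple[str, str], float]) -> dict[str, float]:
    """Derived between-class ratios of a divergence report.

    Input maps (region, class) to the mean divergence percentage; output
    holds the 4d/nd ratio and the CpG/non-CpG ratios for CDS and 3'UTR.
    """
    return {
        "fourd_over_nd": mean_by_cell[("cds", "fourd_all")] / mean_by_cell[("cds", "nd_all")],
        "cds_cpg_over_noncpg": mean_by_cell[("cds", "cpg")] / mean_by_cell[("cds", "non_cpg")],
        "utr3_cpg_over_noncpg": mean_by_cell[("utr3", "cpg")] / mean_by_cell[("utr3", "non_cpg")],
    }


def mean_aligned_length_bp(total_aligned_kb: float, loci: int) -> float:
    """Mean aligned length per locus from a report's totals."""
    if loci <= 0:
        raise ValueError("loci must be positive")
    return 1000.0 * total_aligned_kb / loci


def group_identity_by_category(
    pair_homology: list[tuple[tuple[str, str], float]],
    gene_categories: dict[str, list[str]],
    min_members: int = 5,
) -> list[tuple[str, int, float]]:
    """Mean percent identity per annotation category, most divergent first.

    A pair contributes to every category carried by either member gene;
    categories with fewer than ``min_members`` pairs are suppressed.
    """
    groups: dict[str, list[float]] = defaultdict(list)
    for (gene_a, gene_b), hom in pair_homology:
        cats = set(gene_categories.get(gene_a, [])) | set(gene_categories.get(gene_b, []))
        for cat in cats:
            groups[cat].append(hom)
    rows = [(cat, len(vals), sum(vals) / len(vals))
            for cat, vals in groups.items() if len(vals) >= min_members]
    rows.sort(key=lambda r: (r[2], r[0]))
    return rows
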