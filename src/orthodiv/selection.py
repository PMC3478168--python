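"""NG86 Ka/Ks estimation on orthologous coding sequences.

The Nei–Gojobori (1986) counting method: per-codon synonymous site
fractions are averaged between the two sequences; observed differences are
resolved by averaging synonymous/nonsynonymous steps over all minimal
substitution paths between differing codons (paths through stop codons are
excluded; mutations to stop codons count as nonsynonymous in site
counting).  Proportions are corrected with the Jukes–Cantor formula, and a
two-sided Fisher exact test on (differences vs remaining sites) flags pairs
whose Ka/Ks departs from neutrality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from scipy import stats

from .codons import CODON_TO_AA, STOP_CODONS, synonymous_site_fraction


@dataclass
class SiteCounts:
    S: float   # synonymous sites
    N: float   # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences


@dataclass
class KaKsResult:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float | None
    pn: float | None
    Ks: float | None
    Ka: float | None
    ratio: float | None
    fisher_p: float | None
    flag: str = ""


def _codon_sites(codon: str) -> float:
    """Synonymous sites of one codon (0..3)."""
    return sum(synonymous_site_fraction(codon, p) for p in range(3))


def _path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (Sd, Nd) over all minimal substitution paths a -> b.

    Paths passing through a stop codon are excluded; if every path is
    blocked, the stop-passing paths are used as a fallback so the codon pair
    still contributes its differences.
    """
    diff_positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_positions:
        return 0.0, 0.0
    results: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        cur = codon_a
        sd = nd = 0
        hit_stop = False
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else results).append((sd, nd))
    if not results:
        results = blocked
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def ng86_site_counts(codon_seq_a: str, codon_seq_b: str) -> SiteCounts:
    """Synonymous/nonsynonymous sites and differences for two in-frame CDSs.

    Codons containing N or gap characters, and codon pairs where either
    member is a stop codon, are skipped entirely.
    """
    if len(codon_seq_a) != len(codon_seq_b):
        raise ValueError("coding sequences differ in length")
    if len(codon_seq_a) % 3:
        raise ValueError("coding sequence length not divisible by 3")
    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(codon_seq_a), 3):
        ca, cb = codon_seq_a[k : k + 3], codon_seq_b[k : k + 3]
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        S_a += _codon_sites(ca)
        S_b += _codon_sites(cb)
        sd, nd = _path_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    return SiteCounts(S=S, N=N, Sd=Sd, Nd=Nd)


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None where the formula diverges."""
    if p >= 0.75:
        return None
    return abs(-0.75 * math.log(1.0 - 4.0 * p / 3.0))  # abs() normalizes -0.0


def kaks_estimate(counts: SiteCounts, pair_id: str = "") -> KaKsResult:
    """Ka, Ks and their ratio from NG86 counts.

    The ratio is undefined when Ks is zero or either correction diverges;
    such results carry a flag.
    """
    ps = counts.Sd / counts.S if counts.S > 0 else None
    pn = counts.Nd / counts.N if counts.N > 0 else None
    Ks = _jukes_cantor(ps) if ps is not None else None
    Ka = _jukes_cantor(pn) if pn is not None else None
    flag = ""
    if ps is not None and ps >= 0.75 or pn is not None and pn >= 0.75:
        flag = "saturated"
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    elif Ks is not None and Ks == 0.0:
        flag = flag or "ks_zero"
    return KaKsResult(pair_id=pair_id, S=counts.S, N=counts.N,
                      Sd=counts.Sd, Nd=counts.Nd, ps=ps, pn=pn,
                      Ks=Ks, Ka=Ka, ratio=ratio, fisher_p=None, flag=flag)


def fisher_exact_kaks(result: KaKsResult) -> float:
    """Two-sided Fisher exact p for the 2x2 of differences vs remaining sites.

    Table: [[Sd, S - Sd], [Nd, N - Nd]], with the real-valued site counts
    rounded to the nearest integer (the exact test requires integers).
    """
    table = [
        [round(result.Sd), round(result.S - result.Sd)],
        [round(result.Nd), round(result.N - result.Nd)],
    ]
    for row in table:
        for cell in row:
            if cell < 0:
                raise ValueError(f"negative cell after rounding: {table}")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def kaks_pair(codon_seq_a: str, codon_seq_b: str, pair_id: str = "") -> KaKsResult:
    """Full NG86 Ka/Ks with Fisher test for one aligned CDS pair."""
    result = kaks_estimate(ng86_site_counts(codon_seq_a, codon_seq_b), pair_id)
    result.fisher_p = fisher_exact_kaks(result)
    return result
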