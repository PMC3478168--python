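"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — brute-force
enumeration, exact rational arithmetic, or direct per-site simulation — and
never imports the implementation paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@lru_cache(maxsize=None)
def aa(codon: str) -> str:
    return "*" if codon in STOPS else str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# codon degeneracy (brute force via Biopython translation)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def degeneracy_oracle(codon: str, position: int) -> str:
    if codon in STOPS or any(b not in BASES for b in codon):
        return "other"
    ref = aa(codon)
    outcomes = []
    for b in BASES:
        if b == codon[position]:
            continue
        mut = codon[:position] + b + codon[position + 1 :]
        outcomes.append(aa(mut) != ref)
    if all(outcomes):
        return "nd"
    if not any(outcomes):
        return "4d"
    return "other"


@lru_cache(maxsize=None)
def pair_degeneracy_oracle(codon_a: str, codon_b: str, position: int) -> str:
    la = degeneracy_oracle(codon_a, position)
    lb = degeneracy_oracle(codon_b, position)
    return la if la == lb else "other"


# ---------------------------------------------------------------------------
# NG86 (exhaustive path enumeration)
# ---------------------------------------------------------------------------

def ng86_codon_sites_oracle(codon: str) -> float:
    """Synonymous sites of one codon = (synonymous single-base changes)/3,
    counting changes to stop codons as nonsynonymous."""
    ref = aa(codon)
    syn = 0
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if mut not in STOPS and aa(mut) == ref:
                syn += 1
    return syn / 3.0


def ng86_differences_oracle(ca: str, cb: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all minimal paths avoiding stop codons;
    falls back to stop-passing paths when all are blocked."""
    positions = [p for p in range(3) if ca[p] != cb[p]]
    if not positions:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(positions):
        cur, sd, nd, through_stop = ca, 0, 0, False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOPS:
                through_stop = True
            if aa(cur) == aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if through_stop else clean).append((sd, nd))
    paths = clean or dirty
    return (sum(x for x, _ in paths) / len(paths),
            sum(y for _, y in paths) / len(paths))


# ---------------------------------------------------------------------------
# exact tests (rational arithmetic)
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exactly."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


def fisher_two_sided_oracle(table: list[list[int]]) -> Fraction:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    margin-fixed tables no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    total = math.comb(N, c1)

    def prob(x: int) -> Fraction:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), total)

    p_obs = prob(a)
    return sum((prob(x) for x in range(0, min(r1, c1) + 1) if prob(x) <= p_obs),
               Fraction(0))


# ---------------------------------------------------------------------------
# naive Markov clustering (independent reference iteration)
# ---------------------------------------------------------------------------

def naive_mcl_oracle(weights, inflation: float, iters: int = 300) -> list[set[int]]:
    """Plain-list MCL: self-loops = max incident weight, column stochastic,
    square then inflate to a fixed iteration count; clusters = connected
    components of the limit support."""
    n = len(weights)
    m = [[float(weights[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        inc = max(m[i][j] for j in range(n) if j != i) if n > 1 else 0.0
        m[i][i] = inc if inc > 0 else 1.0
    for j in range(n):
        s = sum(m[i][j] for i in range(n))
        for i in range(n):
            m[i][j] /= s
    for _ in range(iters):
        sq = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        for j in range(n):
            col = [sq[i][j] ** inflation for i in range(n)]
            s = sum(col)
            for i in range(n):
                sq[i][j] = col[i] / s if s else 0.0
        m = sq
    adj = [[m[i][j] > 1e-9 or m[j][i] > 1e-9 for j in range(n)] for i in range(n)]
    seen, comps = set(), []
    for s0 in range(n):
        if s0 in seen:
            continue
        stack, comp = [s0], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(u for u in range(n) if adj[v][u] and u not in comp)
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# per-site Monte-Carlo divergence oracle
# ---------------------------------------------------------------------------

class SiteClassOracle:
    """Direct per-site simulation of the generative substitution model,
    measured with the downstream classification rules.

    Simulates one long contiguous ancestral CDS (uniform sense codons) and
    one UTR tract, evolves two copies along branches t1 and t2 under the
    declared model (frozen ancestral CpG context and nd class, transition
    bias kappa, acceptance thinning of amino-acid changes, stop-codon
    rejection), then classifies every column the way the divergence engine
    declares (observed-union CpG, both-codon degeneracy agreement) and
    returns per-class divergence with its Monte-Carlo standard error.
    """

    def __init__(self, t1: float, t2: float, kappa: float, cpg_mult: float,
                 f_nd: float, f_ns: float, utr_rate_mult: float, seed: int):
        self.t1, self.t2 = t1, t2
        self.kappa = kappa
        self.cpg_mult = cpg_mult
        self.f_nd, self.f_ns = f_nd, f_ns
        self.utr_rate_mult = utr_rate_mult
        self.rng = np.random.default_rng(seed)

    # -- shared machinery ---------------------------------------------------

    def _cpg_flags(self, seq: str) -> np.ndarray:
        flags = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                flags[i] = flags[i + 1] = True
        return flags

    def _propose(self, cur: str) -> str:
        if self.rng.random() < self.kappa / (self.kappa + 2.0):
            return TRANSITION[cur]
        alts = [b for b in BASES if b != cur and b != TRANSITION[cur]]
        return alts[int(self.rng.integers(2))]

    def _evolve_cds(self, anc: str, t: float, cpg: np.ndarray,
                    nd: np.ndarray) -> str:
        rates = np.full(len(anc), t)
        rates[cpg] *= self.cpg_mult
        counts = self.rng.poisson(rates)
        seq = list(anc)
        for pos in np.flatnonzero(counts):
            for _ in range(counts[pos]):
                cur = seq[pos]
                new = self._propose(cur)
                ci, ph = divmod(pos, 3)
                codon = "".join(seq[3 * ci : 3 * ci + 3])
                mut = codon[:ph] + new + codon[ph + 1 :]
                if mut in STOPS:
                    continue
                if aa(mut) != aa(codon):
                    f = self.f_nd if nd[pos] else self.f_ns
                    if self.rng.random() >= f:
                        continue
                seq[pos] = new
        return "".join(seq)

    def _evolve_utr(self, anc: str, t: float, cpg: np.ndarray) -> str:
        rates = np.full(len(anc), t * self.utr_rate_mult)
        rates[cpg] *= self.cpg_mult
        seq = list(anc)
        counts = self.rng.poisson(rates)
        for pos in np.flatnonzero(counts):
            for _ in range(counts[pos]):
                seq[pos] = self._propose(seq[pos])
        return "".join(seq)

    # -- public measurements ------------------------------------------------

    def cds_expectations(self, n_codons: int) -> dict[str, tuple[float, float]]:
        """Per-class (divergence, MC standard error) for a CDS tract."""
        sense = sorted(set(
            a + b + c for a in BASES for b in BASES for c in BASES
        ) - STOPS)
        idx = self.rng.integers(0, len(sense), size=n_codons)
        anc = "".join(sense[i] for i in idx)
        cpg = self._cpg_flags(anc)
        nd = np.zeros(len(anc), dtype=bool)
        for ci in range(n_codons):
            codon = anc[3 * ci : 3 * ci + 3]
            for ph in range(3):
                nd[3 * ci + ph] = degeneracy_oracle(codon, ph) == "nd"
        s1 = self._evolve_cds(anc, self.t1, cpg, nd)
        s2 = self._evolve_cds(anc, self.t2, cpg, nd)

        cpg1, cpg2 = self._cpg_flags(s1), self._cpg_flags(s2)
        cpg_obs = cpg1 | cpg2
        tallies: dict[str, list[int]] = {
            k: [0, 0] for k in ("all", "non_cpg", "cpg", "nd_all", "fourd_all")
        }
        for pos in range(len(anc)):
            ci, ph = divmod(pos, 3)
            ca, cb = s1[3 * ci : 3 * ci + 3], s2[3 * ci : 3 * ci + 3]
            sub = s1[pos] != s2[pos]
            keys = ["all", "cpg" if cpg_obs[pos] else "non_cpg"]
            deg = pair_degeneracy_oracle(ca, cb, ph)
            if deg == "nd":
                keys.append("nd_all")
            elif deg == "4d":
                keys.append("fourd_all")
            for k in keys:
                tallies[k][0] += sub
                tallies[k][1] += 1
        return {k: (s / n, math.sqrt((s / n) * (1 - s / n) / n))
                for k, (s, n) in tallies.items() if n}

    @staticmethod
    def _best_diagonal_block(s1: str, s2: str, match: float = 2.0,
                             mismatch: float = 3.0) -> tuple[int, int]:
        """Maximum-scoring contiguous segment of the match/mismatch score
        profile (Kadane) — the on-diagonal optimum of a local alignment of
        two equal-length indel-free sequences."""
        best_score = cur_score = 0.0
        best = (0, 0)
        cur_start = 0
        for i, (a, b) in enumerate(zip(s1, s2)):
            cur_score += match if a == b else -mismatch
            if cur_score <= 0:
                cur_score = 0.0
                cur_start = i + 1
            elif cur_score > best_score:
                best_score = cur_score
                best = (cur_start, i + 1)
        return best

    def utr_expectations(self, n_pairs: int, len_range: tuple[int, int],
                         min_block: int = 30,
                         min_ident: float = 70.0) -> dict[str, tuple[float, float]]:
        """Per-class (divergence, MC SE) for UTR tracts, measured the way
        the pipeline measures them: best local block per pair, kept only
        when it clears the length and identity stringency."""
        tallies = {k: [0, 0] for k in ("all", "non_cpg", "cpg")}
        for _ in range(n_pairs):
            n = int(self.rng.integers(len_range[0], len_range[1] + 1))
            anc = "".join(BASES[i] for i in self.rng.integers(0, 4, size=n))
            cpg = self._cpg_flags(anc)
            s1 = self._evolve_utr(anc, self.t1, cpg)
            s2 = self._evolve_utr(anc, self.t2, cpg)
            lo, hi = self._best_diagonal_block(s1, s2)
            if hi - lo < min_block:
                continue
            matches = sum(1 for k in range(lo, hi) if s1[k] == s2[k])
            if 100.0 * matches / (hi - lo) < min_ident:
                continue
            cpg_obs = self._cpg_flags(s1) | self._cpg_flags(s2)
            for pos in range(lo, hi):
                sub = s1[pos] != s2[pos]
                for k in ("all", "cpg" if cpg_obs[pos] else "non_cpg"):
                    tallies[k][0] += sub
                    tallies[k][1] += 1
        return {k: (s / n, math.sqrt((s / n) * (1 - s / n) / n))
                for k, (s, n) in tallies.items() if n}
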