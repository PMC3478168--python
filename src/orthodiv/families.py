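"""Protein-family clustering across three species and core-family enrichment.

Translated genes become nodes of an undirected similarity graph (edge weight
is the larger bitscore of the two directed hits); Markov clustering with
inflation 1.6 partitions the graph into families; families with members from
all three species are the core, and per-term overrepresentation in the core
is scored with the exact hypergeometric upper tail.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codons import reverse_complement, translate
from .io_formats import SimilarityHit, TranscriptRecord, log


@dataclass
class TranslatedGene:
    gene_id: str
    species: str
    protein: str
    nt_span: int  # nucleotide span of the translated region


@dataclass
class ProteinFamily:
    family_id: int
    members: dict[str, list[str]]  # species -> gene ids
    is_core: bool
    converged: bool = True

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(sp for sp, m in self.members.items() if m)


def prepare_translations(
    transcripts: list[TranscriptRecord],
    protein_hits: list[SimilarityHit],
    min_nt_len: int = 200,
    evalue_max: float = 1e-5,
) -> list[TranslatedGene]:
    """Longest translated region per gene, from its frame-bearing hits.

    Only hits below ``evalue_max`` count; genes whose longest translated
    region spans fewer than ``min_nt_len`` nucleotides are dropped, as are
    genes without any qualifying hit.
    """
    by_id = {t.id: t for t in transcripts}
    best_span: dict[str, SimilarityHit] = {}
    for h in protein_hits:
        if h.evalue >= evalue_max or h.query not in by_id:
            continue
        span = h.q_end - h.q_start + 1
        cur = best_span.get(h.query)
        if cur is None or span > (cur.q_end - cur.q_start + 1):
            best_span[h.query] = h
    out: list[TranslatedGene] = []
    for t in transcripts:
        h = best_span.get(t.id)
        if h is None:
            continue
        span = h.q_end - h.q_start + 1
        if span < min_nt_len:
            continue
        seq = t.seq if h.frame >= 0 else reverse_complement(t.seq)
        start = (h.q_start - 1) if h.frame >= 0 else (len(seq) - h.q_end)
        region = seq[start : start + span - span % 3]
        out.append(TranslatedGene(gene_id=t.id, species=t.species,
                                  protein=translate(region), nt_span=span))
    log.info("prepare_translations: %d of %d genes kept", len(out), len(transcripts))
    return out


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def build_similarity_graph(
    nodes: list[str], hits: list[SimilarityHit],
) -> tuple[list[str], np.ndarray]:
    """Symmetric weight matrix: max bitscore over the two directed hits.

    Self-hits are ignored (self-loops are added by the clustering step).
    """
    index = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for h in hits:
        i, j = index.get(h.query), index.get(h.subject)
        if i is None or j is None or i == j:
            continue
        if h.bitscore > w[i, j]:
            w[i, j] = w[j, i] = h.bitscore
    return nodes, w


def mcl_cluster_matrix(
    weights: np.ndarray, inflation: float = 1.6,
    tol: float = 1e-8, max_iter: int = 200, prune: float = 1e-12,
) -> tuple[list[list[int]], bool]:
    """Markov clustering of a symmetric non-negative weight matrix.

    Self-loops are set to each node's maximum incident weight (isolated
    nodes get 1) before column normalization; iteration alternates
    expansion (matrix square) and inflation (entrywise power, renormalize)
    with per-column pruning of entries below ``prune``, until the largest
    entry change drops below ``tol`` or ``max_iter`` is reached.  Clusters
    are the weakly connected components of the limit matrix's support.
    Returns (clusters as index lists, converged flag).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = weights.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    m = weights.astype(float).copy()
    np.fill_diagonal(m, 0.0)
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        log.warning("mcl_cluster: no convergence after %d iterations", max_iter)
    # clusters: connected components of the support of the limit matrix
    support = (m > prune) | (m.T > prune)
    np.fill_diagonal(support, True)
    seen = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.flatnonzero(support[v]):
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        clusters.append(sorted(comp))
    clusters.sort(key=lambda c: c[0])
    return clusters, converged


def mcl_cluster(
    genes: list[TranslatedGene], hits: list[SimilarityHit],
    inflation: float = 1.6, **kwargs,
) -> list[ProteinFamily]:
    """Cluster translated genes into protein families (singletons allowed)."""
    nodes = sorted(g.gene_id for g in genes)
    species_of = {g.gene_id: g.species for g in genes}
    _, w = build_similarity_graph(nodes, hits)
    clusters, converged = mcl_cluster_matrix(w, inflation=inflation, **kwargs)
    families = []
    species_all = sorted({g.species for g in genes})
    for fid, idxs in enumerate(clusters):
        members: dict[str, list[str]] = {sp: [] for sp in species_all}
        for i in idxs:
            members[species_of[nodes[i]]].append(nodes[i])
        families.append(ProteinFamily(
            family_id=fid, members=members,
            is_core=all(members[sp] for sp in species_all),
            converged=converged,
        ))
    return families


def classify_families(families: list[ProteinFamily]) -> dict[frozenset[str], int]:
    """Venn counts: number of families per species-composition category."""
    counts: dict[frozenset[str], int] = defaultdict(int)
    for fam in families:
        counts[fam.species_set] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    term: str
    k_core: int              # annotated core genes carrying the term
    K_population: int        # annotated genes carrying the term
    n_core: int              # annotated core genes (draws)
    N_population: int        # annotated genes (population)
    per_species: dict[str, int]
    p_value: float
    p_bonferroni: float


def hypergeom_enrichment(
    core_genes: set[str], all_genes: set[str],
    annotations: dict[str, list[str]], alpha: float = 1e-5,
    species_of: dict[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Exact hypergeometric over-representation of terms among core genes.

    The urn is restricted to annotated genes: population = annotated genes
    in ``all_genes``, successes = those carrying the term, draws = annotated
    core genes.  p = P(X >= k).  Terms below ``alpha`` (raw, as the cutoff
    is applied without correction) are returned with Bonferroni-adjusted
    values in a side column, sorted by p then term.
    """
    if not core_genes <= all_genes:
        raise ValueError("core gene set must be a subset of the population")
    annotated = {g for g in all_genes if annotations.get(g)}
    core_annotated = core_genes & annotated
    N, n = len(annotated), len(core_annotated)
    term_all: dict[str, set[str]] = defaultdict(set)
    for g in annotated:
        for t in annotations[g]:
            term_all[t].add(g)
    n_terms = len(term_all)
    rows = []
    for term in sorted(term_all):
        carriers = term_all[term]
        K = len(carriers)
        k = len(carriers & core_annotated)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        if p >= alpha:
            continue
        per_species: dict[str, int] = defaultdict(int)
        if species_of:
            for g in carriers & core_annotated:
                per_species[species_of[g]] += 1
        rows.append(EnrichmentRow(
            term=term, k_core=k, K_population=K, n_core=n, N_population=N,
            per_species=dict(per_species), p_value=p,
            p_bonferroni=min(1.0, p * n_terms),
        ))
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows
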