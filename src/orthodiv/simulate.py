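"""Synthetic three-species transcriptome generator with known ground truth.

Emulates the generative structure behind a three-species comparative
transcriptome study: ortholog triples descend from codon-structured common
ancestors along the unrooted tree (A, B, C) with per-site-class substitution
rates — hypermutable CpG dinucleotides, a transition bias kappa, purifying
constraint at nondegenerate sites — plus UTR flanks with their own rate,
planted paralogs, log-normally distributed read abundances (74-bp reads) and
planted heterozygous SNPs.  Every simulated feature is registered in a
TruthTable so each downstream stage can be scored against ground truth.

Conventions that downstream classification relies on:

* CpG context is defined on the ancestor and frozen; the rate multiplier
  never re-evaluates context after a mutation.
* A site's nd/4d class for the acceptance step is likewise frozen at the
  ancestral codon.
* Mutations creating a stop codon are always rejected, so CDS structure
  (ATG .. single terminal stop) survives evolution.
* No indels: orthologs keep identical lengths and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import codons
from .io_formats import ReadAlignment, SimilarityHit, TranscriptRecord

SPECIES = ("A", "B", "C")


@dataclass
class EvolParams:
    """Evolutionary and sampling parameters of the generator.

    Branch lengths are expected substitutions per site (before class
    multipliers and acceptance thinning) on the unrooted three-taxon tree.
    """

    n_genes: int = 500
    cds_len_range: tuple[int, int] = (300, 900)
    utr5_len_range: tuple[int, int] = (20, 100)
    utr3_len_range: tuple[int, int] = (40, 160)
    t_A: float = 0.02
    t_B: float = 0.005
    t_C: float = 0.005
    kappa: float = 4.0
    cpg_mult: float = 6.0
    f_nd: float = 0.1
    f_ns: float = 0.3
    utr_rate_mult: float = 1.7
    paralog_frac: float = 0.1
    het_rate: float = 0.1
    read_len: int = 74
    mean_coverage: float = 30.0
    abundance_sigma: float = 1.2
    loss_frac: float = 0.15
    spurious_hit_rate: float = 0.02
    read_error_rate: float = 0.0
    cpg_ts_only: bool = False   # deamination mode: CpG-site proposals are C->T/G->A only
    seed: int = 0

    def branch(self, species: str) -> float:
        return {"A": self.t_A, "B": self.t_B, "C": self.t_C}[species]

    def validate(self) -> None:
        for name in ("cds_len_range", "utr5_len_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"degenerate range {name}={lo, hi}")
        if self.cds_len_range[0] < 9:
            raise ValueError("CDS length range must allow start + codon + stop")
        for name in ("t_A", "t_B", "t_C", "kappa", "cpg_mult", "utr_rate_mult",
                     "het_rate", "mean_coverage", "paralog_frac", "loss_frac",
                     "spurious_hit_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f_nd", "f_ns"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")


@dataclass
class PlantedSnp:
    species: str
    gene_id: str
    pos: int            # 0-based transcript coordinate
    ref: str
    alt: str
    freq: float


@dataclass
class Mutation:
    pos: int
    ref: str
    alt: str


@dataclass
class GeneTruth:
    """Ground truth for one ancestral gene and its descendants."""

    anc_id: str
    anc_seq: str
    cds_start: int      # 0-based half-open; CDS includes the stop codon
    cds_end: int
    present: dict[str, bool]
    gene_ids: dict[str, str]
    mutations: dict[str, list[Mutation]] = field(default_factory=dict)
    abundance: float = 0.0
    protein_id: str = ""


@dataclass
class TruthTable:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    # paralog transcript id -> the transcript it duplicates (same species)
    paralogs: dict[str, str] = field(default_factory=dict)
    snps: list[PlantedSnp] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def ortholog_pairs(self, sp1: str, sp2: str) -> list[tuple[str, str]]:
        """True one-to-one ortholog pairs between two species."""
        out = []
        for g in self.genes.values():
            if g.present[sp1] and g.present[sp2]:
                out.append((g.gene_ids[sp1], g.gene_ids[sp2]))
        return out


def _gene_rng(seed: int, stage: int, index: int) -> np.random.Generator:
    """Per-gene substream so partial re-runs reproduce (single seed keys all)."""
    return np.random.default_rng([seed, stage, index])


# ---------------------------------------------------------------------------
# ancestors
# ---------------------------------------------------------------------------

def simulate_ancestors(params: EvolParams) -> tuple[list[TranscriptRecord], TruthTable]:
    """Codon-structured ancestral genes: 5'UTR + (ATG .. sense codons .. stop) + 3'UTR."""
    params.validate()
    truth = TruthTable()
    records = []
    sense = [c for c in codons.SENSE_CODONS]
    stops = sorted(codons.STOP_CODONS)
    for i in range(params.n_genes):
        rng = _gene_rng(params.seed, 0, i)
        n_codons = int(rng.integers(params.cds_len_range[0] // 3,
                                    params.cds_len_range[1] // 3 + 1))
        utr5_len = int(rng.integers(params.utr5_len_range[0], params.utr5_len_range[1] + 1))
        utr3_len = int(rng.integers(params.utr3_len_range[0], params.utr3_len_range[1] + 1))
        body = "".join(rng.choice(sense) for _ in range(max(n_codons - 2, 1)))
        cds = "ATG" + body + stops[rng.integers(len(stops))]
        utr5 = "".join(rng.choice(list(codons.BASES), size=utr5_len))
        utr3 = "".join(rng.choice(list(codons.BASES), size=utr3_len))
        anc_id = f"anc{i:05d}"
        seq = utr5 + cds + utr3
        truth.genes[anc_id] = GeneTruth(
            anc_id=anc_id,
            anc_seq=seq,
            cds_start=utr5_len,
            cds_end=utr5_len + len(cds),
            present={sp: True for sp in SPECIES},
            gene_ids={sp: f"{sp}_{anc_id}" for sp in SPECIES},
            mutations={sp: [] for sp in SPECIES},
            protein_id=f"P_{anc_id}",
        )
        records.append(TranscriptRecord(id=anc_id, species="ancestor", seq=seq))
    return records, truth


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def ancestral_cpg_flags(seq: str) -> np.ndarray:
    """Boolean flag per site: participates in a CG dinucleotide of ``seq``."""
    flags = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            flags[i] = True
            flags[i + 1] = True
    return flags


def _site_rates(gene: GeneTruth, t: float, params: EvolParams) -> np.ndarray:
    rates = np.full(len(gene.anc_seq), t)
    cpg = ancestral_cpg_flags(gene.anc_seq)
    rates[cpg] *= params.cpg_mult
    utr = np.ones(len(gene.anc_seq), dtype=bool)
    utr[gene.cds_start : gene.cds_end] = False
    rates[utr] *= params.utr_rate_mult
    return rates


def _ancestral_nd_flags(gene: GeneTruth) -> np.ndarray:
    """Per-site flag: nondegenerate in the ancestral codon (CDS sense codons only)."""
    flags = np.zeros(len(gene.anc_seq), dtype=bool)
    for cstart in range(gene.cds_start, gene.cds_end, 3):
        codon = gene.anc_seq[cstart : cstart + 3]
        if codon in codons.STOP_CODONS:
            continue
        for phase in range(3):
            flags[cstart + phase] = codons.degeneracy(codon, phase) == "nd"
    return flags


def evolve_sequence(gene: GeneTruth, t: float, params: EvolParams,
                    rng: np.random.Generator) -> tuple[str, list[Mutation]]:
    """Evolve one gene copy along a branch of nominal length ``t``.

    Proposal counts are Poisson(t x class multiplier) per site; proposed
    target bases favor transitions by kappa; acceptance thins amino-acid
    changing proposals by f_nd (ancestrally nondegenerate sites) or f_ns
    (other coding sites); synonymous and UTR proposals are always accepted;
    proposals creating a stop codon are always rejected.
    """
    seq = list(gene.anc_seq)
    rates = _site_rates(gene, t, params)
    nd_flags = _ancestral_nd_flags(gene)
    cpg_flags = ancestral_cpg_flags(gene.anc_seq)
    n_props = rng.poisson(rates)
    mutations: list[Mutation] = []
    p_ts = params.kappa / (params.kappa + 2.0)
    in_cds = lambda p: gene.cds_start <= p < gene.cds_end
    for pos in np.flatnonzero(n_props):
        for _ in range(n_props[pos]):
            cur = seq[pos]
            if params.cpg_ts_only and cpg_flags[pos]:
                new = codons.TRANSITION[cur]
            elif rng.random() < p_ts:
                new = codons.TRANSITION[cur]
            else:
                tvs = [b for b in codons.BASES if b != cur and b != codons.TRANSITION[cur]]
                new = tvs[int(rng.integers(2))]
            if in_cds(pos):
                phase = (pos - gene.cds_start) % 3
                cstart = pos - phase
                old_codon = "".join(seq[cstart : cstart + 3])
                new_codon = old_codon[:phase] + new + old_codon[phase + 1 :]
                old_aa = codons.CODON_TO_AA[old_codon]
                new_aa = codons.CODON_TO_AA[new_codon]
                if new_aa == "*" and old_aa != "*":
                    continue  # never create a stop
                if old_aa == "*":
                    if new_aa != "*":
                        continue  # never destroy the terminal stop
                elif new_aa != old_aa:
                    f_accept = params.f_nd if nd_flags[pos] else params.f_ns
                    if rng.random() >= f_accept:
                        continue
            seq[pos] = new
            mutations.append(Mutation(pos=int(pos), ref=cur, alt=new))
    return "".join(seq), mutations


def evolve_triple(ancestors: list[TranscriptRecord], params: EvolParams,
                  truth: TruthTable) -> dict[str, list[TranscriptRecord]]:
    """Evolve each ancestor independently along the three terminal branches.

    A ``loss_frac`` fraction of genes is dropped from one species chosen at
    random, so that non-core protein families exist downstream.
    """
    species_sets: dict[str, list[TranscriptRecord]] = {sp: [] for sp in SPECIES}
    for i, anc in enumerate(ancestors):
        gene = truth.genes[anc.id]
        rng = _gene_rng(params.seed, 1, i)
        if rng.random() < params.loss_frac:
            lost = SPECIES[int(rng.integers(3))]
            gene.present[lost] = False
        for sp in SPECIES:
            seq, muts = evolve_sequence(gene, params.branch(sp), params, rng)
            if not gene.present[sp]:
                continue
            gene.mutations[sp] = muts
            species_sets[sp].append(
                TranscriptRecord(id=gene.gene_ids[sp], species=sp, seq=seq)
            )
    return species_sets


def plant_paralogs(species_sets: dict[str, list[TranscriptRecord]],
                   params: EvolParams, truth: TruthTable) -> dict[str, list[TranscriptRecord]]:
    """Duplicate a fraction of genes within one species with extra divergence.

    The duplicate evolves from the retained species copy for an extra branch
    of twice that species' length, emulating an older within-genome
    duplication that the same-reference-protein filter must reject.
    """
    out = {sp: list(records) for sp, records in species_sets.items()}
    by_id = {r.id: r for records in species_sets.values() for r in records}
    eligible = [a for a in sorted(truth.genes)
                if any(truth.genes[a].present[sp] for sp in SPECIES)]
    n_dup = round(params.paralog_frac * len(eligible))
    pick_rng = np.random.default_rng([params.seed, 2])
    chosen = sorted(pick_rng.choice(len(eligible), size=n_dup, replace=False)) \
        if n_dup else []
    for i in chosen:
        anc_id = eligible[int(i)]
        gene = truth.genes[anc_id]
        rng = _gene_rng(params.seed, 2, int(i))
        hosts = [sp for sp in SPECIES if gene.present[sp]]
        host = hosts[int(rng.integers(len(hosts)))]
        source = by_id[gene.gene_ids[host]]
        shifted = replace(gene, anc_seq=source.seq)  # evolve from the extant copy
        seq, _ = evolve_sequence(shifted, 2.0 * params.branch(host), params, rng)
        dup_id = source.id + "_dup"
        out[host].append(TranscriptRecord(id=dup_id, species=host, seq=seq))
        truth.paralogs[dup_id] = source.id
    return out


# ---------------------------------------------------------------------------
# reads and SNPs
# ---------------------------------------------------------------------------

def simulate_reads(species_set: list[TranscriptRecord], params: EvolParams,
                   truth: TruthTable) -> list[ReadAlignment]:
    """Error-free ungapped reads with log-normal per-gene abundance.

    Expected read count is abundance x transcript length; counts are Poisson
    around that expectation so coverage fluctuates like shotgun data.  Genes
    carrying planted heterozygous SNPs emit reads from two haplotypes at the
    registered allele frequency.  Transcripts shorter than the read length
    are skipped with a warning count in the log.
    """
    from .io_formats import log

    truth_by_id = {g.gene_ids[sp]: g for g in truth.genes.values()
                   for sp in SPECIES if g.present[sp]}
    mean_abund = float(np.exp(params.abundance_sigma ** 2 / 2.0))
    reads: list[ReadAlignment] = []
    skipped = 0
    for i, rec in enumerate(species_set):
        rng = _gene_rng(params.seed, 3, i)
        if len(rec.seq) < params.read_len:
            skipped += 1
            continue
        gene = truth_by_id.get(rec.id)
        abundance = float(rng.lognormal(0.0, params.abundance_sigma))
        if gene is not None:
            gene.abundance = abundance
        expected = (abundance / mean_abund) * params.mean_coverage \
            * len(rec.seq) / params.read_len
        n_reads = int(rng.poisson(expected))
        # plant heterozygous SNPs inside the CDS (truth coordinates)
        hap_alt = None
        gene_snps: list[PlantedSnp] = []
        if gene is not None and params.het_rate > 0:
            n_snps = int(rng.poisson(params.het_rate))
            if n_snps:
                hap = list(rec.seq)
                positions = set()
                for _ in range(n_snps):
                    pos = int(rng.integers(gene.cds_start, gene.cds_end - 3))
                    if pos in positions:
                        continue
                    positions.add(pos)
                    ref = rec.seq[pos]
                    alt = [b for b in codons.BASES if b != ref][int(rng.integers(3))]
                    hap[pos] = alt
                    snp = PlantedSnp(species=rec.species, gene_id=rec.id,
                                     pos=pos, ref=ref, alt=alt, freq=0.5)
                    gene_snps.append(snp)
                    truth.snps.append(snp)
                hap_alt = "".join(hap)
        max_start = len(rec.seq) - params.read_len
        for j in range(n_reads):
            start = int(rng.integers(0, max_start + 1))
            template = rec.seq
            if hap_alt is not None and rng.random() < gene_snps[0].freq:
                template = hap_alt
            read_seq = template[start : start + params.read_len]
            if params.read_error_rate > 0:
                bases = list(read_seq)
                for k in np.flatnonzero(rng.random(params.read_len) < params.read_error_rate):
                    bases[k] = codons.BASES[int(rng.integers(4))]
                read_seq = "".join(bases)
            reads.append(ReadAlignment(
                read_id=f"{rec.id}_r{j:06d}", target_id=rec.id, pos=start + 1,
                cigar=[("M", params.read_len)], seq=read_seq,
            ))
    if skipped:
        log.warning("simulate_reads: %d transcripts shorter than read_len skipped", skipped)
    return reads


# ---------------------------------------------------------------------------
# similarity tables
# ---------------------------------------------------------------------------

def _identity(seq1: str, seq2: str) -> tuple[int, float]:
    matches = sum(1 for a, b in zip(seq1, seq2) if a == b)
    return matches, 100.0 * matches / max(len(seq1), 1)


def _hit(query: str, subject: str, seq_q: str, seq_s: str, frame: int = 0) -> SimilarityHit:
    matches, pct = _identity(seq_q, seq_s)
    length = min(len(seq_q), len(seq_s))
    bitscore = round(2.0 * matches, 1)
    evalue = 10.0 ** (-min(bitscore / 10.0, 180.0))
    return SimilarityHit(
        query=query, subject=subject, pct_identity=round(pct, 2),
        aln_length=length, mismatches=length - matches, gap_opens=0,
        q_start=1, q_end=len(seq_q), s_start=1, s_end=len(seq_s),
        evalue=evalue, bitscore=bitscore, frame=frame,
    )


def simulate_similarity_tables(
    species_sets: dict[str, list[TranscriptRecord]],
    params: EvolParams, truth: TruthTable,
) -> dict[tuple[str, str], list[SimilarityHit]]:
    """Nucleotide hit tables for each ordered species pair touching species A.

    Every true homology (shared ancestor, including planted paralogs) yields a
    hit whose identity is the observed identity and whose e-value decreases
    with score; spurious unrelated hits appear at high e-value at rate
    ``spurious_hit_rate`` per query.
    """
    by_id = {r.id: r for records in species_sets.values() for r in records}
    members: dict[str, dict[str, list[str]]] = {}  # anc -> species -> ids
    for g in truth.genes.values():
        members[g.anc_id] = {sp: [g.gene_ids[sp]] for sp in SPECIES if g.present[sp]}
    for dup_id, src_id in truth.paralogs.items():
        sp = dup_id.split("_", 1)[0]
        anc = "anc" + src_id.split("anc", 1)[1].split("_")[0]
        members[anc].setdefault(sp, []).append(dup_id)

    tables: dict[tuple[str, str], list[SimilarityHit]] = {}
    for qsp, ssp in (("A", "B"), ("B", "A"), ("A", "C"), ("C", "A")):
        hits: list[SimilarityHit] = []
        subject_ids = sorted(r.id for r in species_sets[ssp])
        rng = np.random.default_rng([params.seed, 4, ord(qsp), ord(ssp)])
        for rec in species_sets[qsp]:
            anc = "anc" + rec.id.split("anc", 1)[1].split("_")[0]
            for sid in members[anc].get(ssp, []):
                hits.append(_hit(rec.id, sid, rec.seq, by_id[sid].seq))
            if rng.random() < params.spurious_hit_rate and subject_ids:
                other = subject_ids[int(rng.integers(len(subject_ids)))]
                if other not in members[anc].get(ssp, []):
                    L = 40
                    hits.append(SimilarityHit(
                        query=rec.id, subject=other, pct_identity=68.0,
                        aln_length=L, mismatches=13, gap_opens=0,
                        q_start=1, q_end=L, s_start=1, s_end=L,
                        evalue=float(rng.uniform(1e-4, 1.0)), bitscore=30.0,
                    ))
        tables[(qsp, ssp)] = hits
    return tables


def reference_proteins(truth: TruthTable) -> list[TranscriptRecord]:
    """Translated ancestral CDSs standing in for the reference protein database.

    Synthetic stand-ins: id ``P_<ancestor>``, one protein per ancestral gene,
    stop codon excluded.
    """
    out = []
    for anc_id in sorted(truth.genes):
        g = truth.genes[anc_id]
        prot = codons.translate(g.anc_seq[g.cds_start : g.cds_end - 3])
        out.append(TranscriptRecord(id=g.protein_id, species="ref", seq=prot))
    return out


def simulate_protein_hits(
    species_sets: dict[str, list[TranscriptRecord]],
    params: EvolParams, truth: TruthTable,
) -> dict[str, list[SimilarityHit]]:
    """Transcript-vs-reference-protein hits (13-column, frame filled).

    Each transcript, paralogs included, hits its own ancestor's protein with
    exact CDS coordinates; identity is the observed amino-acid identity.
    """
    out: dict[str, list[SimilarityHit]] = {}
    gene_by_anc = truth.genes
    for sp in SPECIES:
        hits = []
        for rec in species_sets[sp]:
            anc = "anc" + rec.id.split("anc", 1)[1].split("_")[0]
            g = gene_by_anc[anc]
            n_res = (g.cds_end - g.cds_start) // 3 - 1  # minus the stop
            prot_q = codons.translate(rec.seq[g.cds_start : g.cds_end - 3])
            prot_s = codons.translate(g.anc_seq[g.cds_start : g.cds_end - 3])
            matches, pct = _identity(prot_q, prot_s)
            bitscore = round(2.0 * matches, 1)
            hits.append(SimilarityHit(
                query=rec.id, subject=g.protein_id, pct_identity=round(pct, 2),
                aln_length=n_res, mismatches=n_res - matches, gap_opens=0,
                q_start=g.cds_start + 1, q_end=g.cds_end - 3,
                s_start=1, s_end=n_res,
                evalue=10.0 ** (-min(bitscore / 10.0, 180.0)), bitscore=bitscore,
                frame=g.cds_start % 3 + 1,
            ))
        out[sp] = hits
    return out


def simulate_allvall_protein_hits(
    species_sets: dict[str, list[TranscriptRecord]],
    params: EvolParams, truth: TruthTable,
) -> list[SimilarityHit]:
    """All-against-all translated-gene hits across the three species.

    Genes sharing an ancestor (orthologs and paralogs) hit each other in both
    directions with bitscores from amino-acid identity; unrelated genes do
    not align (the families stage consumes this as its similarity graph).
    """
    by_anc: dict[str, list[TranscriptRecord]] = {}
    prot: dict[str, str] = {}
    for sp in SPECIES:
        for rec in species_sets[sp]:
            anc = "anc" + rec.id.split("anc", 1)[1].split("_")[0]
            g = truth.genes[anc]
            by_anc.setdefault(anc, []).append(rec)
            prot[rec.id] = codons.translate(rec.seq[g.cds_start : g.cds_end - 3])
    hits: list[SimilarityHit] = []
    for anc in sorted(by_anc):
        group = by_anc[anc]
        for q in group:
            for s in group:
                if q.id == s.id:
                    continue
                hits.append(_hit(q.id, s.id, prot[q.id], prot[s.id]))
    return hits


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotation_tables(
    species_sets: dict[str, list[TranscriptRecord]],
    params: EvolParams, truth: TruthTable,
    n_terms: int = 30, enriched_terms: list[str] | None = None,
    enrich_prob: float = 0.25, background_lambda: float = 2.0,
) -> dict[str, list[str]]:
    """Gene-to-term annotation with planted enrichment among core genes.

    Each gene draws Poisson(``background_lambda``) terms uniformly from the
    term universe; genes destined for core families (present in all three
    species) additionally carry each enriched term with probability
    ``enrich_prob`` — roughly a five-fold rate increase at the defaults.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    terms = [f"T{i:04d}" for i in range(n_terms)]
    if enriched_terms is None:
        enriched_terms = terms[: min(3, n_terms)]
    truth.enriched_terms = list(enriched_terms)
    ann: dict[str, list[str]] = {}
    all_ids = sorted(r.id for recs in species_sets.values() for r in recs)
    core_ancs = {g.anc_id for g in truth.genes.values()
                 if all(g.present[sp] for sp in SPECIES)}
    rng = np.random.default_rng([params.seed, 5])
    for gid in all_ids:
        anc = "anc" + gid.split("anc", 1)[1].split("_")[0]
        k = int(rng.poisson(background_lambda))
        chosen = set(rng.choice(terms, size=min(k, n_terms), replace=False)) if k else set()
        if anc in core_ancs:
            for t in enriched_terms:
                if rng.random() < enrich_prob:
                    chosen.add(t)
        if chosen:
            ann[gid] = sorted(chosen)
    truth.annotations = ann
    return ann
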