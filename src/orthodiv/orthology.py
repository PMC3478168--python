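"""Reciprocal-best-hit orthology, paralog filtering, and CDS/UTR delineation.

The flow: candidate pairs from mutual best nucleotide hits (minimum sequence
length 200 bp, score ties dropped), then a conservative paralog filter that
keeps only pairs whose members each map unambiguously to the same reference
protein below an e-value ceiling, then rule-based delineation of the coding
region by projecting the reference protein's first residue and stop codon
onto each transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .codons import STOP_CODONS, reverse_complement, translate
from .io_formats import SimilarityHit, log


@dataclass
class OrthologPair:
    """A matched transcript pair sharing one reference protein."""

    gene_a: str
    gene_b: str
    ref_protein: str
    evalue_a: float
    evalue_b: float


@dataclass
class MemberPartition:
    """CDS/UTR coordinates for one member, on the re-oriented sequence.

    Coordinates are 0-based half-open; the CDS includes the terminal stop
    codon when one was found.
    """

    gene: str
    seq: str                       # re-oriented (reverse-complemented if frame < 0)
    cds_start: int
    cds_end: int
    utr5: tuple[int, int] | None
    utr3: tuple[int, int] | None
    start_missing: bool = False
    stop_missing: bool = False
    reoriented: bool = False

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    def internal_stop(self) -> bool:
        """An in-frame stop strictly before the final codon of the CDS."""
        for p in range(self.cds_start, self.cds_end - 3, 3):
            if self.seq[p : p + 3] in STOP_CODONS:
                return True
        return False


@dataclass
class RegionPartition:
    pair: OrthologPair
    a: MemberPartition
    b: MemberPartition


@dataclass
class AlignedRegionPair:
    """Gapless aligned columns of one region of one ortholog pair.

    ``columns[k] = (i, j)`` indexes the two re-oriented member sequences;
    for the cds region ``phases[k]`` is the codon phase (0..2) of column k,
    identical in both members by construction.
    """

    region: str                    # 'utr5' | 'cds' | 'utr3'
    columns: list[tuple[int, int]]
    phases: list[int] | None = None


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit | None]:
    """Per query: the unique maximum-bitscore hit, or None on a score tie."""
    best: dict[str, SimilarityHit] = {}
    tied: set[str] = set()
    for h in hits:
        cur = best.get(h.query)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.query] = h
            tied.discard(h.query)
        elif h.bitscore == cur.bitscore and h.subject != cur.subject:
            tied.add(h.query)
    return {q: (None if q in tied else h) for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: list[SimilarityHit], hits_ba: list[SimilarityHit],
    len_a: dict[str, int], len_b: dict[str, int], min_len: int = 200,
) -> list[tuple[str, str]]:
    """Mutual-best-hit candidate pairs, both members at least ``min_len`` bp.

    Best hit means unique maximum bitscore; any tie for best excludes the
    query.  The result is symmetric in the two input tables.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        if hit is None:
            continue
        b = hit.subject
        back = best_ba.get(b)
        if back is None or back.subject != a:
            continue
        if len_a.get(a, 0) < min_len or len_b.get(b, 0) < min_len:
            continue
        pairs.append((a, b))
    log.info("reciprocal_best_hits: %d candidate pairs", len(pairs))
    return pairs


def filter_same_reference(
    candidates: list[tuple[str, str]],
    protein_hits_a: list[SimilarityHit], protein_hits_b: list[SimilarityHit],
    evalue_max: float = 1e-5,
) -> list[OrthologPair]:
    """Keep pairs whose members map unambiguously to the same reference protein.

    Each member's best protein hit (unique by bitscore; any tie is ambiguous
    and drops the pair) must name the same protein at e-value below
    ``evalue_max``.
    """
    best_a = _best_hits(protein_hits_a)
    best_b = _best_hits(protein_hits_b)
    kept = []
    for a, b in candidates:
        ha, hb = best_a.get(a), best_b.get(b)
        if ha is None or hb is None:
            continue
        if ha.evalue >= evalue_max or hb.evalue >= evalue_max:
            continue
        if ha.subject != hb.subject:
            continue
        kept.append(OrthologPair(gene_a=a, gene_b=b, ref_protein=ha.subject,
                                 evalue_a=ha.evalue, evalue_b=hb.evalue))
    log.info("filter_same_reference: %d ortholog pairs", len(kept))
    return kept


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

class DelineationError(ValueError):
    """Raised when a member has no usable protein alignment."""


def delineate_member(gene: str, seq: str, hit: SimilarityHit,
                     ref_protein_len: int, stop_window: int = 30) -> MemberPartition:
    """Project the reference protein onto one transcript and cut CDS/UTRs.

    The start codon is the in-frame ATG nearest the projection of reference
    residue 1, searching upstream within the transcript first, then
    downstream within the aligned region.  The stop codon is the first
    in-frame TAA/TAG/TGA within ``stop_window`` bp (inclusive ends) of the
    projected reference stop.  A missing start or stop sets a partial flag
    and clips the CDS to the aligned region.
    """
    if hit is None:
        raise DelineationError(f"no protein alignment for {gene!r}")
    reoriented = False
    q_start, q_end = hit.q_start, hit.q_end
    if hit.frame < 0:
        seq = reverse_complement(seq)
        q_start, q_end = len(seq) - hit.q_end + 1, len(seq) - hit.q_start + 1
        reoriented = True
    aln_start = q_start - 1                       # 0-based, in frame
    aln_end = q_end                               # 0-based exclusive
    proj = aln_start - 3 * (hit.s_start - 1)      # projected base 1 of residue 1

    cds_start = None
    pos = proj
    while pos >= 0:                               # upstream (projection first)
        if seq[pos : pos + 3] == "ATG":
            cds_start = pos
            break
        pos -= 3
    if cds_start is None:
        pos = proj + 3
        while pos + 3 <= aln_end:                 # then downstream in the alignment
            if seq[pos : pos + 3] == "ATG":
                cds_start = pos
                break
            pos += 3
    start_missing = cds_start is None
    if start_missing:
        cds_start = aln_start

    proj_stop = proj + 3 * ref_protein_len        # projected stop-codon start
    cds_end = None
    for k in range(-(stop_window // 3), stop_window // 3 + 1):
        p = proj_stop + 3 * k
        if p < cds_start + 3 or p + 3 > len(seq):
            continue
        if seq[p : p + 3] in STOP_CODONS:
            cds_end = p + 3
            break
    stop_missing = cds_end is None
    if stop_missing:
        end = min(aln_end, len(seq))
        cds_end = cds_start + 3 * max((end - cds_start) // 3, 0)
    if cds_end <= cds_start:
        raise DelineationError(f"empty CDS after delineation for {gene!r}")

    utr5 = (0, cds_start) if (not start_missing and cds_start > 0) else None
    utr3 = (cds_end, len(seq)) if (not stop_missing and cds_end < len(seq)) else None
    return MemberPartition(gene=gene, seq=seq, cds_start=cds_start, cds_end=cds_end,
                           utr5=utr5, utr3=utr3, start_missing=start_missing,
                           stop_missing=stop_missing, reoriented=reoriented)


def delineate_regions(pair: OrthologPair, seqs: dict[str, str],
                      protein_hits_a: list[SimilarityHit],
                      protein_hits_b: list[SimilarityHit],
                      ref_protein_lens: dict[str, int],
                      stop_window: int = 30) -> RegionPartition:
    best_a = _best_hits(protein_hits_a)
    best_b = _best_hits(protein_hits_b)
    n_res = ref_protein_lens[pair.ref_protein]
    a = delineate_member(pair.gene_a, seqs[pair.gene_a], best_a.get(pair.gene_a),
                         n_res, stop_window)
    b = delineate_member(pair.gene_b, seqs[pair.gene_b], best_b.get(pair.gene_b),
                         n_res, stop_window)
    return RegionPartition(pair=pair, a=a, b=b)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignScoring:
    """Alignment scoring defaults (standard BLAST-like values)."""

    protein_open: float = 11.0
    protein_extend: float = 1.0
    nt_match: float = 2.0
    nt_mismatch: float = 3.0
    nt_open: float = 5.0
    nt_extend: float = 2.0
    utr_min_block: int = 30
    utr_min_ident: float = 70.0


def _protein_aligner(sc: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -sc.protein_open
    aligner.extend_gap_score = -sc.protein_extend
    return aligner


def _nt_local_aligner(sc: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = sc.nt_match
    aligner.mismatch_score = -sc.nt_mismatch
    aligner.open_gap_score = -sc.nt_open
    aligner.extend_gap_score = -sc.nt_extend
    return aligner


def _aligned_columns(alignment) -> list[tuple[int, int]]:
    cols = []
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        cols.extend((qs + k, ss + k) for k in range(qe - qs))
    return cols


def align_utr_pair(seq_a: str, seq_b: str, sc: AlignScoring) -> list[tuple[int, int]] | None:
    """Best local nucleotide block between two UTRs; None if nothing aligns
    or the block fails the length/identity stringency."""
    if not seq_a or not seq_b:
        return None
    aligner = _nt_local_aligner(sc)
    alignments = aligner.align(seq_a, seq_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    cols = _aligned_columns(alignments[0])
    if len(cols) < sc.utr_min_block:
        return None
    matches = sum(1 for i, j in cols if seq_a[i] == seq_b[j])
    if 100.0 * matches / len(cols) < sc.utr_min_ident:
        return None
    return cols


def align_cds_pair(pa: MemberPartition, pb: MemberPartition,
                   sc: AlignScoring) -> AlignedRegionPair | None:
    """Codon-aware CDS alignment: translate, align globally, back-map.

    The terminal stop codon is excluded; columns inside protein gaps are
    excluded; every retained column carries its codon phase.
    """
    def coding(p: MemberPartition) -> tuple[int, str]:
        end = p.cds_end - (0 if p.stop_missing else 3)
        return p.cds_start, p.seq[p.cds_start : end]

    off_a, nt_a = coding(pa)
    off_b, nt_b = coding(pb)
    prot_a, prot_b = translate(nt_a), translate(nt_b)
    if not prot_a or not prot_b:
        return None
    alignments = _protein_aligner(sc).align(prot_a, prot_b)
    if len(alignments) == 0:
        return None
    columns: list[tuple[int, int]] = []
    phases: list[int] = []
    for i, j in _aligned_columns(alignments[0]):
        for ph in range(3):
            columns.append((off_a + 3 * i + ph, off_b + 3 * j + ph))
            phases.append(ph)
    if not columns:
        return None
    return AlignedRegionPair(region="cds", columns=columns, phases=phases)


def filter_regions(partitions: list[RegionPartition],
                   cds_min_len: int = 150,
                   scoring: AlignScoring | None = None) -> list[RegionPartition]:
    """Apply the CDS and UTR acceptance rules.

    A pair is dropped when either member's CDS is shorter than
    ``cds_min_len`` bp or contains an internal in-frame stop codon.  A UTR
    pair survives only if its best local block reaches the configured length
    and identity stringency (the surrogate for a search-engine e-value
    cutoff); a failing UTR pair is discarded while the CDS is retained.
    """
    sc = scoring or AlignScoring()
    kept: list[RegionPartition] = []
    for part in partitions:
        if part.a.cds_len < cds_min_len or part.b.cds_len < cds_min_len:
            continue
        if part.a.internal_stop() or part.b.internal_stop():
            continue
        for region in ("utr5", "utr3"):
            ia, ib = getattr(part.a, region), getattr(part.b, region)
            if ia is None or ib is None:
                setattr(part.a, region, None)
                setattr(part.b, region, None)
                continue
            cols = align_utr_pair(part.a.seq[ia[0]:ia[1]], part.b.seq[ib[0]:ib[1]], sc)
            if cols is None:
                setattr(part.a, region, None)
                setattr(part.b, region, None)
        kept.append(part)
    log.info("filter_regions: %d of %d pairs kept", len(kept), len(partitions))
    return kept


def align_pair_regions(part: RegionPartition,
                       scoring: AlignScoring | None = None) -> list[AlignedRegionPair]:
    """Aligned gapless columns for each surviving region of one pair."""
    sc = scoring or AlignScoring()
    out: list[AlignedRegionPair] = []
    for region in ("utr5", "cds", "utr3"):
        if region == "cds":
            aligned = align_cds_pair(part.a, part.b, sc)
            if aligned is not None:
                out.append(aligned)
            continue
        ia, ib = getattr(part.a, region), getattr(part.b, region)
        if ia is None or ib is None:
            continue
        cols = align_utr_pair(part.a.seq[ia[0]:ia[1]], part.b.seq[ib[0]:ib[1]], sc)
        if cols is None:
            continue
        out.append(AlignedRegionPair(
            region=region,
            columns=[(ia[0] + i, ib[0] + j) for i, j in cols],
        ))
    return out
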