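"""Within-species SNP detection on orthologous CDS from read pileups.

Columns are built from mapped reads restricted to CDS intervals (M/I/D
CIGAR operations only; insertions are ignored, deletions skip columns).  A
site is called when depth >= 10 and the second-most-common base clears the
configurable support gates (count >= 3 and frequency >= 0.2 by default; the
depth gate is the published criterion, the support gates suppress singleton
noise).  The reference allele is the assembled transcript base, and the
effect is read off the standard codon table — a change to a stop codon is
nonsynonymous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import BASES, translate_codon
from .io_formats import ReadAlignment, log

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PileupColumn:
    gene_id: str
    cds_pos: int                 # 0-based position within the CDS
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass
class SnpCall:
    gene_id: str
    cds_pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    effect: str | None           # 'synonymous' | 'nonsynonymous' | None
    ref_aa: str | None = None
    alt_aa: str | None = None
    codon_index: int = -1
    phase: int = -1


def pileup_cds(
    alignments: list[ReadAlignment],
    cds_intervals: dict[str, tuple[int, int]],
) -> dict[str, np.ndarray]:
    """Base-count arrays (cds_len x 4) per gene, restricted to the CDS.

    ``cds_intervals`` maps transcript id to its 0-based half-open CDS.
    Alignments to unknown transcripts are skipped with a logged count.
    """
    piles: dict[str, np.ndarray] = {}
    skipped = 0
    for a in alignments:
        interval = cds_intervals.get(a.target_id)
        if interval is None:
            skipped += 1
            continue
        cds_start, cds_end = interval
        pile = piles.get(a.target_id)
        if pile is None:
            pile = piles[a.target_id] = np.zeros((cds_end - cds_start, 4), dtype=np.int32)
        ref_pos = a.pos - 1           # 0-based transcript coordinate
        read_pos = 0
        for op, length in a.cigar:
            if op in ("M", "=", "X"):
                lo = max(ref_pos, cds_start)
                hi = min(ref_pos + length, cds_end)
                for p in range(lo, hi):
                    base = a.seq[read_pos + (p - ref_pos)]
                    if base in _BASE_IDX:
                        pile[p - cds_start, _BASE_IDX[base]] += 1
                ref_pos += length
                read_pos += length
            elif op == "I" or op == "S":
                read_pos += length    # insertions/clips: ignored
            elif op == "D" or op == "N":
                ref_pos += length     # deletions skip columns
            # H/P consume nothing
    if skipped:
        log.info("pileup_cds: %d alignments to unknown transcripts skipped", skipped)
    return piles


def call_snps(
    piles: dict[str, np.ndarray],
    cds_seqs: dict[str, str],
    min_depth: int = 10,
    min_alt_count: int = 3,
    min_alt_freq: float = 0.2,
) -> list[SnpCall]:
    """Variant sites passing the depth and alternate-allele support gates.

    ``cds_seqs`` maps gene id to its CDS nucleotide sequence (the transcript
    consensus, which defines the reference allele).  Effects are classified
    for every call whose codon is resolvable.
    """
    calls: list[SnpCall] = []
    for gene in sorted(piles):
        pile = piles[gene]
        cds = cds_seqs[gene]
        depths = pile.sum(axis=1)
        order = np.argsort(pile, axis=1)
        for pos in np.flatnonzero(depths >= min_depth):
            depth = int(depths[pos])
            second = BASES[order[pos, -2]]
            second_count = int(pile[pos, order[pos, -2]])
            if second_count < min_alt_count or second_count / depth < min_alt_freq:
                continue
            ref = cds[pos]
            top = BASES[order[pos, -1]]
            alt = top if top != ref else second
            if alt == ref:
                continue
            call = SnpCall(gene_id=gene, cds_pos=int(pos), ref=ref, alt=alt,
                           depth=depth,
                           alt_count=int(pile[pos, _BASE_IDX[alt]]),
                           effect=None)
            classify_snp_effect(call, cds)
            calls.append(call)
    return calls


def classify_snp_effect(call: SnpCall, cds_seq: str) -> str | None:
    """Synonymous/nonsynonymous effect of substituting the alt base.

    Fills the call's codon fields in place and returns the effect; a codon
    containing N leaves the effect undetermined (None).
    """
    codon_index, phase = divmod(call.cds_pos, 3)
    codon = cds_seq[3 * codon_index : 3 * codon_index + 3]
    if len(codon) < 3:
        return None
    alt_codon = codon[:phase] + call.alt + codon[phase + 1 :]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    call.codon_index, call.phase = codon_index, phase
    if ref_aa is None or alt_aa is None:
        call.effect = None
        return None
    call.ref_aa, call.alt_aa = ref_aa, alt_aa
    call.effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return call.effect
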