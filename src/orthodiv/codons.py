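"""Standard genetic code helpers shared by the divergence, selection and SNP stages."""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

_table = CodonTable.unambiguous_dna_by_id[1]  # the standard code

CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)
BASES = "ACGT"

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def is_transition(b1: str, b2: str) -> bool:
    return TRANSITION.get(b1) == b2


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stop, None if ambiguous (contains N)."""
    return CODON_TO_AA.get(codon)


def translate(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TO_AA.get(seq[i : i + 3])
        aas.append(aa if aa is not None else "X")
    return "".join(aas)


@lru_cache(maxsize=None)
def degeneracy(codon: str, position: int) -> str:
    """Degeneracy class of one codon position: 'nd', '4d' or 'other'.

    Enumerates the three alternative bases.  A change to a stop codon counts
    as amino-acid-changing.  Codons containing N, and stop codons themselves,
    are 'other'.
    """
    if position not in (0, 1, 2):
        raise ValueError(f"codon position must be 0..2, got {position}")
    aa = CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        return "other"
    changed = 0
    for b in BASES:
        if b == codon[position]:
            continue
        alt = codon[:position] + b + codon[position + 1 :]
        if CODON_TO_AA[alt] != aa:
            changed += 1
    if changed == 3:
        return "nd"
    if changed == 0:
        return "4d"
    return "other"


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str, position: int) -> float:
    """Fraction of the three single-base changes at this position that are
    synonymous (mutations to stop codons count as nonsynonymous)."""
    aa = CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot count sites for codon {codon!r}")
    syn = 0
    for b in BASES:
        if b == codon[position]:
            continue
        alt = codon[:position] + b + codon[position + 1 :]
        if CODON_TO_AA[alt] == aa:
            syn += 1
    return syn / 3.0


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))
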