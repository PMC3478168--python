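"""Readers and writers for every external format the pipeline touches.

Conventions: all file-level coordinates are 1-based inclusive (BLAST/SAM
style); everything internal is 0-based half-open. The conversion happens
here and nowhere else.  ``N`` bases are accepted on input and excluded from
compared-site counts downstream.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("orthodiv")


def setup_logging(quiet: bool = False) -> None:
    """Stage-name logging to stderr; ``quiet`` suppresses everything below WARNING."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.WARNING if quiet else logging.INFO)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptRecord:
    """One assembled transcript ("distinct sequence") of one species."""

    id: str
    species: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SimilarityHit:
    """One row of a tabular similarity search (BLAST outfmt-6 dialect).

    ``frame`` is 0 for nucleotide-vs-nucleotide hits and in {-3..-1, 1..3}
    for translated searches (optional 13th column).
    """

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    frame: int = 0


@dataclass
class ReadAlignment:
    """A mapped read: 1-based leftmost position, parsed CIGAR, bases."""

    read_id: str
    target_id: str
    pos: int
    cigar: list[tuple[str, int]]
    seq: str
    mapq: int = 60


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, species: str = "") -> list[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Duplicate ids
    and empty sequences are errors.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        records.append(TranscriptRecord(id=rec.id, species=species, seq=seq))
    log.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_BLAST_INT = (3, 4, 5, 6, 7, 8, 9)  # aln_length .. s_end


def parse_blast_tab(path) -> list[SimilarityHit]:
    """Parse 12- or 13-column tab-separated similarity hits, in file order."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(parts)}"
                )
            try:
                hit = SimilarityHit(
                    query=parts[0],
                    subject=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    frame=int(parts[12]) if len(parts) == 13 else 0,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if hit.evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative evalue")
            if hit.aln_length < 1:
                raise ValueError(f"{path}:{lineno}: alignment length < 1")
            hits.append(hit)
    return hits


def write_blast_tab(hits, path, frame_column: bool = False) -> None:
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.query, h.subject, f"{h.pct_identity:.2f}", str(h.aln_length),
                str(h.mismatches), str(h.gap_opens), str(h.q_start), str(h.q_end),
                str(h.s_start), str(h.s_end), f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
            ]
            if frame_column:
                cols.append(str(h.frame))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# SAM (minimal dialect: @SQ header lines, flags 0/16/4, ops M/I/D)
# ---------------------------------------------------------------------------

_CIGAR_OPS = set("MIDNSHP=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"malformed CIGAR {cigar!r}")
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_query_length(ops) -> int:
    return sum(n for op, n in ops if op in "MIS=X")


def parse_sam_min(path) -> list[ReadAlignment]:
    """Parse the minimal SAM dialect: mapped single-end records only.

    Unmapped records (flag bit 4) are skipped.  Target ids are validated
    against ``@SQ`` header lines when any are present.  A CIGAR whose query
    span disagrees with the sequence length is an error naming the read.
    """
    alignments: list[ReadAlignment] = []
    sq_ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for f in line.split("\t")[1:]:
                        if f.startswith("SN:"):
                            sq_ids.add(f[3:])
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ValueError(f"SAM record with {len(parts)} fields in {path}")
            qname, flag, rname, pos, mapq, cigar, _, _, _, seq = parts[:10]
            if int(flag) & 4:
                continue
            ops = parse_cigar(cigar)
            if cigar_query_length(ops) != len(seq):
                raise ValueError(
                    f"CIGAR/sequence length mismatch for read {qname!r}"
                )
            if sq_ids and rname not in sq_ids:
                raise ValueError(f"read {qname!r} maps to unknown target {rname!r}")
            alignments.append(
                ReadAlignment(read_id=qname, target_id=rname, pos=int(pos),
                              cigar=ops, seq=seq, mapq=int(mapq))
            )
    log.info("parse_sam_min: %d mapped records from %s", len(alignments), path)
    return alignments


def write_sam(alignments, references: dict[str, int], path) -> None:
    """Write mapped single-end records with an @SQ header (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{references[name]}\n")
        for a in alignments:
            cigar = "".join(f"{n}{op}" for op, n in a.cigar)
            fh.write(
                f"{a.read_id}\t0\t{a.target_id}\t{a.pos}\t{a.mapq}\t{cigar}"
                f"\t*\t0\t0\t{a.seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv_report(rows, schema: list[str], path, formats: dict | None = None) -> None:
    """Write dict rows against an explicit column schema.

    Every row must carry exactly the schema's keys; a missing or extra field
    is an error naming the column.  ``formats`` maps column name to a
    printf-style format (divergence percentages use ``"%.2f"`` so the report
    re-parses at the documented display precision).
    """
    formats = formats or {}
    with open(path, "w") as fh:
        fh.write("\t".join(schema) + "\n")
        for row in rows:
            extra = set(row) - set(schema)
            if extra:
                raise ValueError(f"row has unexpected column(s): {sorted(extra)}")
            missing = set(schema) - set(row)
            if missing:
                raise ValueError(f"row is missing column(s): {sorted(missing)}")
            cells = []
            for col in schema:
                val = row[col]
                if val is None:
                    cells.append("")
                elif col in formats:
                    cells.append(formats[col] % val)
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Minimal rooted-tree node; ``length`` is the branch to the parent."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf():
        if not node.label:
            raise ValueError("unlabeled leaf in tree")
        return f"{node.label}:{node.length:g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = node.label or ""
    return f"({inner}){label}:{node.length:g}"


def format_newick(tree: TreeNode) -> str:
    if tree.is_leaf():
        raise ValueError("tree must have at least one internal node")
    for leaf in tree.leaves():
        if not leaf.label:
            raise ValueError("unlabeled leaf in tree")
        if leaf.length < 0:
            raise ValueError(f"negative branch length at leaf {leaf.label!r}")
    inner = ",".join(_newick_node(c) for c in tree.children)
    return f"({inner});"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config_file(path) -> dict:
    """Load a flat key-value YAML config; returns {} for an empty file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return data
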