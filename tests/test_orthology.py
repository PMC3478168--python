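"""RBH pairing, paralog filtering, CDS/UTR delineation, region alignment."""

from __future__ import annotations

import numpy as np
import pytest

from orthodiv.io_formats import SimilarityHit
from orthodiv.orthology import (
    AlignScoring, MemberPartition, OrthologPair, RegionPartition,
    align_cds_pair, align_pair_regions, align_utr_pair, delineate_member,
    filter_regions, filter_same_reference, reciprocal_best_hits,
)


def hit(q, s, bitscore, evalue=1e-40, frame=1, q_start=1, q_end=100,
        s_start=1, s_end=100):
    return SimilarityHit(q, s, 95.0, 100, 5, 0, q_start, q_end,
                         s_start, s_end, evalue, bitscore, frame)


LEN = {f"{x}{i}": 500 for x in "ab" for i in range(1, 5)}


class TestReciprocalBestHits:
    def test_mutual_best_kept(self):
        pairs = reciprocal_best_hits([hit("a1", "b1", 300)],
                                     [hit("b1", "a1", 300)], LEN, LEN)
        assert pairs == [("a1", "b1")]

    def test_non_mutual_dropped(self):
        pairs = reciprocal_best_hits(
            [hit("a1", "b1", 300)],
            [hit("b1", "a2", 400), hit("b1", "a1", 300)], LEN, LEN)
        assert pairs == []

    def test_bitscore_tie_excludes_query(self):
        pairs = reciprocal_best_hits(
            [hit("a1", "b1", 300), hit("a1", "b2", 300)],
            [hit("b1", "a1", 300)], LEN, LEN)
        assert pairs == []

    def test_min_length_gate(self):
        short = dict(LEN)
        short["a1"] = 199
        assert reciprocal_best_hits([hit("a1", "b1", 300)],
                                    [hit("b1", "a1", 300)], short, LEN) == []

    def test_symmetry(self):
        """Swapping the two hit tables member-swaps the result."""
        rng = np.random.default_rng(3)
        ab, ba = [], []
        for i in range(30):
            q, s = f"a{rng.integers(8)}", f"b{rng.integers(8)}"
            ab.append(hit(q, s, float(rng.integers(50, 400))))
            q, s = f"b{rng.integers(8)}", f"a{rng.integers(8)}"
            ba.append(hit(q, s, float(rng.integers(50, 400))))
        lens = {f"{x}{i}": 500 for x in "ab" for i in range(8)}
        fwd = reciprocal_best_hits(ab, ba, lens, lens)
        rev = reciprocal_best_hits(ba, ab, lens, lens)
        assert sorted(fwd) == sorted((a, b) for b, a in rev)


class TestSameReferenceFilter:
    def test_same_protein_kept(self):
        pairs = filter_same_reference(
            [("a1", "b1")], [hit("a1", "P1", 200)], [hit("b1", "P1", 210)])
        assert len(pairs) == 1 and pairs[0].ref_protein == "P1"

    def test_different_proteins_dropped(self):
        assert filter_same_reference(
            [("a1", "b1")], [hit("a1", "P1", 200)], [hit("b1", "P2", 210)]) == []

    def test_protein_tie_is_ambiguous(self):
        assert filter_same_reference(
            [("a1", "b1")],
            [hit("a1", "P1", 200), hit("a1", "P2", 200)],
            [hit("b1", "P1", 210)]) == []

    def test_evalue_ceiling(self):
        assert filter_same_reference(
            [("a1", "b1")], [hit("a1", "P1", 200, evalue=1e-4)],
            [hit("b1", "P1", 210)]) == []


class TestDelineation:
    def test_constructed_start_and_utr5(self):
        # transcript AA + ATG GCT TGA: projection falls on the ATG
        seq = "AAATGGCTTGA"
        h = hit("g", "P", 100, q_start=3, q_end=8, s_start=1, s_end=2)
        part = delineate_member("g", seq, h, ref_protein_len=2)
        assert part.cds_start == 2
        assert part.utr5 == (0, 2)
        assert seq[part.cds_start : part.cds_start + 3] == "ATG"
        assert not part.start_missing and not part.stop_missing
        assert part.seq[part.cds_end - 3 : part.cds_end] == "TGA"

    def test_stop_within_window_accepted(self):
        # reference stop projects 6 bp before the actual in-frame TGA
        seq = "ATGGCTGCAGCCGCGTGA"
        h = hit("g", "P", 100, q_start=1, q_end=9, s_start=1, s_end=3)
        part = delineate_member("g", seq, h, ref_protein_len=3)
        # projected stop at position 9; real stop at 15 (within +-30)
        assert part.cds_end == 18 and not part.stop_missing

    def test_missing_start_flag(self):
        seq = "CCCCCCGCTGCAGCCTGA"
        h = hit("g", "P", 100, q_start=7, q_end=15, s_start=1, s_end=3)
        part = delineate_member("g", seq, h, ref_protein_len=3)
        assert part.start_missing
        assert part.cds_start == 6      # clipped to the aligned region
        assert part.utr5 is None

    def test_negative_frame_reorients(self):
        from orthodiv.codons import reverse_complement
        fwd = "AAATGGCTTGA"
        seq = reverse_complement(fwd)
        h = hit("g", "P", 100, frame=-1,
                q_start=len(seq) - 8 + 1, q_end=len(seq) - 3 + 1,
                s_start=1, s_end=2)
        part = delineate_member("g", seq, h, ref_protein_len=2)
        assert part.reoriented
        assert part.seq == fwd
        assert part.cds_start == 2


def _partition(seq, cds_start, cds_end, gene="g", utr5=None, utr3=None,
               stop_missing=False):
    return MemberPartition(gene=gene, seq=seq, cds_start=cds_start,
                           cds_end=cds_end, utr5=utr5, utr3=utr3,
                           stop_missing=stop_missing)


def _pairpart(a, b):
    return RegionPartition(pair=OrthologPair(a.gene, b.gene, "P", 0, 0), a=a, b=b)


class TestFilterRegions:
    def test_short_cds_dropped(self):
        seq = "ATG" + "GCT" * 48 + "TGA"  # 150 bp total
        ok = _partition(seq, 0, len(seq))
        short = _partition(seq[:147], 0, 147)
        assert filter_regions([_pairpart(ok, ok)]) != []
        assert filter_regions([_pairpart(short, short)]) == []

    def test_internal_stop_dropped(self):
        seq = "ATG" + "GCT" * 20 + "TAA" + "GCT" * 30 + "TGA"
        part = _partition(seq, 0, len(seq))
        assert filter_regions([_pairpart(part, part)]) == []

    def test_short_utr_discarded_cds_kept(self):
        cds = "ATG" + "GCT" * 60 + "TGA"
        utr = "ACGTACGTACGT"  # 12 bp, below the 30-bp stringency
        seq = utr + cds
        part = _partition(seq, 12, len(seq), utr5=(0, 12))
        (kept,) = filter_regions([_pairpart(part, part)])
        assert kept.a.utr5 is None and kept.b.utr5 is None


class TestAlignRegions:
    def test_identical_cds_full_columns(self):
        seq = "ATG" + "GCTAGCGAT" * 11 + "TGA"   # 105 bp with stop
        part = _partition(seq, 0, len(seq))
        aligned = align_cds_pair(part, part, AlignScoring())
        # stop codon excluded from the comparison columns
        assert len(aligned.columns) == len(seq) - 3
        assert all(part.seq[i] == part.seq[j] for i, j in aligned.columns)
        assert aligned.phases == [0, 1, 2] * ((len(seq) - 3) // 3)

    def test_inserted_codon_columns_absent(self):
        base = "ATG" + "GCTAGCGATCCTAAAGGG" * 6 + "TGA"
        ins = base[:30] + "CAG" + base[30:]
        pa = _partition(base, 0, len(base))
        pb = _partition(ins, 0, len(ins))
        aligned = align_cds_pair(pa, pb, AlignScoring())
        assert len(aligned.columns) == len(base) - 3  # gap columns excluded
        matches = sum(pa.seq[i] == pb.seq[j] for i, j in aligned.columns)
        assert matches == len(base) - 3

    def test_unrelated_utrs_rejected(self):
        rng = np.random.default_rng(9)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        assert align_utr_pair(a, b, AlignScoring()) is None

    def test_matches_exhaustive_gapless_oracle_on_toys(self):
        """The retained local block scores at least as well as every gapless
        substring pairing of 20-bp toys (and equals it when gapless wins)."""
        sc = AlignScoring(utr_min_block=4, utr_min_ident=0.0)
        rng = np.random.default_rng(17)
        for _ in range(25):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
            b = list(a)
            for p in rng.choice(20, size=4, replace=False):
                b[p] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            best = 0.0
            for la in range(len(a)):
                for lb in range(len(b)):
                    score = 0.0
                    for k in range(min(len(a) - la, len(b) - lb)):
                        score += 2.0 if a[la + k] == b[lb + k] else -3.0
                        best = max(best, score)
            cols = align_utr_pair(a, b, sc)
            got = 0.0
            if cols:
                got = sum(2.0 if a[i] == b[j] else -3.0 for i, j in cols)
            assert got >= best or got == pytest.approx(best)

    def test_column_regions_disjoint(self, small_bundle):
        """Across the aligned output of real pairs, every column index pair
        belongs to exactly one region."""
        from orthodiv.pipeline import run_orthology
        cfg, paths, _ = small_bundle
        result = run_orthology(
            cfg, paths["fasta_a"], paths["fasta_b"], paths["hits_ab"],
            paths["hits_ba"], paths["prot_a"], paths["prot_b"],
            paths["ref_proteins"], paths["fasta_a"].parent / "_pairs.tsv",
            paths["fasta_a"].parent / "_regions.tsv")
        checked = 0
        for gene_a, regions in result.aligned.items():
            seen: set[tuple[int, int]] = set()
            for region in regions:
                for col in region.columns:
                    assert col not in seen
                    seen.add(col)
            checked += bool(regions)
        assert checked > 10


class TestZeroDivergenceRecovery:
    def test_delineation_recovers_true_cds(self):
        """On zero-divergence synthetic pairs the delineated CDS equals the
        generator's ground truth exactly."""
        from orthodiv import simulate as sim
        p = sim.EvolParams(n_genes=12, t_A=0.0, t_B=0.0, t_C=0.0,
                           loss_frac=0.0, paralog_frac=0.0, seed=5)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        prot_hits = sim.simulate_protein_hits(sets, p, truth)
        lens = {r.id: len(r.seq) for r in sim.reference_proteins(truth)}
        best = {h.query: h for h in prot_hits["A"]}
        for rec in sets["A"]:
            g = truth.genes["anc" + rec.id.split("anc")[1]]
            part = delineate_member(rec.id, rec.seq, best[rec.id],
                                    lens[g.protein_id])
            assert (part.cds_start, part.cds_end) == (g.cds_start, g.cds_end)
            assert not part.start_missing and not part.stop_missing
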