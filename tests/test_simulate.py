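"""Synthetic-data generator: structure, limits, determinism, planted truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from orthodiv import simulate as sim
from orthodiv.codons import STOP_CODONS
from orthodiv.families import hypergeom_enrichment
from orthodiv.io_formats import TranscriptRecord, write_sam


def params(**kw) -> sim.EvolParams:
    base = dict(n_genes=5, seed=123)
    base.update(kw)
    return sim.EvolParams(**base)


class TestAncestors:
    def test_codon_structure(self):
        ancestors, truth = sim.simulate_ancestors(params(n_genes=1))
        g = truth.genes[ancestors[0].id]
        cds = g.anc_seq[g.cds_start : g.cds_end]
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        assert len(cds) % 3 == 0
        assert all(cds[i : i + 3] not in STOP_CODONS
                   for i in range(0, len(cds) - 3, 3))

    def test_fixed_cds_length(self):
        ancestors, truth = sim.simulate_ancestors(params(cds_len_range=(300, 300)))
        for a in ancestors:
            g = truth.genes[a.id]
            assert g.cds_end - g.cds_start == 300

    def test_determinism(self):
        a1, _ = sim.simulate_ancestors(params())
        a2, _ = sim.simulate_ancestors(params())
        assert [(x.id, x.seq) for x in a1] == [(x.id, x.seq) for x in a2]

    def test_degenerate_range_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            sim.simulate_ancestors(params(cds_len_range=(900, 300)))


class TestEvolution:
    def test_zero_branch_length_identity(self):
        p = params(t_A=0.0, t_B=0.0, t_C=0.0, loss_frac=0.0)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        for sp in sim.SPECIES:
            for rec, anc in zip(sets[sp], ancestors):
                assert rec.seq == anc.seq

    def test_full_nd_constraint(self):
        """f_nd=0 forbids every substitution at ancestrally nondegenerate sites."""
        p = params(n_genes=3, cds_len_range=(1200, 1200), t_A=0.2, f_nd=0.0,
                   loss_frac=0.0)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        for rec, anc in zip(sets["A"], ancestors):
            g = truth.genes[anc.id]
            nd = sim._ancestral_nd_flags(g)
            diffs = [i for i, (x, y) in enumerate(zip(anc.seq, rec.seq)) if x != y]
            assert diffs, "expected some substitutions at this rate"
            assert not any(nd[i] for i in diffs)

    def test_no_stop_codons_created(self):
        p = params(n_genes=5, t_A=0.3, f_nd=1.0, f_ns=1.0, loss_frac=0.0)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        for rec, anc in zip(sets["A"], ancestors):
            g = truth.genes[anc.id]
            cds = rec.seq[g.cds_start : g.cds_end]
            assert all(cds[i : i + 3] not in STOP_CODONS
                       for i in range(0, len(cds) - 3, 3))
            assert cds[-3:] in STOP_CODONS

    def test_mutation_events_registered(self):
        p = params(n_genes=3, t_A=0.05, loss_frac=0.0)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        for rec, anc in zip(sets["A"], ancestors):
            g = truth.genes[anc.id]
            rebuilt = list(g.anc_seq)
            for m in g.mutations["A"]:
                rebuilt[m.pos] = m.alt
            assert "".join(rebuilt) == rec.seq


class TestParalogs:
    def _sets(self, p):
        ancestors, truth = sim.simulate_ancestors(p)
        return sim.evolve_triple(ancestors, p, truth), truth

    def test_zero_fraction_unchanged(self):
        p = params(n_genes=20, paralog_frac=0.0, loss_frac=0.0)
        sets, truth = self._sets(p)
        out = sim.plant_paralogs(sets, p, truth)
        assert {sp: len(v) for sp, v in out.items()} == \
            {sp: len(v) for sp, v in sets.items()}
        assert truth.paralogs == {}

    def test_exact_duplicate_count(self):
        p = params(n_genes=100, paralog_frac=0.1, loss_frac=0.0)
        sets, truth = self._sets(p)
        out = sim.plant_paralogs(sets, p, truth)
        assert len(truth.paralogs) == 10
        assert sum(len(v) for v in out.values()) == 310

    def test_paralog_diverges_from_source(self):
        p = params(n_genes=50, paralog_frac=0.2, t_B=0.02, loss_frac=0.0)
        sets, truth = self._sets(p)
        out = sim.plant_paralogs(sets, p, truth)
        by_id = {r.id: r for v in out.values() for r in v}
        for dup, src in truth.paralogs.items():
            assert by_id[dup].seq != by_id[src].seq


class TestReads:
    def test_single_gene_gets_all_reads(self):
        p = params(n_genes=1, het_rate=0.0, loss_frac=0.0)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        reads = sim.simulate_reads(sets["A"], p, truth)
        assert reads and all(r.target_id == sets["A"][0].id for r in reads)
        for r in reads:
            start = r.pos - 1
            assert r.seq == sets["A"][0].seq[start : start + p.read_len]

    def test_planted_snp_allele_counts_binomial(self):
        """At frequency 0.5 the alternate-allele depth behaves Binomial(d, 1/2)."""
        p = params(n_genes=1, het_rate=1.0, mean_coverage=200.0,
                   abundance_sigma=0.0, loss_frac=0.0, cds_len_range=(600, 600))
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        reads = sim.simulate_reads(sets["A"], p, truth)
        assert truth.snps, "expected at least one planted site at rate 1.0"
        snp = truth.snps[0]
        depth = alt = 0
        for r in reads:
            off = snp.pos - (r.pos - 1)
            if 0 <= off < len(r.seq):
                depth += 1
                alt += r.seq[off] == snp.alt
        assert depth > 50
        sd = 0.5 * np.sqrt(depth)
        assert abs(alt - 0.5 * depth) < 4 * sd

    def test_short_transcript_skipped(self):
        p = params(read_len=74)
        truth = sim.TruthTable()
        reads = sim.simulate_reads(
            [TranscriptRecord("tiny", "A", "ACGT" * 10)], p, truth)
        assert reads == []

    def test_fixed_seed_byte_identical_sam(self, tmp_path):
        p = params(n_genes=3, loss_frac=0.0)
        outs = []
        for tag in ("x", "y"):
            ancestors, truth = sim.simulate_ancestors(p)
            sets = sim.evolve_triple(ancestors, p, truth)
            reads = sim.simulate_reads(sets["A"], p, truth)
            path = tmp_path / f"{tag}.sam"
            write_sam(reads, {r.id: len(r.seq) for r in sets["A"]}, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]


class TestSimilarityTables:
    def _setup(self, **kw):
        p = params(n_genes=10, loss_frac=0.0, **kw)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        sets = sim.plant_paralogs(sets, p, truth)
        return p, sets, truth

    def test_identical_pair_full_identity(self):
        p, sets, truth = self._setup(t_A=0.0, t_B=0.0, t_C=0.0,
                                     paralog_frac=0.0, spurious_hit_rate=0.0)
        tables = sim.simulate_similarity_tables(sets, p, truth)
        for h in tables[("A", "B")]:
            assert h.pct_identity == 100.0
            assert h.evalue <= 1e-50

    def test_paralog_produces_competing_hits(self):
        p, sets, truth = self._setup(paralog_frac=0.3, spurious_hit_rate=0.0)
        tables = sim.simulate_similarity_tables(sets, p, truth)
        hosts = {dup.split("_", 1)[0] for dup in truth.paralogs}
        assert hosts, "expected planted paralogs"
        host = sorted(hosts)[0]
        hits = tables[("A", host)]
        by_query: dict[str, int] = {}
        for h in hits:
            by_query[h.query] = by_query.get(h.query, 0) + 1
        assert max(by_query.values()) >= 2

    def test_zero_spurious_rate_hit_count(self):
        p, sets, truth = self._setup(paralog_frac=0.0, spurious_hit_rate=0.0)
        tables = sim.simulate_similarity_tables(sets, p, truth)
        assert len(tables[("A", "B")]) == len(truth.ortholog_pairs("A", "B"))


class TestAnnotations:
    @staticmethod
    def _manual_truth(rng, n_genes, core_frac):
        truth = sim.TruthTable()
        sets = {sp: [] for sp in sim.SPECIES}
        for i in range(n_genes):
            core = rng.random() < core_frac
            lost = None if core else sim.SPECIES[int(rng.integers(3))]
            present = {sp: sp != lost for sp in sim.SPECIES}
            gid = f"anc{i:05d}"
            truth.genes[gid] = sim.GeneTruth(
                anc_id=gid, anc_seq="ATGTAA", cds_start=0, cds_end=6,
                present=present, gene_ids={sp: f"{sp}_{gid}" for sp in sim.SPECIES})
            for sp in sim.SPECIES:
                if present[sp]:
                    sets[sp].append(TranscriptRecord(f"{sp}_{gid}", sp, "ATGTAA"))
        return truth, sets

    @staticmethod
    def _enrichment_pvals(truth, sets, ann, alpha=1.0):
        core = {g.gene_ids[sp] for g in truth.genes.values()
                if all(g.present.values()) for sp in sim.SPECIES}
        everything = {r.id for v in sets.values() for r in v}
        return hypergeom_enrichment(core, everything, ann, alpha=alpha)

    def test_no_enrichment_type_one_rate(self):
        """With no planted terms, nothing clears the 1e-5 cutoff across 200
        simulated annotation replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        for rep in range(200):
            truth, sets = self._manual_truth(rng, 250, core_frac=0.85)
            p = params(seed=int(rng.integers(2**31)))
            ann = sim.simulate_annotation_tables(sets, p, truth,
                                                 n_terms=25, enriched_terms=[])
            rows = self._enrichment_pvals(truth, sets, ann, alpha=1e-5)
            hits += bool(rows)
        assert hits == 0

    def test_planted_term_power(self):
        """A term planted at an elevated rate among core genes is detected in
        at least 95% of replicates."""
        rng = np.random.default_rng(77)
        detected = 0
        for rep in range(60):
            truth, sets = self._manual_truth(rng, 250, core_frac=0.6)
            p = params(seed=int(rng.integers(2**31)))
            ann = sim.simulate_annotation_tables(
                sets, p, truth, n_terms=25, enriched_terms=["T0000"],
                enrich_prob=0.25)
            rows = self._enrichment_pvals(truth, sets, ann, alpha=1e-5)
            detected += any(r.term == "T0000" for r in rows)
        assert detected / 60 >= 0.95

    def test_single_term_everywhere_not_enriched(self):
        rng = np.random.default_rng(5)
        truth, sets = self._manual_truth(rng, 50, core_frac=0.8)
        ann = {r.id: ["T0000"] for v in sets.values() for r in v}
        rows = self._enrichment_pvals(truth, sets, ann, alpha=1.01)
        (row,) = [r for r in rows if r.term == "T0000"]
        assert row.p_value == pytest.approx(1.0)


def test_seed_determinism_whole_bundle():
    """Identical params and seed reproduce every generated artifact."""
    outs = []
    for _ in range(2):
        p = params(n_genes=8)
        ancestors, truth = sim.simulate_ancestors(p)
        sets = sim.evolve_triple(ancestors, p, truth)
        sets = sim.plant_paralogs(sets, p, truth)
        tables = sim.simulate_similarity_tables(sets, p, truth)
        ann = sim.simulate_annotation_tables(sets, p, truth)
        outs.append((
            {sp: [(r.id, r.seq) for r in v] for sp, v in sets.items()},
            {k: [dataclasses.astuple(h) for h in v] for k, v in tables.items()},
            ann,
        ))
    assert outs[0] == outs[1]
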