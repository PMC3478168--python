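"""End-to-end orchestration: simulate (optionally), then run every stage
and emit the full TSV/Newick report bundle into a run directory.

The bundle is a pure function of (config, inputs): a single seed keys all
stochastic stages, file iteration orders are sorted, and floats are written
at fixed precision, so two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import divergence as dv
from . import expression as xp
from . import families as fm
from . import orthology as oy
from . import phylogeny as ph
from . import selection as sl
from . import simulate as sim
from . import snp as sn
from .io_formats import (
    load_config_file, log, parse_blast_tab, parse_sam_min, read_fasta,
    setup_logging, write_blast_tab, write_fasta, write_newick, write_sam,
    write_tsv_report,
)


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline, with the published defaults."""

    min_len: int = 200             # minimum transcript length for RBH pairs (bp)
    prot_evalue: float = 1e-5      # reference-protein hit ceiling
    cds_min: int = 150             # minimum CDS length (bp)
    stop_window: int = 30          # stop-codon search window (bp, inclusive)
    utr_min_block: int = 30        # UTR stringency surrogate: block length (bp)
    utr_min_ident: float = 70.0    # ... and percent identity
    inflation: float = 1.6         # MCL inflation
    enrich_alpha: float = 1e-5     # hypergeometric cutoff (raw p)
    min_category_members: int = 5  # identity-by-category suppression
    rpkm_low: float = 20.0
    rpkm_high: float = 50.0
    snp_min_depth: int = 10
    snp_min_alt_count: int = 3
    snp_min_alt_freq: float = 0.2
    distance_model: str = "TN93"
    gc_mode: str = "first"
    seed: int = 0
    quiet: bool = False
    evol: sim.EvolParams = field(default_factory=sim.EvolParams)

    def validate(self) -> None:
        for name in ("min_len", "cds_min", "stop_window", "utr_min_block",
                     "snp_min_depth", "snp_min_alt_count", "min_category_members"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        self.evol.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        evol = sim.EvolParams(**data.pop("evol", {}))
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data, evol=evol)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cfg = cls.from_dict(load_config_file(path))
        cfg.evol.seed = cfg.seed
        return cfg


REPORT_FORMATS = {
    "divergence_pct": "%.2f", "se_pct": "%.2f", "binomial_se_pct": "%.3f",
    "pct_cpg": "%.2f", "pct_gc": "%.2f", "ts_tv": "%.2f",
    "homology_pct": "%.2f", "rpkm": "%.1f", "mean_identity_pct": "%.2f",
    "Ka": "%.4f", "Ks": "%.4f", "ka_ks": "%.4f", "fisher_p": "%.3e",
    "p_value": "%.3e", "p_bonferroni": "%.3e",
    "S": "%.2f", "N": "%.2f", "Sd": "%.2f", "Nd": "%.2f",
}


# ---------------------------------------------------------------------------
# simulation stage
# ---------------------------------------------------------------------------

def simulate_inputs(config: PipelineConfig,
                    outdir: Path) -> tuple[dict[str, Path], sim.TruthTable]:
    """Generate the full synthetic input bundle plus ground-truth tables."""
    params = config.evol
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    ancestors, truth = sim.simulate_ancestors(params)
    species_sets = sim.evolve_triple(ancestors, params, truth)
    species_sets = sim.plant_paralogs(species_sets, params, truth)
    reads = sim.simulate_reads(species_sets["A"], params, truth)
    nt_tables = sim.simulate_similarity_tables(species_sets, params, truth)
    prot_tables = sim.simulate_protein_hits(species_sets, params, truth)
    allvall = sim.simulate_allvall_protein_hits(species_sets, params, truth)
    annotations = sim.simulate_annotation_tables(species_sets, params, truth)
    proteins = sim.reference_proteins(truth)

    paths: dict[str, Path] = {}
    for sp in sim.SPECIES:
        paths[f"fasta_{sp.lower()}"] = p = outdir / f"{sp}.fa"
        write_fasta(species_sets[sp], p)
    paths["ref_proteins"] = outdir / "ref_proteins.fa"
    write_fasta(proteins, paths["ref_proteins"])
    for (qsp, ssp), hits in nt_tables.items():
        key = f"hits_{qsp.lower()}{ssp.lower()}"
        paths[key] = p = outdir / f"{key}.tsv"
        write_blast_tab(hits, p)
    for sp, hits in prot_tables.items():
        key = f"prot_{sp.lower()}"
        paths[key] = p = outdir / f"{key}.tsv"
        write_blast_tab(hits, p, frame_column=True)
    paths["allvall"] = outdir / "allvall.tsv"
    write_blast_tab(allvall, paths["allvall"])
    paths["sam_a"] = outdir / "reads_A.sam"
    write_sam(reads, {r.id: len(r.seq) for r in species_sets["A"]}, paths["sam_a"])
    paths["annotations"] = outdir / "annotations.tsv"
    with open(paths["annotations"], "w") as fh:
        fh.write("gene\tterm\n")
        for gid in sorted(annotations):
            for term in annotations[gid]:
                fh.write(f"{gid}\t{term}\n")

    # ground-truth bundle
    write_tsv_report(
        [{"ancestor": g.anc_id, "cds_start": g.cds_start, "cds_end": g.cds_end,
          **{f"present_{sp}": int(g.present[sp]) for sp in sim.SPECIES},
          "abundance": f"{g.abundance:.6f}"}
         for g in (truth.genes[a] for a in sorted(truth.genes))],
        ["ancestor", "cds_start", "cds_end", "present_A", "present_B",
         "present_C", "abundance"],
        truth_dir / "genes.tsv")
    write_tsv_report(
        [{"paralog": d, "source": s} for d, s in sorted(truth.paralogs.items())],
        ["paralog", "source"], truth_dir / "paralogs.tsv")
    write_tsv_report(
        [{"species": s.species, "gene": s.gene_id, "pos": s.pos,
          "ref": s.ref, "alt": s.alt, "freq": s.freq} for s in truth.snps],
        ["species", "gene", "pos", "ref", "alt", "freq"], truth_dir / "snps.tsv")
    (truth_dir / "enriched_terms.txt").write_text(
        "\n".join(truth.enriched_terms) + "\n")
    paths["_truth"] = truth_dir
    return paths, truth  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

def run_expression(config: PipelineConfig, sam_path, fasta_path, out_path) -> list[xp.ExpressionRecord]:
    alignments = parse_sam_min(sam_path)
    lengths = {r.id: len(r.seq) for r in read_fasta(fasta_path)}
    counts = xp.count_mapped_reads(alignments)
    records = xp.compute_rpkm(counts, lengths, total_mapped=len(alignments))
    xp.bin_expression(records, low_cut=config.rpkm_low, high_cut=config.rpkm_high)
    write_tsv_report(
        [{"gene": r.gene_id, "length_bp": r.length, "reads": r.raw_reads,
          "rpkm": r.rpkm, "expr_class": r.expr_class} for r in records],
        ["gene", "length_bp", "reads", "rpkm", "expr_class"],
        out_path, formats=REPORT_FORMATS)
    return records


@dataclass
class OrthologyResult:
    pairs: list[oy.OrthologPair]
    partitions: list[oy.RegionPartition]
    aligned: dict[str, list[oy.AlignedRegionPair]]  # keyed by gene_a
    seqs_a: dict[str, str]
    seqs_b: dict[str, str]


def run_orthology(config: PipelineConfig, fasta_a, fasta_b, hits_ab, hits_ba,
                  prot_a, prot_b, ref_proteins, pairs_out, regions_out) -> OrthologyResult:
    recs_a = read_fasta(fasta_a, species="A")
    recs_b = read_fasta(fasta_b, species="B")
    seqs_a = {r.id: r.seq for r in recs_a}
    seqs_b = {r.id: r.seq for r in recs_b}
    prot_lens = {r.id: len(r.seq) for r in read_fasta(ref_proteins)}
    h_ab, h_ba = parse_blast_tab(hits_ab), parse_blast_tab(hits_ba)
    ph_a, ph_b = parse_blast_tab(prot_a), parse_blast_tab(prot_b)

    candidates = oy.reciprocal_best_hits(
        h_ab, h_ba, {k: len(v) for k, v in seqs_a.items()},
        {k: len(v) for k, v in seqs_b.items()}, min_len=config.min_len)
    pairs = oy.filter_same_reference(candidates, ph_a, ph_b,
                                     evalue_max=config.prot_evalue)
    scoring = oy.AlignScoring(utr_min_block=config.utr_min_block,
                              utr_min_ident=config.utr_min_ident)
    seqs = dict(seqs_a)
    seqs.update(seqs_b)
    partitions = []
    for pair in pairs:
        try:
            partitions.append(oy.delineate_regions(
                pair, seqs, ph_a, ph_b, prot_lens, stop_window=config.stop_window))
        except oy.DelineationError as exc:
            log.info("delineation dropped pair (%s, %s): %s",
                     pair.gene_a, pair.gene_b, exc)
    partitions = oy.filter_regions(partitions, cds_min_len=config.cds_min,
                                   scoring=scoring)
    aligned = {p.pair.gene_a: oy.align_pair_regions(p, scoring) for p in partitions}

    kept_pairs = [p.pair for p in partitions]
    write_tsv_report(
        [{"gene_a": p.gene_a, "gene_b": p.gene_b, "ref_protein": p.ref_protein,
          "evalue_a": f"{p.evalue_a:.2e}", "evalue_b": f"{p.evalue_b:.2e}"}
         for p in kept_pairs],
        ["gene_a", "gene_b", "ref_protein", "evalue_a", "evalue_b"], pairs_out)
    rows = []
    for part in partitions:
        for side, m in (("a", part.a), ("b", part.b)):
            rows.append({
                "gene": m.gene, "member": side,
                "cds_start": m.cds_start, "cds_end": m.cds_end,
                "utr5": f"{m.utr5[0]}-{m.utr5[1]}" if m.utr5 else "",
                "utr3": f"{m.utr3[0]}-{m.utr3[1]}" if m.utr3 else "",
                "start_missing": int(m.start_missing),
                "stop_missing": int(m.stop_missing),
            })
    write_tsv_report(rows, ["gene", "member", "cds_start", "cds_end", "utr5",
                            "utr3", "start_missing", "stop_missing"], regions_out)
    return OrthologyResult(pairs=kept_pairs, partitions=partitions,
                           aligned=aligned, seqs_a=seqs_a, seqs_b=seqs_b)


def run_divergence(config: PipelineConfig, ortho: OrthologyResult,
                   annotations: dict[str, list[str]],
                   summary_out, homology_out, category_out):
    per_pair = []
    for part in ortho.partitions:
        regions = ortho.aligned[part.pair.gene_a]
        cells = dv.tally_pair(regions, part.a.seq, part.b.seq)
        per_pair.append((f"{part.pair.gene_a}|{part.pair.gene_b}", cells))
    rows, homology, stats = dv.summarize_divergence(per_pair, gc_mode=config.gc_mode)
    write_tsv_report(
        [{"region": r.region, "class": r.cls, "loci": r.loci,
          "substitutions": r.substitutions, "compared_bp": r.compared_bp,
          "divergence_pct": r.divergence_pct, "se_pct": r.se_pct,
          "binomial_se_pct": r.binomial_se_pct, "ts": r.ts, "tv": r.tv,
          "ts_tv": r.ts_tv, "pct_cpg": r.pct_cpg, "pct_gc": r.pct_gc}
         for r in rows],
        ["region", "class", "loci", "substitutions", "compared_bp",
         "divergence_pct", "se_pct", "binomial_se_pct", "ts", "tv", "ts_tv",
         "pct_cpg", "pct_gc"],
        summary_out, formats=REPORT_FORMATS)
    write_tsv_report(
        [{"pair": h.pair_id, "compared_bp": h.compared_bp,
          "substitutions": h.substitutions, "homology_pct": h.homology_pct}
         for h in homology],
        ["pair", "compared_bp", "substitutions", "homology_pct"],
        homology_out, formats=REPORT_FORMATS)
    pair_hom = [((h.pair_id.split("|")[0], h.pair_id.split("|")[1]), h.homology_pct)
                for h in homology]
    cats = dv.group_identity_by_category(pair_hom, annotations,
                                         min_members=config.min_category_members)
    write_tsv_report(
        [{"category": c, "n_pairs": n, "mean_identity_pct": m} for c, n, m in cats],
        ["category", "n_pairs", "mean_identity_pct"], category_out,
        formats=REPORT_FORMATS)
    return rows, homology, stats


def run_selection(config: PipelineConfig, ortho: OrthologyResult, out_path) -> list[sl.KaKsResult]:
    results = []
    for part in ortho.partitions:
        cds = next((r for r in ortho.aligned[part.pair.gene_a] if r.region == "cds"), None)
        if cds is None:
            continue
        # reconstruct the gapless aligned codon sequences
        codons_a = []
        codons_b = []
        for k in range(0, len(cds.columns) - 2, 3):
            if cds.phases[k] != 0:
                continue
            (ia, ja), (ib, jb), (ic, jc) = cds.columns[k : k + 3]
            if not (ib == ia + 1 and ic == ia + 2 and jb == ja + 1 and jc == ja + 2):
                continue
            codons_a.append(part.a.seq[ia : ia + 3])
            codons_b.append(part.b.seq[ja : ja + 3])
        if not codons_a:
            continue
        result = sl.kaks_pair("".join(codons_a), "".join(codons_b),
                              pair_id=f"{part.pair.gene_a}|{part.pair.gene_b}")
        results.append(result)
    write_tsv_report(
        [{"pair": r.pair_id, "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
          "Ka": r.Ka, "Ks": r.Ks, "ka_ks": r.ratio, "fisher_p": r.fisher_p,
          "flag": r.flag} for r in results],
        ["pair", "S", "N", "Sd", "Nd", "Ka", "Ks", "ka_ks", "fisher_p", "flag"],
        out_path, formats=REPORT_FORMATS)
    return results


def run_families(config: PipelineConfig, species_fastas: dict[str, Path],
                 prot_hit_paths: dict[str, Path], allvall_path,
                 annotations: dict[str, list[str]],
                 families_out, venn_out, enrich_out):
    genes: list[fm.TranslatedGene] = []
    for sp in sorted(species_fastas):
        transcripts = read_fasta(species_fastas[sp], species=sp)
        hits = parse_blast_tab(prot_hit_paths[sp])
        genes.extend(fm.prepare_translations(
            transcripts, hits, min_nt_len=config.min_len,
            evalue_max=config.prot_evalue))
    allvall = parse_blast_tab(allvall_path)
    families = fm.mcl_cluster(genes, allvall, inflation=config.inflation)
    venn = fm.classify_families(families)
    core_genes = {g for f in families if f.is_core for m in f.members.values() for g in m}
    all_genes = {g.gene_id for g in genes}
    species_of = {g.gene_id: g.species for g in genes}
    enriched = fm.hypergeom_enrichment(core_genes, all_genes, annotations,
                                       alpha=config.enrich_alpha,
                                       species_of=species_of)
    write_tsv_report(
        [{"family": f.family_id, "is_core": int(f.is_core),
          **{f"n_{sp}": len(f.members.get(sp, [])) for sp in ("A", "B", "C")},
          "members": ",".join(sorted(sum(f.members.values(), [])))}
         for f in families],
        ["family", "is_core", "n_A", "n_B", "n_C", "members"], families_out)
    write_tsv_report(
        [{"species_set": "+".join(sorted(k)), "n_families": v}
         for k, v in sorted(venn.items(), key=lambda kv: "+".join(sorted(kv[0])))],
        ["species_set", "n_families"], venn_out)
    write_tsv_report(
        [{"term": r.term, "k_core": r.k_core, "K_population": r.K_population,
          "n_core": r.n_core, "N_population": r.N_population,
          **{f"n_{sp}": r.per_species.get(sp, 0) for sp in ("A", "B", "C")},
          "p_value": r.p_value, "p_bonferroni": r.p_bonferroni}
         for r in enriched],
        ["term", "k_core", "K_population", "n_core", "N_population",
         "n_A", "n_B", "n_C", "p_value", "p_bonferroni"],
        enrich_out, formats=REPORT_FORMATS)
    return families, venn, enriched


def run_phylogeny(config: PipelineConfig, ortho_ab: OrthologyResult,
                  ortho_ac: OrthologyResult, tree_out, dist_out):
    pairs_ab = [(p.gene_a, p.gene_b) for p in ortho_ab.pairs]
    pairs_ac = [(p.gene_a, p.gene_b) for p in ortho_ac.pairs]
    triples = ph.threeway_orthologs(pairs_ab, pairs_ac)

    def cds_columns(ortho: OrthologyResult) -> dict[str, list[tuple[int, int]]]:
        out = {}
        for part in ortho.partitions:
            cds = next((r for r in ortho.aligned[part.pair.gene_a]
                        if r.region == "cds"), None)
            if cds:
                out[part.pair.gene_a] = cds.columns
        return out

    seqs: dict[str, str] = {}
    for ortho in (ortho_ab, ortho_ac):
        for part in ortho.partitions:
            seqs[part.pair.gene_a] = part.a.seq
            seqs[part.pair.gene_b] = part.b.seq
    alignment = ph.build_concatenation(triples, cds_columns(ortho_ab),
                                       cds_columns(ortho_ac), seqs)
    dm = ph.pairwise_distance(alignment, model=config.distance_model)
    tree = ph.nj_tree(dm)
    write_newick(tree, tree_out)
    write_tsv_report(
        [{"taxon": lab, **{other: f"{dm.matrix[i, j]:.6f}"
                           for j, other in enumerate(dm.labels)}}
         for i, lab in enumerate(dm.labels)],
        ["taxon", *dm.labels], dist_out)
    return alignment, dm, tree


def run_snp(config: PipelineConfig, sam_path, ortho: OrthologyResult, out_path) -> list[sn.SnpCall]:
    alignments = parse_sam_min(sam_path)
    intervals = {p.a.gene: (p.a.cds_start, p.a.cds_end) for p in ortho.partitions}
    cds_seqs = {p.a.gene: p.a.seq[p.a.cds_start : p.a.cds_end]
                for p in ortho.partitions}
    piles = sn.pileup_cds(alignments, intervals)
    calls = sn.call_snps(piles, cds_seqs, min_depth=config.snp_min_depth,
                         min_alt_count=config.snp_min_alt_count,
                         min_alt_freq=config.snp_min_alt_freq)
    write_tsv_report(
        [{"gene": c.gene_id, "cds_pos": c.cds_pos, "ref": c.ref, "alt": c.alt,
          "depth": c.depth, "alt_count": c.alt_count,
          "effect": c.effect or "undetermined",
          "ref_aa": c.ref_aa or "", "alt_aa": c.alt_aa or ""} for c in calls],
        ["gene", "cds_pos", "ref", "alt", "depth", "alt_count", "effect",
         "ref_aa", "alt_aa"], out_path)
    return calls


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def load_annotation_table(path) -> dict[str, list[str]]:
    ann: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene, term = line.rstrip("\n").split("\t")
            ann.setdefault(gene, []).append(term)
    return {g: sorted(t) for g, t in ann.items()}


def run_all(config: PipelineConfig, workdir, simulate: bool = True,
            manifest: dict | None = None, allow_partial: bool = False) -> dict:
    """Run every stage in order; returns a summary dict of outputs and counts.

    In simulate mode the generator writes the inputs first; otherwise the
    manifest must name them.  A missing input halts before any stage runs
    unless ``allow_partial`` lets read-dependent stages be skipped.
    """
    config.validate()
    setup_logging(config.quiet)
    workdir = Path(workdir)
    outdir = workdir / "reports"
    outdir.mkdir(parents=True, exist_ok=True)
    if simulate:
        config.evol.seed = config.seed
        inputs, _truth = simulate_inputs(config, workdir / "inputs")
    else:
        if manifest is None:
            raise ValueError("manifest required when not simulating")
        inputs = {k: Path(v) for k, v in manifest.items()}
        required = ["fasta_a", "fasta_b", "hits_ab", "hits_ba", "prot_a",
                    "prot_b", "ref_proteins"]
        missing = [k for k in required if k not in inputs or not inputs[k].exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")

    summary: dict = {"outputs": {}, "counts": {}}

    def out(name: str) -> Path:
        p = outdir / name
        summary["outputs"][name] = str(p)
        return p

    have_sam = "sam_a" in inputs and Path(inputs["sam_a"]).exists()
    if have_sam:
        records = run_expression(config, inputs["sam_a"], inputs["fasta_a"],
                                 out("expression_A.tsv"))
        summary["counts"]["expression_genes"] = len(records)
    elif not allow_partial:
        raise FileNotFoundError("sam_a input missing (use allow_partial to skip)")
    else:
        log.warning("run_all: expression stage skipped (no SAM input)")

    annotations = (load_annotation_table(inputs["annotations"])
                   if "annotations" in inputs else {})

    ortho_results: dict[str, OrthologyResult] = {}
    for other in ("b", "c"):
        key_ab, key_ba = f"hits_a{other}", f"hits_{other}a"
        if key_ab not in inputs:
            continue
        ortho_results[other] = run_orthology(
            config, inputs["fasta_a"], inputs[f"fasta_{other}"],
            inputs[key_ab], inputs[key_ba], inputs["prot_a"],
            inputs[f"prot_{other}"], inputs["ref_proteins"],
            out(f"ortholog_pairs_A{other.upper()}.tsv"),
            out(f"regions_A{other.upper()}.tsv"))
        summary["counts"][f"ortholog_pairs_A{other.upper()}"] = \
            len(ortho_results[other].pairs)

    ortho_ab = ortho_results.get("b")
    if ortho_ab is None:
        raise RuntimeError("orthology stage produced no A-B pairs")

    rows, homology, stats = run_divergence(
        config, ortho_ab, annotations, out("divergence_summary_AB.tsv"),
        out("pair_homology_AB.tsv"), out("category_identity_AB.tsv"))
    summary["counts"]["divergence_cells"] = len(rows)
    if stats:
        summary["counts"]["mean_homology_pct"] = round(stats.mean_homology_pct, 4)

    kaks = run_selection(config, ortho_ab, out("kaks_AB.tsv"))
    summary["counts"]["kaks_pairs"] = len(kaks)

    if "allvall" in inputs:
        fastas = {sp: inputs[f"fasta_{sp.lower()}"] for sp in ("A", "B", "C")
                  if f"fasta_{sp.lower()}" in inputs}
        prots = {sp: inputs[f"prot_{sp.lower()}"] for sp in fastas}
        families, venn, enriched = run_families(
            config, fastas, prots, inputs["allvall"], annotations,
            out("families.tsv"), out("venn_counts.tsv"), out("enrichment.tsv"))
        summary["counts"]["families"] = len(families)
        summary["counts"]["core_families"] = sum(f.is_core for f in families)
        summary["counts"]["enriched_terms"] = len(enriched)

    if "c" in ortho_results:
        alignment, dm, tree = run_phylogeny(
            config, ortho_ab, ortho_results["c"], out("tree.nwk"),
            out("distances.tsv"))
        summary["counts"]["concat_columns"] = alignment.n_columns

    if have_sam:
        calls = run_snp(config, inputs["sam_a"], ortho_ab, out("snps_A.tsv"))
        summary["counts"]["snps_A"] = len(calls)
        summary["counts"]["snps_A_synonymous"] = \
            sum(c.effect == "synonymous" for c in calls)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"outputs": sorted(summary["outputs"]),
                   "counts": summary["counts"]}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
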