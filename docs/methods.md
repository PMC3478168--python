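# Methods

## The analysis

orthodiv reconstructs the comparative-transcriptomics workflow used to
quantify divergence between closely related insect species from assembled
transcripts alone: ortholog identification between species pairs, coding /
untranslated region delineation from reference-protein alignments,
site-class-partitioned divergence, Ka/Ks selection screening, protein-family
clustering across three species, a neighbor-joining phylogeny, read-based
expression quantification, and within-species SNP calling. The stages are
independent library modules; `pipeline.run_all` chains them and a single
seed makes the whole bundle reproducible byte for byte.

## Orthology and region delineation

Candidate pairs are reciprocal best hits by **bitscore** (e-values are used
only as thresholds, because bitscores are database-size independent). Any
tie for best excludes the query — the conservative reading of
"unambiguous". Both sequences must be at least `min_len` = 200 bp. The
paralog filter requires each member's unique best reference-protein hit to
be the **same protein** at E < 1e-5.

The CDS is delineated by projecting reference residue 1 through the protein
hit's coordinates: the start codon is the in-frame ATG nearest that
projection (searching upstream within the transcript first, then downstream
within the aligned region); the stop codon is the first in-frame
TAA/TAG/TGA within ±30 bp (inclusive) of the projected reference stop,
scanning 5'→3'. A missing start or stop sets a partial flag and clips the
CDS to the aligned region. Negative-frame protein hits reverse-complement
the transcript first; all downstream coordinates refer to the re-oriented
sequence. CDS pairs shorter than 150 bp or containing an internal in-frame
stop are discarded.

CDS pairs are aligned codon-aware: translate, global protein alignment
(BLOSUM62, gap open 11 / extend 1), back-mapped to nucleotides; the
terminal stop codon and all gap columns are excluded. UTRs are aligned by
optimal local nucleotide alignment (match +2, mismatch −3, gap open 5 /
extend 2). Because no installed search engine statistic is computed here,
the published UTR e-value cutoff (E < 1e-30) is replaced by a surrogate
stringency: the best local block must span ≥ 30 bp at ≥ 70% identity (both
configurable). This is a documented deviation; at the divergence levels in
question it keeps essentially all genuine UTR pairs while rejecting random
sequence.

## Site classes and divergence

A codon position is **nd** (nondegenerate) when all three alternative bases
change the amino acid (a change to a stop counts as a change) and **4d**
when none does; a column is labelled nd/4d only when *both* codons agree,
otherwise it falls into "other", which counts in the "all" cell but in
neither subset (the published table reports nd and 4d as subsets of CDS,
not a partition). A column is **CpG** when its base participates in a CG
dinucleotide in *either* sequence, evaluated on the full original sequence
so context outside the aligned region counts; the union rule keeps every
cell symmetric under species swap.

Pooled divergence is total substitutions over total compared base pairs
(columns containing N are excluded everywhere). The primary SE column is
the across-locus standard error — the standard deviation of per-locus
divergences over √loci — because at thousands of loci the between-locus
dispersion dominates the binomial error; the binomial SE is emitted as a
secondary column. %GC counts G/C bases of the first species by default
(`gc_mode="mean"` averages the two); the choice is recorded in the report.
Per-pair homology is 100 − per-pair CDS divergence; the homology block
reports both dispersion candidates (SD of the per-pair divergence as a
proportion and as a percentage) since either scale may be wanted.

## Ka/Ks

The NG86 estimator is used because every step is brute-force verifiable:
synonymous site fractions per codon position (mutations to stops count
nonsynonymous), averaged between the two sequences; observed differences
averaged over all minimal substitution paths, excluding paths through stop
codons (with stop-passing paths as a fallback when all are blocked, so the
codon pair still contributes); Jukes–Cantor correction, undefined when
4p/3 ≥ 1. The Fisher exact 2×2 is (differences vs remaining sites) with
site counts rounded to integers; the rounding error is bounded by half a
site. A YN-style estimator was deliberately not implemented — NG86 is the
primary, fully specified method here.

## Protein families and enrichment

Edge weight is the larger bitscore of the two directed hits; self-loops are
set to each node's maximum incident weight before column normalization
(standard Markov-clustering practice). Iteration alternates expansion
(matrix square) and inflation (entrywise power 1.6, renormalize) with
per-column pruning below 1e-12, until the largest entry change is below
1e-8 or 200 iterations (non-convergence returns the current clustering with
a warning flag). Clusters are the connected components of the limit
matrix's support; singletons are allowed. The "longest translated region ≥
200 bp" filter is read literally as a nucleotide span (~66 aa).

Enrichment restricts the urn to annotated genes: population = annotated
genes overall, successes = carriers of the term, draws = annotated core
genes, p = P(X ≥ k) from the exact hypergeometric tail. The cutoff is a raw
p < 1e-5 with no correction, matching the published procedure; Bonferroni
values are reported in a side column for transparency.

## Phylogeny

Gene triples anchor on the A member (the species common to both pair
lists); an A-gene paired ambiguously in either list is dropped. Columns
present in both pairwise CDS alignments are concatenated in stable gene-id
order with gap and N columns removed. Distances are closed-form p, K2P or
TN93 (default TN93, which accommodates unequal base frequencies and
distinct purine/pyrimidine transition rates); the original analysis used
MEGA's Maximum Composite Likelihood, which is not re-implemented — a
documented substitution, both being "substitutions per site" on near-equal
scales at these divergences. The tree is Saitou–Nei neighbor joining with
an exact linear solve for the final three branches; negative branch lengths
are clamped to zero with a warning.

## Expression and SNPs

RPKM = reads × 10⁹ / (length × total mapped reads), where "total mapped"
counts SAM records kept by the reader, not raw sequencer output. The
published strict inequalities (high > 50, medium 50 > RPKM > 20, low < 20)
leave the boundary values unassigned; both 20 and 50 are binned medium so
the classes partition.

Pileups honor M/I/D CIGAR operations only (transcript-space alignment needs
no splicing); insertions are ignored and deletions skip columns. The
published gate is depth ≥ 10; the alternate-allele support gates (minor
count ≥ 3 and frequency ≥ 0.2, both configurable) are this package's own
addition — without them any single discordant base at depth 10 becomes a
call — and are labelled as such in the output header. The reference allele
is the assembled transcript base. Effect classification substitutes the
alternate base into its codon; a change to a stop codon is nonsynonymous,
and a codon containing N leaves the effect undetermined.

## The synthetic-data generator

The generator is first-class, tested code that defines the study conditions
for every end-to-end check. Each ancestral gene is 5'UTR + CDS + 3'UTR with
the CDS codon-structured (ATG, uniform sense codons, one terminal stop).
Evolution along each terminal branch proposes mutations per site at rate
t × class multiplier — ×`cpg_mult` at sites inside a CG dinucleotide of the
ancestor, ×`utr_rate_mult` outside the CDS — with transitions favored
kappa : 1 per alternative. Amino-acid-changing proposals are accepted with
probability `f_nd` at ancestrally nondegenerate sites and `f_ns` at other
coding sites; synonymous and UTR proposals are always accepted;
stop-creating (and terminal-stop-destroying) proposals are always rejected,
so the CDS filter downstream never discards genes nondeterministically.

Two conventions make the per-class expectations analytically and
Monte-Carlo checkable: CpG context and the nd classification are both
**frozen at the ancestor** (no re-evaluation after mutation), matching how
sites are classified downstream at these divergences. An optional
deamination mode (`cpg_ts_only`) makes CpG-site proposals C→T/G→A only,
reproducing the elevated CpG transition/transversion ratio seen in real
data; it is off by default because the default conditions only need the
rate elevation.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 500 | enough loci for stable pooled per-class estimates at desk scale |
| `cds_len_range` | 300–900 bp | brackets the observed mean aligned CDS length (~480 bp) |
| `utr5/utr3_len_range` | 20–100 / 40–160 bp | 5'UTRs shorter than 3'UTRs; many fall below the 30-bp UTR stringency, as in the real data where few UTR pairs survive |
| `t_A, t_B, t_C` | 0.02, 0.005, 0.005 | outgroup-vs-ingroup asymmetry of the three-species system (A–B and A–C divergence ≈ 2× B–C) |
| `kappa` | 4 | transition bias reproducing CDS ts/tv ≈ 2–3 |
| `cpg_mult` | 6 | CpG/non-CpG divergence ratio of ~5–6 observed in the CDS |
| `f_nd`, `f_ns` | 0.1, 0.3 | strong constraint at nd sites (nd ≪ 4d divergence), moderate elsewhere; yields mean Ka/Ks ≈ 0.1–0.2 |
| `utr_rate_mult` | 1.7 | UTR divergence ~1.5–2× CDS |
| `paralog_frac` | 0.1 | exercises the same-protein filter with a visible planted signal |
| `het_rate` | 0.1 /gene | within the observed per-gene SNP range (~0.05–0.25) |
| `read_len` | 74 bp | the platform read length |
| `mean_coverage` | 30× | most planted heterozygous sites clear the depth-10 gate while some fail it, so both gate branches are exercised |
| `abundance_sigma` | 1.2 | right-skewed log-normal expression: the top class carries a disproportionate read share |
| `loss_frac` | 0.15 | per-gene absence from one random species, so non-core family categories exist |

Reads are error-free (an error-rate knob defaults to 0), ungapped, with
uniform start positions; per-gene counts are Poisson around abundance ×
length (abundance log-normal), the standard count model for shotgun data.
Genes with planted heterozygous SNPs emit reads from two haplotypes at
frequency 0.5. Similarity tables carry observed identities with e-values
decreasing in score, competing paralog hits, and a low rate of spurious
high-e-value hits. Reference "proteins" are the translated ancestral CDSs —
synthetic stand-ins for a protein database, named as such.

What the generator does **not** emulate: indels (so real-data alignment
gaps are exercised only by dedicated unit fixtures), sequencing error,
codon-usage and composition bias, recombination, paired-end structure, and
assembly artifacts. Passing end-to-end tests therefore demonstrates the
correctness of the counting, filtering and estimation machinery under a
clean generative model, not robustness to assembly noise.

## Numerical choices

* Coordinates are 1-based inclusive at every file boundary (BLAST/SAM
  convention) and 0-based half-open internally; conversion is confined to
  the I/O module.
* One `numpy` SeedSequence-style stream per run keyed by the seed, with
  per-gene substreams, so partial re-runs reproduce; all iteration orders
  are sorted and floats are written at fixed precision — two runs with the
  same seed are byte-identical.
* Alignment tie-breaks take the aligner's first reported optimum
  (deterministic for fixed inputs).
* Divergence cells with zero compared bp are emitted with the value
  undefined (blank), as is ts/tv with zero transversions and the
  across-locus SE at a single locus.
* MCL: tolerance 1e-8, cap 200 iterations, pruning 1e-12 — values logged in
  the module docstring and configurable.
* Distance saturation (a non-positive logarithm argument) raises an error
  naming the pair rather than returning NaN.

## Problem sizes used in the checks

The end-to-end checks run the default 500-gene triple (~260 kb of aligned
CDS) and verify pooled per-class divergences against an independent
per-site Monte-Carlo oracle at one million coding sites plus ~5,000
simulated UTR pairs per region, at a tolerance of three combined
Monte-Carlo standard errors. Exact-test verification enumerates every
hypergeometric urn with population ≤ 60 and every 2×2 Fisher table with
total ≤ 60 (up to the symmetry group). These sizes were chosen so the whole
suite completes in a few minutes on one CPU while leaving the statistical
tolerances comfortably narrower than the effects being checked.

## Known limitations

* NG86, not a maximum-likelihood codon model; with strong transition bias
  the neutral Ka/Ks expectation sits below 1 (verified explicitly in the
  tests), so absolute ratios are conservative.
* The UTR e-value stringency is a surrogate (block length + identity), not
  a Karlin–Altschul statistic.
* Best-local-block UTR extraction clips diverged block ends, biasing UTR
  divergence slightly downward; the Monte-Carlo oracle reproduces the same
  measurement, and the effect is a few percent relative at these lengths.
* One sequence per species: within-population polymorphism is collapsed by
  the consensus transcripts, so SNP calling and divergence are cleanly
  separated by construction.
* Multi-mapping reads are counted at their first reported alignment; there
  is no TPM/FPKM variant and no indel SNP calling.
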