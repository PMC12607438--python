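# Methods

This note documents the statistical models, the sequence models, the
synthetic-data generator and the numerical choices behind `cernanet`,
and states what the passing test suite does and does not demonstrate.

## Count model and differential expression

Counts for feature *f* in sample *s* are modeled as negative binomial
with mean μ_fs and variance μ_fs + φ·μ_fs² — the quadratic
mean–variance convention used by edgeR-style analyses. φ is a single
common dispersion per layer (no tagwise or trended shrinkage): with
three replicates per group there is little information for per-feature
dispersions, and a common φ keeps the test exactly enumerable and
oracle-checkable.

**Normalization.** Trimmed mean of M-values (TMM): the reference
column is the sample whose upper-quartile relative abundance is
closest to the mean; gene-wise log-ratios M and average abundances A
are computed on library-scaled counts against it; the M values are
trimmed 30% per tail and the A values 5% per tail; the
precision-weighted mean M gives each sample's factor, rescaled to
geometric mean 1. The implementation reproduces edgeR's
`calcNormFactors` to ≲0.5% on random matrices (one test runs edgeR via
Rscript as an independent cross-check; remaining differences are
tie-handling at the trim boundaries).

**Exact test.** For a two-group comparison the samples are first
scaled to the geometric-mean effective library size (rounding
half-to-even), so that per-sample means are equal under the null.
Conditioning on the total t of a feature, the group-A sum follows a
distribution obtained from the convolution of NB(n_a/φ) and NB(n_b/φ)
components whose success parameter cancels; φ = 0 gives the Poisson
limit, a Binomial(t, n_a/(n_a+n_b)) conditional. The two-sided p-value
follows the minimum-likelihood rule: the sum of the probabilities of
all splits s ∈ [0, t] with Pr(s) ≤ Pr(observed). This rule is
symmetric, exhaustively enumerable, and reduces to the standard
two-sided exact binomial test at φ = 0. Probabilities are compared
with a relative tie tolerance of 1e−12 so discrete ties count as "as
extreme"; p-values are clamped into (0, 1].

**Dispersion estimate.** Method of moments: per feature, the pooled
within-group variance s² and grand mean x̄ over all groups with ≥ 2
replicates give max(0, (s² − x̄)/x̄²); the layer estimate is the median
across features. The median of a χ²-distributed variance estimate sits
slightly below its mean, so the estimator is mildly conservative
toward 0 (≈ 8% low at 8 within-group degrees of freedom); simulations
at φ = 0.2 recover estimates within [0.15, 0.25].

**Calling rules.** circRNA and mRNA: |log₂FC| ≥ `lfc_min` (default 1)
and BH-adjusted q ≤ `q_max` (default 0.05). miRNA: raw p ≤ `p_max`
(default 0.05) with no fold-change filter — miRNA screens of this kind
conventionally use the unadjusted p, and no fold-change requirement is
imposed. log₂FC is log₂((CPM_B + 0.5)/(CPM_A + 0.5)) on group-mean
TMM-CPM; the 0.5 pseudocount keeps zero-count features finite. The
sign convention for contrast (A, B) is "positive = up in B". The
adjusted q is Benjamini–Hochberg (computed by
`scipy.stats.false_discovery_control`).

**qPCR utility.** `relative_quantification` implements 2^(−ΔΔCt):
ΔCt = Ct_target − Ct_reference per condition, ΔΔCt = ΔCt_treated −
ΔCt_control, fold change 2^(−ΔΔCt); replicate Ct vectors are averaged.

## Sequence model: sites, score, energy

Seed sites follow the canonical taxonomy on miRNA positions 2–8
(1-based): a 6mer core is a perfect Watson–Crick reverse complement of
positions 2–7 on the target; 7mer-m8 adds a match to position 8;
7mer-A1 adds an adenosine opposite position 1; 8mer has both. G:U
wobble is not accepted in the seed. All matching windows are reported
(no overlap resolution); coordinates are 0-based starts of the 6mer
core on the target as given (5′→3′; no reverse-strand scan). circRNAs
are scanned as their linear sequence with the first 7 nt appended, so
sites spanning the back-splice junction are found; site starts are
restricted to the original length to avoid duplicates.

The 0–100 **site score** is a declared, transparent scale — it is not
a re-fit of any published scoring model, it simply preserves the
conventional 0–100 range on which a "score ≥ 50" cutoff is meaningful:
base points per type (6mer 30, 7mer-A1 50, 7mer-m8 60, 8mer 75) plus
25 × (A/U fraction of the ±30 nt flanks), clamped to [0, 100]. The
base points order the types (8mer > 7mer-m8 > 7mer-A1 > 6mer) and the
AU bonus encodes the well-known accessibility preference for AU-rich
context. A bare 6mer cannot reach 50; a 7mer needs an AU-rich context;
an 8mer always passes.

The **duplex free energy** is a simplified nearest-neighbor sum:
helix initiation +4.09 kcal/mol plus one stacking term per adjacent
base-pair step in (a) the seed helix (positions 2–7, plus 8 for
m8-type sites; the A1 adenosine is recognized, not paired) and (b) the
longest contiguous complementary block between miRNA positions 12–17
and the 18 nt of target upstream of the site, where G:U wobble is
allowed. The stack table ships with the package: the ten Watson–Crick
classes carry Turner-2004 free energies; wobble-containing classes
carry representative negative magnitudes. Every entry is strictly
negative, so extending pairing strictly lowers the energy — the
monotonicity the pair filter relies on. No loop, bulge or full
hybridization folding is modeled; the scale is calibrated so that a
seed-only 6mer (≈ −3 to −9 kcal/mol) fails a −10 kcal/mol cutoff while
an 8mer with a 3′-supplementary block (≈ −14 to −22) passes.

A **target pair** keeps its best site (highest score, ties broken by
lower energy, then smaller position) and must pass both filters:
score ≥ `site_score_min` (50) AND energy ≤ `energy_max_kcal` (−10),
emulating the intersection of a seed-based and an energy-based
predictor.

## Correlation network and triads

Profiles are log₂(CPM+1) on TMM-normalized libraries, computed across
the samples of the contrast's two groups (n = 6 by default;
`correlation_samples: all` switches to the full design, n = 12).
Pearson r is tested with the t-distribution on n − 2 degrees of
freedom; p-values are raw by design (no multiplicity correction on
correlation edges — the conventional screen applies r and p cutoffs
directly). Constant profiles raise an explicit error rather than
returning a silent r = 0; pipeline code skips such features.

Candidate pairs are restricted before any correlation is computed:
circRNA–miRNA and miRNA–mRNA pairs require differential expression of
both members plus predicted binding; circRNA–mRNA pairs require a
shared predicted miRNA (this keeps the quadratic pair space
mechanistically admissible). Edge thresholds: r ≤ −0.4 and p ≤ 0.05
for the two repression edges; r ≥ +0.4 and p ≤ 0.05 for the
sponge–target support edge. The positive threshold mirrors the
negative one symmetrically; both are configurable. A triad is the join
of the three edge classes over a shared miRNA.

**Core selection.** Per comparison, miRNAs are ranked by the number of
distinct interaction pairs they participate in (circRNA–miRNA plus
miRNA–mRNA pairs over the triad set), with ties broken alphabetically;
the core is the intersection of the per-comparison top-k sets
(k = 10). Ranking by degree is one of several defensible readings of
"highest interaction probability across relationship pairs"; it is the
only quantity defined for a miRNA purely by the relationship pairs
themselves, and the ranking hook is pluggable. **Integration** keeps
triads whose (miRNA, mRNA) combination appears in both comparisons'
cores and whose mRNA is on the supplied whitelist (all triad mRNAs
when no whitelist is given), and flattens them into deduplicated
sponge/target interaction pairs.

**Permutation null.** The negative control permutes each layer's
sample columns *independently*. A single permutation shared by all
layers is not a null for this estimator: Pearson edges are invariant
under relabeling (the per-sample values never move), so only the DE
gate is affected, and the minority of permutations that re-align the
group partition let planted signal straight through. Independent
per-layer permutation destroys cross-layer association jointly and
empirically yields 0 triads at the default settings.

## Enrichment and PPI

Term enrichment is the one-sided upper-tail hypergeometric test of a
query set against term memberships. The universe defaults to all genes
present in the annotation map (not a genome): with user-supplied
annotations this is the only self-consistent background, and it is
overridable. BH adjustment is applied within each namespace. Terms
with zero overlap are skipped. No GO-DAG propagation or pathway
topology is modeled; annotation content is always user input, never
fetched.

PPI edges are undirected, de-duplicated, self-loop-free, and filtered
at confidence ≥ 0.40 (inclusive). Hubs are the top-n genes by degree,
ties broken by name.

## Synthetic-data generator

The generator emulates the structure of a grouped three-layer
transcriptome study:

* **Design** — 4 groups × 3 replicates (names Som/Stm/Sad/Ud in the
  pipeline default: juvenile, pre-pubertal and adult stages of one
  breed plus a second-breed adult group), 12 samples.
* **Scale** — 300 mRNAs, 80 circRNAs, 60 miRNAs, 10 planted axes:
  desk-scale, but with enough decoy features for false-discovery
  estimates.
* **Counts** — NB with variance μ + φμ², φ = 0.05; per-feature
  baselines log-uniform in [μ₀/3, 3μ₀] with μ₀ = 200; library factors
  log-uniform in [0.7, 1.4] (enough spread to exercise TMM without
  extreme outliers). Mean structure is exactly
  baseline × 2^effect(group) × libfactor, so expected counts have a
  closed form the tests check.
* **Planted axes** — each axis's circRNA and mRNA share an alternating
  group profile (+3 log₂ in every other group), and its miRNA carries
  the complementary profile, so sponge and target are up where the
  free miRNA is down. Anti-correlation is induced through these shared
  group-level effects, not per-sample latent noise — it mirrors the
  between-group design on which the correlations are computed, and it
  guarantees a full ±3 log₂ contrast between any two adjacent groups.
  A further 15% of non-axis features per layer receive random group
  effects (decoy differential expression).
* **Sequences** — miRNAs 20–24 nt with P(first base = U) = 0.8;
  3′UTRs 200–600 nt; circRNAs 200–2000 nt (log-uniform; within the
  200–20,000 nt range typical of exonic circRNAs). Planted partners
  carry one full site: 3′-supplementary block (reverse complement of
  miRNA 12–17), 2-nt spacer, m8 complement, seed core, A1 adenosine.
  Planted miRNAs are drawn with ≥ 3 G/C in the seed and in the
  supplementary region so the planted duplex reliably clears
  −10 kcal/mol; their seeds are pairwise distinct. All decoy sequences
  are scrubbed of 7mer-or-better sites for planted miRNAs (chance
  6mers remain, as in real UTRs).

What the generator does **not** emulate: read-level artifacts
(adapters, quality, rRNA), back-splice-junction detection from
alignments, isoform structure, per-feature (tagwise) dispersion
variation, batch effects, conserved-site structure, or any real GO /
KEGG / STRING content. Passing recovery tests therefore demonstrate
that the inference chain is correct and calibrated under its own
model assumptions — not that those thresholds are optimal for any
particular real dataset.

## Determinism and numerical choices

* One user seed; each stochastic stage derives a child seed as the
  blake2s hash of `"<seed>:<stage>"` folded to 31 bits, so stages are
  individually reproducible.
* All output tables are deterministically sorted and written with a
  fixed float format; `run-all` with a fixed seed is byte-identical
  across runs (tested).
* Library equalization rounds half-to-even; the exact test compares
  split probabilities with relative tolerance 1e−12; p-values clamp to
  the smallest positive float rather than 0 (r = ±1 correlations
  likewise).
* Thresholds are inclusive (≥ / ≤) throughout; for the continuous
  quantities (q, r, energy) the distinction from strict inequalities
  is measure-zero, and inclusive boundaries make the PPI 0.40 edge
  case well-defined.

## Problem sizes used by the tests

The unit and acceptance suites run at the generator's default scale
(440 features × 12 samples) with 20-seed replication for recovery
statistics, 2000 features for calibration checks, 100 random
sequence pairs for scanner/oracle equivalence, and exhaustive
enumeration for totals ≤ 50 in the exact-test oracle — sizes chosen to
give stable Monte-Carlo estimates at desk scale. `scripts/acceptance.py`
reports the same quantities from a fresh run.

## Known limitations

* Classic exact test only: no GLM / quasi-likelihood path, no
  multi-factor designs, no tagwise dispersion moderation.
* The site score and duplex energy are declared stand-ins on the
  conventional scales, suitable for threshold screens and planted-site
  recovery; they do not reproduce TargetScan context++ or
  miRanda/RNAhybrid alignments and should not be interpreted as
  calibrated binding affinities.
* Correlation edges use raw p-values by design; with many candidate
  pairs the edge lists are screening output, not inference-grade
  discoveries.
* Enrichment results depend entirely on the supplied annotation and
  universe choice.
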