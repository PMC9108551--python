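# Methods

## Scores

Every interval is 0-based half-open (BED convention), enforced by all
parsers. A candidate site belongs to the gene with which it shares the most
exonic bases (ties broken to the lexicographically smallest gene id, logged;
sites without exonic overlap are dropped and counted). The "peak region" of
a site is its intersection with the host gene's exons, so spliced genes are
handled in exonic coordinate space.

For a coverage track, `lib_total` is the summed depth over the union of
exonic bases of the loaded genes, and all depths are scaled by
`1e6 / lib_total` (depth per million exonic coverage) before scoring. This
makes IP and input libraries of different size comparable; how the original
analysis normalized libraries is not documented, so this standard choice is
a package decision and POI should be read as a relative enrichment.

Per site, replicate and condition:

- `POI = (d_IP + ε) / (d_IN + ε)` where `d_IP`, `d_IN` are the mean
  normalized depths over the site's exonic bases in the matched IP and input
  libraries of that replicate;
- `POM = (d_IP + ε) / (m_gene + ε)` where `m_gene` is the median normalized
  depth over *all* exonic bases of the host gene (zeros included — dropping
  them would act as an undocumented expression filter; 50th percentile with
  linear interpolation).

The peak summary is the mean (not the sum) over peak bases, so scores are
comparable across site widths. The POM denominator is taken on the IP track
by default; `pom_denominator="input"` switches it, since the source
description names no fraction. The pseudocount ε = 0.5 normalized-depth
units guarantees positivity and finite log scores; QC flags (`LOW_INPUT`,
`LOW_GENE`, `ZERO_IP`) mark scores where ε dominated a denominator or the
peak had no IP signal. Because ε acts on the normalized scale, scores from
very large libraries (where per-base normalized depths approach ε) are
shrunk toward 1; the flags make this visible.

Coverage is treated as unstranded by default (stranded quantification is
not part of the original analysis description); a stranded mode accepting a
plus/minus bedGraph pair per sample is available. Tracks may be stored
dense or run-length encoded; both representations return identical depths
by contract (property-tested).

## The specificity decision rule

For each site, the replicate-level log2(POI) and log2(POM) values are
compared between the reference and the perturbed condition with two
separate Welch unequal-variance two-sided t-tests (Welch–Satterthwaite
degrees of freedom). A site is `specific` exactly when

1. mean log2 POI (reference) > mean log2 POI (perturbed), and
2. mean log2 POM (reference) > mean log2 POM (perturbed), and
3. p_POI < α or p_POM < α (α = 0.05 by default, uncorrected).

Decisions taken where the procedure's description is silent: the t-test is
Welch's (no pairing is stated and n = 3 per arm makes equal-variance
pooling fragile); scores are tested on the log2 scale because they are
fold-change ratios (`log_scores=False` reverts to raw scores); mean
orderings use strict inequality, so exact ties are conservatively not
specific; no multiple-testing correction is applied in the primary rule
(the rule is stated with a raw p < 0.05), but `bh=True` reports
Benjamini–Hochberg q-values alongside as a clearly separate extension.
`welch_t` handles the degenerate constant-and-equal-groups case as (t = 0,
p = 1) and constant-but-unequal groups as (±inf, 0); it is validated
against an independent reference implementation to 1e-10.

Global methylation per condition (optionally per replicate) is summarized
as the median POI and POM over a supplied m6A-site panel and over a
control-site panel, with a two-sided Mann–Whitney test comparing the panel
and control POI distributions. The Mann–Whitney choice is a package
decision (no test is named for this comparison in the source description);
identical constant distributions return p = 1 directly.

## The simulator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with full ground truth:

- **Genes.** Exonic gene length is lognormal (median 1500 bp, σ = 0.4 on the
  log scale, clipped to [600, 50000]), split into 3 near-equal exons
  separated by 150 bp introns; genes are laid end-to-end over 4 chromosomes
  with 200 bp gaps. Strand alternates and is ignored by default scoring.
- **Expression.** Each gene carries a relative expression factor
  `x_g ~ lognormal(mean 1, σ = 0.75)`, emulating per-gene expression
  heterogeneity across four orders of magnitude.
- **Sites.** One candidate site (100 bp) per gene, placed uniformly inside
  one exon. A fraction (default 20%) is truly enriched with fold
  `enrichment_ref` (default 4) in the reference arm and `enrichment_pert`
  (default 1, i.e. methylation abolished) in the perturbed arm; the rest are
  null. Enrichment is rectangular over the site's exonic span, matching the
  rectangular peak-region scoring (no shaped summit).
- **Counts.** Per base, per library: `Poisson(mean_depth · x_g · s_lib ·
  m_bio · m_tech · e(base))`, where `s_lib` is a per-library lognormal size
  factor (CV 0.2), `m_bio ~ Gamma(shape 20)` is a per-(gene, replicate)
  biological factor shared by the matched IP and input libraries of that
  replicate (both fractions derive from the same RNA sample, so biological
  fluctuation is common to them and cancels in POI, as in a real matched
  design), `m_tech ~ Gamma(shape 100)` is a per-(gene, library) technical
  factor drawn independently for every library (each prep captures a gene
  with its own efficiency), and `e(base)` is the site's enrichment for IP
  bases inside an enriched site, else 1; input libraries always use e = 1.
  Counts are therefore negative-binomial marginally. Defaults: mean exonic
  input depth 50, three replicates per arm.

Everything is driven by one seed (`numpy.random.default_rng` with distinct
derived streams for structure and coverage), and file outputs are
byte-deterministic.

What the simulator does *not* model — and hence what passing benchmarks do
not demonstrate about real data: fragment-level autocorrelation (per-base
counts are independent within a gene), shaped peak summits, GC/mappability
bias, PCR duplication, antibody off-target binding, multi-isoform genes, and
imperfect peak boundaries. Benchmarks here demonstrate the statistical
machinery is correct and calibrated under its stated assumptions, not
field performance on arbitrary libraries.

## Benchmark scenarios and problem sizes

Pinned scenario configurations (in `meripscore.simulate`):

- `null_calibration_config` — 2000 sites enriched 4-fold in *both* arms
  (depth 50, 3+3 replicates). No site is truly machinery-dependent, so the
  fraction called specific estimates the rule's false-positive rate; it runs
  well below α because the rule additionally demands both mean orderings
  (~0.02–0.03 observed).
- `recovery_config` — generator defaults: 200 dependent (4× → 1×) + 800
  null sites at depth 50. Observed across seeds: sensitivity ≈ 1.0,
  empirical FDR ≈ 0.05–0.07.
- `unit_enrichment_config` — 100 genes, enrichment 1 everywhere; the mean
  realized POI is compared to 1 within Monte-Carlo error. The independent
  technical factor contributes a known E[m/m'] = shape/(shape−1) ≈ 1.01
  ratio inflation, inside the Monte-Carlo band at this size.
- `deep_enrichment_config` — 30 genes, depth 200, 20% of sites enriched
  4-fold in both arms, 8 replicates. Sized from the analytic expectation of
  the generative model: with few genes the normalized depths stay large
  against ε, and the small enriched fraction keeps the enrichment-driven
  IP library-size inflation (which deflates normalized IP depths) small;
  the analytic expectation of mean POI is ≈ 3.8 and the realized value
  falls within 10% of the planted fold of 4.

These sizes keep the full suite and the acceptance script to a couple of
minutes on one CPU while leaving the statistical conclusions stable across
seeds.

## Numerical and degenerate-input choices

- Empty coverage library (`lib_total = 0`): normalized depths are 0 with a
  warning; the pseudocount then yields POI = POM = 1 with flags.
- All-zero gene: median 0; handled by ε downstream.
- Overlapping bedGraph records, negative depths, zero-length sites,
  malformed BED12 blocks: hard validation errors naming the file and line.
- Score tables must be complete over the design (every site × replicate ×
  condition); incomplete tables are rejected rather than silently dropped.
- `specific` is computed exactly as the conjunction above — it is never
  post-hoc edited, and the calls table carries the α used.
- Recovery metrics report NaN when undefined (no dependent sites in truth,
  or no positive calls) rather than forcing 0.

## Bench-assay module

ΔΔCt relative expression assumes perfect per-cycle doubling
(efficiency 2.0, configurable per call): `2^(Ct_ref − Ct_target)`, with
multiple primer pairs averaged on the linear scale after the transform (the
aggregation order is not documented in the source; linear averaging is the
package's decision, recorded here). The sIgM/mIgM isoform ratio is the
ratio of the two relative expressions. RIP fold enrichment computes
pull-down recovery `E = 2^(Ct_input − Ct_IP)` per (gene, antibody) and
reports `[E(target, HA)/E(ref, HA)] / [E(target, ISO)/E(ref, ISO)]`,
normalizing to an unmethylated reference RNA (Gapdh) and an isotype-control
antibody; the double ratio is invariant to any constant Ct offset
(machine calibration cancels, property-tested). GFP-high classification
uses a strict threshold (default 26 arbitrary units, the imaging background
cutoff; "above" implies strict inequality, so a cell exactly at threshold
is low).

## Known limitations

- The pipeline scores *given* candidate sites; it does not discover peaks,
  refine summits, or correct coverage biases.
- With n = 3 replicates the t-tests have little power against subtle
  enrichment changes; the benchmarks use a 4-fold → abolished contrast.
- The ε pseudocount acts on the depth-per-million scale, so its influence
  grows with total library size; users scoring very large panels should
  inspect the QC flags and, if needed, rescale ε.
- The Mann–Whitney panel comparison pools sites within a condition and
  ignores site-level pairing between panels.
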