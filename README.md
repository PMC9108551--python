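# meripscore

Quantification of candidate m6A sites from MeRIP/m6A-seq coverage and
differential RNA-methylation calling between a control and a
methylation-machinery-deficient (e.g. METTL3-knockout) condition.

N6-methyladenosine (m6A) is mapped by immunoprecipitating methylated RNA
fragments with an anti-m6A antibody and sequencing both the pull-down ("IP")
and a matched total-RNA ("input") library. Given gene models, candidate peak
regions and per-base coverage tracks, `meripscore` computes two enrichment
statistics per site, replicate and condition:

- **POI (peak over input)** — mean normalized IP depth over the site's exonic
  bases relative to the same region in the matched input fraction:
  `POI = (d_IP + ε) / (d_IN + ε)`;
- **POM (peak over median)** — the same peak depth relative to the median
  normalized coverage across all exonic bases of the host gene:
  `POM = (d_IP + ε) / (median_gene + ε)`.

Depths are normalized per library to depth-per-million exonic coverage and
ε = 0.5 is a pseudocount keeping both scores positive. A site is called
**machinery-specific** (a genuine m6A site, operationally) when the mean POI
and mean POM across replicates are both strictly higher in the control arm
than in the knockout arm, *and* at least one of the two Welch t-tests
comparing the replicate-level log2 scores between arms is significant at
α = 0.05. Global methylation per sample is summarized as the median POI/POM
over a panel of known m6A sites versus a control-site panel (Mann-Whitney
test). A synthetic-coverage simulator with planted enriched sites and full
ground truth supports calibration and recovery benchmarking, and a small
`aux` module covers the accompanying bench quantifications (ΔΔCt relative
expression, sIgM/mIgM isoform ratio, RIP-qPCR fold enrichment, GFP-high
classification).

Intended users: epitranscriptomics analysts who already have aligned
coverage (bedGraph) and candidate peak calls, and want reproducible site
scoring, knockout-based specificity calls, and a testable simulation of the
whole design. De novo peak calling and read alignment are out of scope.

## Worked example

Simulate a 50-gene triplicate experiment in which 30% of candidate sites are
4-fold enriched in the control (`REF`) arm and unmethylated in the knockout
(`PERTURBED`) arm, then score and call:

```python
from meripscore import score_all, DifferentialMethylation, panel_summary
from meripscore.simulate import SimConfig, simulate_experiment

exp = simulate_experiment(SimConfig(n_genes=50, site_fraction=0.3, seed=42))
scores = score_all(exp.sites, exp.genes, exp.tracks, exp.design)
res = DifferentialMethylation(scores).fit(alpha=0.05)
print(res.summary())
```

```
Differential methylation calling (two Welch t-tests + mean ordering)
====================================================================
conditions:        REF (reference) vs PERTURBED (perturbed)
score scale:       log2
alpha:             0.05 (two-sided, per test, uncorrected)
sites tested:      50
sites specific:    15 (30.0%)
median p (POI):    0.248
median p (POM):    0.417
```

All 15 planted sites are recovered with no false positives:

```python
print(res.recovery(exp.truth.sites))
# {'tp': 15, 'fp': 0, 'fn': 0, 'tn': 35, 'sensitivity': 1.0, 'fdr': 0.0, 'fpr': 0.0}
```

The panel summary shows what a global-methylation readout looks like: in the
control arm the m6A-site panel sits at median POI 3.37 against 0.94 for
control sites (Mann-Whitney p < 1e-3), while in the knockout arm the two
panels are indistinguishable (medians 0.99 vs 1.00, p = 0.53):

```python
print(panel_summary(scores, exp.panel_sites, exp.control_sites))
```

The same pipeline is scriptable from the shell:

```bash
meripscore sim --out simdata --seed 42 --n-genes 50 --site-fraction 0.3
meripscore run --genes simdata/genes.bed12 --sites simdata/sites.bed \
    --design simdata/design.tsv --tracks-dir simdata \
    --panel simdata/panel.bed --control simdata/control.bed --out results/
meripscore bench --calls results/calls.tsv --truth simdata/truth.tsv --out bench.tsv
```

`results/` then contains `scores.tsv` (per site × replicate POI/POM with QC
flags), `calls.tsv` (group means, both p-values, the `specific` verdict),
`panel.tsv`, and a `manifest.json` recording the configuration hash, seed
and input checksums; a rerun on identical inputs is byte-identical.

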