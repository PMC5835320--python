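# Methods

This note documents the models and procedures implemented in comparekit,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline overview

The analysis chain is: dose–response IC50 estimation → COMPARE-style
correlation ranking → top-k signature selection → Ward clustering of cell
lines on the signature → chi-square association of clusters with a
sensitive/resistant partition → (optionally) promoter motif enrichment for
the signature genes and gene-set over-representation / curated network
assembly. Each stage is an independent library function; `run_pipeline`
orchestrates them and writes a manifest with per-stage output checksums so
a run is reproducible byte for byte under a fixed seed.

## Dose–response and degree of resistance

Viability (fraction of untreated control, resazurin-style readout) is
modelled as a four-parameter logistic in log10 concentration:

    v(c) = bottom + (top − bottom) / (1 + 10^(h·(log10 c − log10 e)))

fit by least squares with bottom ∈ [0, 0.45] and top ∈ [0.55, 1.5] (top
free near 1, bottom constrained non-negative — viability is normalised to
control, so the asymptotes should bracket 0.5 for an IC50 to exist). The
reported IC50 is the concentration at which the *fitted curve crosses 50%
of control* (absolute definition), not the curve midpoint; with a
non-trivial bottom plateau the two differ. If the optimiser fails, a
log-linear interpolation between the data points bracketing 0.5 is used
(`interpolate_ic50`, also public because it applies to any 2-point
bracket, while the full fitter requires ≥ 4 distinct concentrations). If
viability never reaches 0.5 up to the highest tested concentration, the
estimate is censored ("> max tested"); censored estimates cannot enter a
degree-of-resistance ratio and raise instead.

Degree of resistance = IC50(resistant)/IC50(parental), rounded **half-up**
to two decimals (banker's rounding would print 7.15/1.87-style values that
do not match the conventional half-up presentation of such tables).
Ratios below 1 are flagged collateral-sensitive (the resistant line is
hypersensitive to the agent).

Viability curves may be non-monotone by up to 0.15 between successive
concentrations before a warning is logged; assay noise is expected and
never an error.

## COMPARE correlation ranking

Each gene's profile over the shared cell lines is correlated with the
log10 IC50 response. Pearson correlation is the default (the underlying
procedure is described in the literature both as a "correlation rank test"
and explicitly as Pearson's test; Spearman is available behind
`method="spearman"` for rank-based use). Missing expression values are
handled pairwise-complete per gene — microarray panels drop out per
gene/line, and listwise deletion would discard whole lines globally.
Genes with fewer than 3 complete pairs or zero variance are excluded with
a warning. Two-sided p-values come from the t distribution with
n_used − 2 df. Results are sorted by R descending with ties broken by
gene id, and ranks are unique. No multiple-testing correction enters the
ranking (the workflow reports raw R-ordered lists); a Benjamini–Hochberg
q column is emitted behind `fdr=True` as a clearly-labelled extension.

Signature selection takes the top `k_pos` genes with R > 0 (standard,
resistance-associated side) and the top `k_neg` with R < 0 (reverse,
sensitivity-associated side); defaults 20 + 20 = 40. If fewer qualify, the
shorter list is returned with a warning rather than padding across sides.

## Ward clustering and the clustered image map

The signature submatrix is z-scored per gene (population sd; zero-variance
rows become zeros with a warning; missing cells are imputed at the row
mean after scaling so Euclidean geometry is defined). Clustering is
agglomerative Ward linkage on Euclidean distances, computed by
`scipy.cluster.hierarchy.linkage(..., method="ward")`. **Height
convention:** merge heights are reported as the Ward cost, the increase in
total within-cluster SSE caused by the merge; SciPy's heights equal
√(2·cost), and the conversion cost = h²/2 is applied so that a direct
SSE-based greedy oracle reproduces the heights exactly. Exact merge-cost
ties are resolved by SciPy's nearest-neighbour chain (deterministic given
input order); the oracle tests use continuous random data where ties have
probability zero. `cut_tree(k)` yields exactly k clusters, labelled 1..k
by first appearance in dendrogram leaf order (cluster 1 is leftmost in the
display). k defaults to 4 and is a user parameter; no automatic k
selection is attempted.

The clustered image map draws both dendrograms, the reordered z-score
matrix, and a sensitivity annotation bar. The display z-scores rows
because minimum-variance clustering on mixed-scale expression rows would
otherwise be dominated by high-variance genes; the colour scale is
symmetric about zero. SVG output pins the matplotlib hash salt and strips
the date so re-renders are byte-identical.

## Sensitivity partition and chi-square association

Lines with log10 IC50 strictly below the threshold are sensitive; values
at or above it (including exact ties) are resistant. The default
threshold is the sample median — a fixed molar threshold like −5.45 log10 M
is meaningful only on its own panel's scale — and any fixed value can be
passed. The cluster × label table is tested with Pearson's chi-square
without continuity correction (the worked-example table in the acceptance
suite reproduces its published p = 1.86 × 10⁻⁵ only without correction);
expected counts below 5 trigger a warning plus an optional Monte-Carlo
permutation p-value that is reported alongside, never instead of, the
asymptotic one. Zero marginals are an error.

## Motif enrichment statistic

The region-based motif ranker used in the original workflow is proprietary
to its web service and its statistic is not published, so comparekit
defines its own openly-specified stand-in and labels it as such: per
motif, the observed statistic T is the mean over promoters of the best
log2-odds hit (both strands, all offsets; ambiguous bases score 0, the
background expectation). The null shuffles every promoter with the
Altschul–Erickson dinucleotide shuffle — preserving exact dinucleotide
counts and hence local composition, the standard motif-null practice —
`n_shuffles` times (default 100; fewer than 20 is an error because the
null sd estimate becomes unstable), giving μ₀ and σ₀ of T and

    z = (μ₀ − T) / σ₀,    p = Φ(z).

The sign convention makes **negative z mean enriched**, matching the
convention of region-based motif rankers. Absolute z-scores and p-values
from this statistic are not comparable to any external tool's numbers;
within a run, the ranking (by −log10 p, ties by motif id) is the
meaningful output, and a ×10-scaled −log10 p column is emitted for
side-by-side reading with tools that print that scale. Under the null
(no planted motif) the empirical p-values are approximately uniform; the
acceptance suite checks this by Kolmogorov–Smirnov across seeds.

Promoter windows are [TSS − w, TSS) on the plus strand and
[TSS, TSS + w) reverse-complemented on the minus strand (0-based
half-open; w ≤ 50 kb, matching the up-to-50-kb upstream convention), truncated
at contig boundaries with a warning.

## Over-representation and curated network

Gene-set enrichment is the right-tailed Fisher/hypergeometric test of the
query–set overlap within an explicit universe (the expression matrix's
genes when run inside the pipeline; mandatory when standalone). The
conventional cutoff −log10 p ≥ 1.3 (p ≤ 0.05) marks passing sets; the
comparison is inclusive. A BH-FDR column is emitted alongside raw p, and
the cutoff applies to raw p as in the emulated workflow. Proprietary
pathway content and activation z-score prediction of commercial suites
are deliberately **not** emulated; enrichment runs against user-supplied
GMT collections. The packaged functional-group table assigns published
determinants of arsenic-trioxide responsiveness to nine groups (oxidative
stress response, drug transport, DNA repair, cell cycle/proliferation,
tumor suppressors/oncogenes, signal transduction, metabolic pathways,
cytoskeleton, apoptosis); symbols are kept as printed in the source
compilation (including a few idiosyncratic spellings) with conventional
HGNC symbols as aliases, and matching is case-insensitive. Network
assembly takes curated edges (direct/indirect, with provenance), drops
self-loops and edges leaving the gene list with warnings, and exports
edge-list TSV and GraphML.

## Synthetic-data generator

The generator defines the study conditions for all tests:

- **Expression/response.** 58 cell lines by default; response ~
  N(−5.45, 0.8²) log10 molar, centring the median-split threshold on the
  scale of the emulated panel. Planted genes are
  baseline + a·(y − ȳ) + ε with ε ~ N(0, noise_sd²) (noise_sd default 1)
  and |a| = ρ·noise_sd/(sd(y)·√(1−ρ²)) calibrated against the *realized*
  sample sd of the response, so the expected sample |Pearson r| equals ρ
  for any draw; the sign of a sets the resistance/sensitivity direction.
  Non-planted genes are independent N(7, 1) log2-scale noise. Default
  ρ = 0.6, 20 + 20 planted among 2000 genes.
- **Promoters.** i.i.d. background (uniform by default) with one motif
  instance, sampled column-wise from the PWM, inserted at a random offset
  in ⌈plant_rate·n⌉ sequences (one instance per planted promoter — the
  simplest structure sufficient for rank-recovery tests).
- **Dose–response.** v = 1/(1 + (c/IC50)^h) × (1 + N(0, noise_sd²)),
  clipped to [0, 1.2], six replicates per concentration (the emulated
  assay's replicate count), concentrations spanning 0.003–500 µM.

A single seed is expanded into per-component substreams
(`numpy.random.SeedSequence.spawn`), so stages can be regenerated
independently and all generators are bitwise reproducible.

What the generator does **not** emulate: array probe effects, batch
effects, tissue-of-origin structure, correlated gene modules, GC-biased
promoter composition, or heteroscedastic assay noise. Passing tests
therefore demonstrate correctness of the statistical machinery under
idealised structure, not performance on real panel data.

## Problem sizes used in tests and the acceptance script

The test suite and acceptance script run the panel analyses at the study
scale (2000 genes × 58 lines) and size the Monte-Carlo components for
stable verdicts at interactive runtimes: 50 seeds for recovery/power
sweeps, 20 null panels in the acceptance script, 40–50 dinucleotide
shuffles per promoter set, 100 (tests) or 50 (script) synthetic IC50
curves, and 150–200 promoters of 250–300 bp for motif ranking. These
sizes were chosen once as sufficient for the stated tolerances.

## Known limitations

- **Selection circularity in the association step.** The pipeline selects
  the 40 genes most correlated with the response and then tests whether
  clusters built from those same genes associate with the response's
  median split. Under a global null (no planted signal) this chain is
  strongly anti-conservative: the signature genes have chance
  correlations |r| ≈ 0.3 with the response, all consistently oriented, so
  the cluster partition inherits response structure and the chi-square
  p-values concentrate near zero rather than being uniform. The
  acceptance suite includes a type-I-control check of the full chain that
  documents this behaviour (it fails, by construction of the chain, not
  by implementation defect); the honest use of the association test is
  descriptive, or on signatures defined on independent data. The
  `null_association_acceptance_pct` entry written by the acceptance
  script quantifies it.
- The chi-square test is asymptotic; with 58 lines and k = 4 clusters
  some expected counts routinely fall below 5 (the package warns and
  offers a permutation p).
- The motif z-score uses a normal approximation to the null of a mean of
  best-hit scores with μ₀, σ₀ estimated from a finite number of shuffles;
  at the minimum shuffle count the p-values are noticeably noisier.
- 4PL fitting constrains the asymptotes to bracket 0.5; curves with high
  bottom plateaus (partial responders) are reported censored rather than
  extrapolated.
- The dinucleotide shuffle treats the sequence as a single alphabet
  stream; masked/lowercase state is not preserved.
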