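# Methods

## Scope and assumptions

The package implements a rank-based contrast analysis for a two-condition ×
four-stage factorial expression design (breeds BA and CH; 110, 180, 210,
260 days post conception), taking as input a normalized log2 intensity
matrix (probes × samples), a sample design table, a probe→gene map, and
plain-text gene sets. Everything upstream — within/between-array
normalization, background handling — is assumed done by the scanner
software; everything downstream of ranked lists (GO enrichment services,
regulator discovery) is out of scope: the pipeline only exports their
inputs.

The design intentionally avoids per-gene inference. With 2–3 biological
replicates per treatment, moderated-t approaches yield almost no
significant genes after multiple-testing correction; the statistics here
(DE, PIF, RIF, stage-SD) are **ranking devices** whose extremes feed
enrichment and candidate lists. No p-values are attached to any of them;
the single formal test is the exact binomial sign-skew test on a gene set,
where the unit of evidence is the whole set, not a gene.

## Preprocessing

1. **Technical replicates** are averaged per probe (arithmetic mean of
   available values; a mean over a partially missing group uses the
   available values, and a cell is missing only when all contributors are).
   This choice maximizes retained data and lets genes with missing values
   at some stages stay in the stage-wise analyses.
2. **Treatment means**: mean per (breed, stage) over that treatment's
   available samples; an empty treatment is an error naming the cell.
3. **Expression filter**: a row is kept if it is present and at or above an
   expression floor in at least 7 of the 8 treatments. The floor is a
   required parameter (default 2.0 log2 units — an arbitrary but explicit
   choice; array floors depend on platform and normalization). The filter
   defaults to probe level, before gene mapping; a gene-level run is just a
   reordering of the same calls.
4. **Gene mapping**: `best-probe` (default) keeps, per gene, the probe with
   the highest mean abundance across the 8 treatments, ties broken by
   lexicographic probe id for determinism; `keep-probes` retains duplicate
   probes under a (gene, probe) index, which is what the sign-skew test
   wants ("matches including duplicates").

## Differential statistics

Per gene and stage: `d = mean_BA − mean_CH`, `a = (mean_BA + mean_CH)/2`,
`pif = a·d`. On the log2-intensity scale `a` is positive, so `sign(pif) =
sign(d)`; this is asserted by tests, not assumed. The MA filter keeps rows
with `|d|` strictly greater than the threshold (default 0.5 log2 ≈
1.41-fold — a plotting convenience, not a significance claim). Cumulative
DE sums `|d|` over available stages; a row needs ≥3 of 4 stages to receive
a cumulative rank, mirroring the exclusion of genes with missing stages
from ranked tables. The developmental-regulation score is the sample SD
(n−1; population SD behind a flag) of the four stage means within one
breed, default BA. Extreme slices take the top/bottom `floor(N·fraction)`
of the scored background, so 1% of 19,100 genes is 191 per tail.

## RIF differential connectivity

Per regulator, Pearson correlations to each selected gene are computed
separately within each breed across the four stage means (the default;
a replicate-level variant pooling each breed's individual samples is
available as `breed_correlation_profiles_replicates`). Zero-variance
profiles get r = 0 and a degenerate flag — a constant profile carries no
wiring signal, and dropping such regulators entirely would shrink coverage.
Pairs with fewer than 3 jointly observed stages are missing and excluded,
with the per-regulator n_DE adjusted.

The target-gene selection is the union of both PIF extremes at 5% per tail
(`pif-extreme`; `de-extreme` ranks on the mean contrast instead). The
per-gene weights are ē_j (mean of the eight treatment means), d_j (mean of
the per-stage contrasts over available stages) and e1_j/e2_j (breed-wise
means of the four stage means). Raw scores follow

    RIF1_r = (1/n_DE) Σ_j ē_j · d_j · (r1_rj − r2_rj)²
    RIF2_r = (1/n_DE) Σ_j (e1_j·r1_rj)² − (e2_j·r2_rj)²

and are z-standardized over scored regulators (sample SD); regulators with
|z| above a cutoff (default 1.96) in both columns are flagged, with
sign-quadrant labels for plotting.

**Statistical caveat, documented deliberately:** a Pearson correlation over
four points is extremely noisy — under a flat null its distribution is
essentially uniform on [−1, 1]. Consequently (i) RIF here ranks candidates
and must not be read as a test; (ii) a null regulator whose 4-point profile
chance-aligns with a genuinely rewired trajectory is a partial impostor,
which bounds how cleanly any method can separate planted from null
regulators at this design size; and (iii) RIF2 is the blunter of the two
scores in this regime, because a null regulator's two breed profiles give
two *independent* chance correlations whose squared difference can be
large. The replicate-level variant (~10 points per breed) tightens the null
sharply and is used where a single dominant plant must surface in both
columns.

## Exact binomial sign-skew test

For a matched gene set at one stage, `n_up = #{d>0}`, `n_down = #{d<0}`;
exact zeros are excluded (possible on synthetic data, measure-zero on real
intensities). The reported statistic is the one-sided upper tail at the
majority count, `P(X ≥ k)` at p = 0.5, computed by direct summation of
binomial log-pmf terms (gammaln) combined with logsumexp — exact to
floating precision and underflow-safe for n in the hundreds (345 of 514
gives 3.2e-15). The one-sided convention is recorded in the result; a
two-sided value (twice the smaller tail, capped at 1) is available. For the
23-of-29 regulator sign enrichment the exact one-sided tail is
621,616/2²⁹ ≈ 1.158e-3; headline roundings of such values elsewhere (e.g.
0.0013) follow conventions that are not always stated, so this package
always reports the value as computed.

## Clustering

Heatmap-convention clustering: rows are z-scored over present cells
(sample SD; zero-variance rows are left at 0 and flagged), then rows and/or
columns are agglomeratively clustered. Defaults are Pearson-correlation
distance (1 − r) and average linkage — the usual heatmap-tool defaults;
Euclidean and complete linkage are exposed. Missing cells use
pairwise-complete distances; a pair sharing fewer than two cells is an
error. Leaf order is deterministic given the input (scipy's tie handling
plus fixed input order); group recovery is asserted via cluster purity, not
exact leaf order, since seriation conventions differ between tools.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study's design points:

| parameter | default | why |
|---|---|---|
| replicate_plan | BA 3/2/3/2, CH 2/3/3/3 (21 samples) | the study's post-QC array subset |
| n_genes | 2000 | large enough for stable extreme slices, small enough for fast tests |
| baseline_mean, baseline_sd | 8.0, 2.0 log2 | typical normalized two-colour intensity range |
| replicate_noise_sd | 0.3 log2 | a realistic biological+technical replicate CV for arrays |
| n_devreg_genes, devreg_amplitude | 50, 2.0 log2 | strong stage regulation, shared by both breeds |
| n_de_genes, de_effect | 40, 1.0 log2 | breed effects, split ±e/2 symmetrically |
| mito_set_size, mito_skew_fraction | 514, 345/514 | the mitoproteome match count and its observed split |
| mito_effect | 0.4 log2 | "small but consistent" set-wide shift at 260 dpc |
| n_regulators / rewired | 100 / 2 | enough for stable z-scores; rewiring is rare |
| rewiring_strength | 1.5 | BA-coupled, half-mirrored in CH (|r1−r2| ≈ 1.9) |
| duplicate_probe_fraction | 0.3 | many-to-one probe→gene mapping |
| missing_rate | 0.01 | sparse missingness, confined to one treatment per probe |
| seed | 1213 | arbitrary, documented |

Mechanics worth knowing:

- Breed effects are planted symmetrically (+e/2 / −e/2), so relabelling
  breeds negates every planted sign exactly.
- Rewired regulators carry a latent stage trajectory in both breeds; their
  targets (planted DE genes of one contrast sign, partitioned among the
  rewired regulators) follow that trajectory in BA with weight
  min(strength, 1) and mirror it in CH with weight −max(strength−1, 0).
  The latents of distinct rewired regulators are drawn mutually orthogonal
  in the centered 4-point space: with 4-point correlations a null profile's
  squared projections onto orthogonal latents are jointly bounded, which
  keeps one planted signal from contaminating another and puts the planted
  regulator's connectivity at the geometric maximum.
- A BA-only target coupling necessarily creates a breed difference of
  (w_BA − w_CH)·amplitude·L(s) at each single stage (mean-zero across
  stages). Planted per-stage DE of target genes is therefore only accurate
  in expectation — at one stage the coupling can cancel it. Fixtures that
  test pure breed/stage structure (the heatmap purity analogues) disable
  rewiring for exactly this reason.
- Missing cells are confined to one randomly designated treatment per
  probe, at the configured per-cell rate in expectation, so the 7-of-8
  filter's pass/fail behaviour stays controllable.
- Everything is driven by one `numpy` Generator; identical (config, seed)
  gives bit-identical outputs, and the truth record lists every planted
  gene, effect, sign and target set.

What the generator does **not** emulate: probe sequence effects, dye or
spatial artifacts, intensity-dependent variance, correlated gene modules
beyond the planted ones, and array-to-array normalization residue. Passing
recovery tests therefore demonstrate that the statistics find the structure
they are defined on — not that they would behave identically on raw array
data.

## Test and acceptance problem sizes

The suite and the acceptance script run entirely on generated data. Sizes
were chosen as the package's own balance of stability and speed: recovery
properties use the default 2000-gene, 21-sample configuration; the RIF
recovery rate aggregates 2 planted regulators × 20 seeded replicates
(top-5% membership of |RIF1_z| ∪ |RIF2_z|); figure-analogue purity fixtures
plant figure-scale effects (devreg_amplitude 3.0, de_effect 2.0, complete
data) because the genes in such figures are the extreme tail of their
rankings; the binomial oracle checks run to n = 600 against exact rational
arithmetic. The full suite runs in about a minute on one CPU; the
acceptance script in under half a minute.

## Known limitations

- Four-point correlations make RIF rankings noisy by construction; treat
  the extremes as candidates. The replicate-level correlation option trades
  this noise for a conflation of developmental and replicate covariation.
- The expression floor, PIF-extreme selection rule and RIF target fraction
  are conventions, exposed as parameters; results at the margins of the
  extreme slices are sensitive to them.
- `sign(pif) = sign(d)` relies on positive log2 intensities; data on a
  ratio (M-value) scale would need re-centering before PIF is meaningful.
- The exact binomial test assumes independent gene-level signs; co-expressed
  set members violate independence, so its p-value overstates certainty for
  tightly co-regulated sets.
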