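# musclenet

Rank-based contrast pipeline for two-condition developmental transcriptomes,
built around the analysis style used to compare *m. Semitendinosus* muscle
development in two cattle breeds — Blonde d'Aquitaine (BA, a breed carrying a
myostatin/*MSTN* mutation) and Charolais (CH) — across four foetal stages
(110, 180, 210 and 260 days post conception) on two-colour expression
microarrays with 2–3 biological replicates per breed × stage *treatment*.

With so few replicates per cell, per-gene significance testing has little
power; the pipeline instead builds genome-wide **ranked lists** and works
with their extremes:

- **DE** — per-gene, per-stage differential expression on the log2 scale,
  `d = mean_BA − mean_CH`, with average abundance `a = (mean_BA + mean_CH)/2`
  (the M and A of an MA plot); a cumulative score `Σ_s |d(g,s)|` ranks overall
  breed responsiveness.
- **Developmental regulation** — the standard deviation of a gene's four
  stage means within one breed; large values flag stage-dependent genes.
- **PIF** (phenotypic impact factor) — `pif = a · d`, which emphasizes genes
  that are both abundant and differential and de-emphasizes noisy
  low-abundance genes; enrichment target lists are the nominal 1% extremes of
  the PIF ranking against the full background.
- **RIF1 / RIF2** (regulatory impact factors) — differential-connectivity
  scores per regulator *r* against a selected set of n_DE genes, from breed-wise
  Pearson correlations r1 (BA) and r2 (CH) across the four stage means:

  ```
  dw_rj  = r1_rj − r2_rj
  RIF1_r = (1/n_DE) Σ_j  ē_j · d_j · dw_rj²
  RIF2_r = (1/n_DE) Σ_j  (e1_j·r1_rj)² − (e2_j·r2_rj)²
  ```

  where ē_j is gene *j*'s mean over the eight treatment means, d_j its mean
  contrast, and e1_j/e2_j its breed-wise means. Scores are z-standardized
  over regulators and the extremes in both columns flagged.
- **Gene-set sign skew** — for a gene set (e.g. the mitoproteome), the split
  of contrast signs at one stage, tested with an exact binomial tail computed
  by direct log-space summation.
- **Heatmap clustering** — row z-score normalization followed by
  agglomerative clustering on Pearson distance (1 − r), average linkage.

A first-class synthetic-data generator (`musclenet.simulate`) emulates the
unbalanced 21-sample study design and plants every signal the pipeline looks
for — stage trajectories, breed DE, a skewed gene set, rewired regulators —
and returns a truth record so recovery is testable without external data.
An optional reader for the GEO series-matrix dialect is included for working
with deposited datasets of this layout.

## Worked example

```python
import musclenet as mn

cfg = mn.SimulationConfig(seed=1213)          # the 21-sample study design
matrix, design, probe_map, truth = mn.simulate_dataset(cfg)
matrix, design = mn.average_technical_replicates(matrix, design)
means = mn.filter_expressed(mn.compute_treatment_means(matrix, design))
gene_means = mn.map_to_genes(means, probe_map)
diff = mn.compute_diff(gene_means)

# mitoproteome-style sign skew at 260 dpc
mito = mn.GeneSet("mito", truth.mito_gene_names)
rows = mn.match_set(diff.index, mito)
print(mn.sign_split(diff, 260, rows=rows))

# regulator rewiring
sel = mn.select_de_genes(diff)                 # PIF extremes, 5% per tail
prof = mn.breed_correlation_profiles(gene_means, truth.regulators, sel)
rif = mn.standardize_and_rank(mn.compute_rif(prof, sel))
print(rif[["rif1_z", "rif2_z", "quadrant"]].head(3).round(2))
```

prints

```
SkewResult(n_up=178, n_down=336, n_zero=0, n_missing=0,
           p_value=1.480596544023861e-12, direction='CH', sided='one')
        rif1_z  rif2_z quadrant
G00620    2.08    2.57       ++
G00606   -3.50   -0.63       --
G00686   -2.39    1.46       -+
```

Of the 514-gene planted set (skewed 345:169 towards CH before noise), 336
come out CH-higher after replicate noise, an exact one-sided binomial tail of
1.5e-12 — the set is coherently down in the *MSTN*-mutant breed. G00606 is
one of the two planted rewired regulators, surfacing at the RIF extremes.

The same steps are exposed as a CLI:

```sh
musclenet simulate --out-dir data --seed 1213
musclenet mito-skew --matrix data/matrix.tsv --design data/design.tsv \
    --map data/probe_map.tsv --set data/mito_set.txt --stage 260 --out skew.tsv
musclenet run --config config.yaml --out-dir results   # full pipeline
```

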