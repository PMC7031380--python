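# psoilcycle

Analysis pipeline for soil phosphorus-cycling functional gene profiles from
shotgun-metagenome KO (KEGG orthology) read-count tables. Starting from an
annotated KO × sample count table and sample metadata, the package provides:

- **catalog** — a packaged 40-gene P-transformation catalog (gene symbol ↔
  KO ids ↔ functional category ↔ transporter/C-P-lyase aggregation group),
  with loading, validation and grouping helpers.
- **profiling** — median library-size normalization, relative abundances as
  percent of annotated reads, transporter-system aggregation (member-gene
  means), category totals, nutrient-input shift statistics
  (`100 × (mean₊ − mean₋)/mean₋`), and taxon-level read-number deltas.
- **stats** — two-way ANOVA (Type-II SS) with Shapiro–Wilk/Levene assumption
  checks, Bonferroni and Benjamini–Hochberg adjustments, Spearman rank
  correlation.
- **ordination** — Bray–Curtis dissimilarity, non-metric multidimensional
  scaling (Kruskal stress-1), ANOSIM with seeded permutation p-values, and
  marginal distance-based linear modelling (Gower-centered pseudo-F with
  permutation inference).
- **network** — per-nutrient-group Spearman co-occurrence networks with a
  random-matrix-theory correlation threshold (NNSD GOE→Poisson transition)
  and BH-FDR edge filtering; topology reports (average degree, density,
  mean clustering) and network comparisons.
- **sem** — observed-variable path analysis by maximum likelihood (nutrient
  inputs → soil pH / N:P ratio → the three gene-category abundances), with
  χ², RMSEA, standardized coefficients and per-equation r².
- **synthetic_data** — seeded generators for full synthetic studies
  (4 sites × 3 treatments × 3 replicates, negative-binomial counts, effect
  multipliers, covariate coupling), planted-block correlation fixtures, and
  path-model data, each with recorded ground truth.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (catalog structure,
brute-force oracles for ANOSIM/DistLM/topology, statistical calibration,
RMT threshold recovery, parameter recovery, determinism).

## Command line

```sh
psoilcycle simulate --seed 42 --out study/          # synthetic study
psoilcycle profile  --ko-table study/ko_counts.tsv --meta study/metadata.tsv \
                    --out profile.tsv
psoilcycle compare  --ko-table study/ko_counts.tsv --meta study/metadata.tsv \
                    --out compare.tsv               # shifts + ANOVA
psoilcycle ordinate --profile profile.tsv --meta study/metadata.tsv \
                    --groups n_contrast --perm 999 --seed 7 --out ord.json
psoilcycle network  --profile profile.tsv --meta study/metadata.tsv \
                    --group plusN --seed 7 --out-prefix net/plusN
psoilcycle sem      --data merged.tsv --out sem.json
psoilcycle run-all  --ko-table study/ko_counts.tsv --meta study/metadata.tsv \
                    --seed 7 --out results/
```

All table formats are TSV (KO tables carry an optional
`__total_annotated__` row with per-sample annotated-read totals); networks
are exported as GraphML plus an edge-list TSV; `run-all` writes a JSON
manifest recording seeds and parameters for full reproducibility.

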