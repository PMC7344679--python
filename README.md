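# sensomet

Linking untargeted LC-MS metabolite features to expert sensory attributes
of wine — a tested, reusable implementation of the full analysis chain:

1. **Preprocessing** — three feature filters with strict boundaries
   (mean intensity < 0.1% of the highest per-feature mean; > 30% missing
   values; retention time < 0.45 min), then normalization by injection
   volume, per-sample median and within-batch per-feature median.
2. **PCA** — unit-variance-scaled NIPALS that tolerates missing values
   without imputation (equals SVD-based PCA on complete data).
3. **Sparse PLS / sPLS-DA** — latent-component regression with exactly
   `keepX` variables selected per component by soft-thresholding;
   indicator coding + maximal-prediction rule for categorical responses;
   hyperparameters chosen by repeated stratified 5-fold cross-validation
   over a (components, keepX) grid.
4. **VIP biomarker scoring** — per-feature variable importance in
   projection,
   `VIP_j = sqrt( p * Σ_a SSY_a w_aj² / Σ_a SSY_a )`,
   with `SSY_a = ‖q_a‖² t_aᵀt_a`; mean(VIP²) = 1 by construction, so
   VIP > 1 flags above-average importance.
5. **Attribute–feature networks** — bipartite graphs with an edge
   wherever VIP > 1.0 (edge weight = VIP), built separately for the 11
   aroma and 4 taste attributes.
6. **Annotation** — exact-mass adduct matching (M+H, M+Na, M+NH4
   positive; M−H, M+AcOH−H negative; M+ for intrinsic cations such as
   flavylium anthocyanins) at 5 ppm, with MSI confidence levels 2/3/4.

Because the original raw data are not publicly deposited, the package
includes a first-class synthetic-data generator that reproduces the
study's design (2 seasons x 3 cluster types x 4 biological x 3 technical
replicates = 72 samples) with known ground truth — planted season and
cluster effects, sensory biomarkers, filter violations and compound
identities — so every stage is verifiable end to end.

Audience: metabolomics / sensometrics researchers who want a transparent,
scriptable alternative to ad-hoc spreadsheets and one-off R sessions for
sensory-guided biomarker discovery.

## Worked example

```python
from scipy import stats
from sensomet import SyntheticConfig, generate_dataset, preprocess, fit_pca

table, meta, scores, db, truth = generate_dataset(SyntheticConfig(seed=0))
processed, report = preprocess(table, meta)
print(report.n_input_features, "->", report.n_output_features)

pca = fit_pca(processed, n_components=5)
season = meta.aligned_to(processed)["season"]
r = stats.pointbiserialr((season == "S1").astype(float), pca.scores[:, 0]).correlation
print(f"PC1 vs season |r| = {abs(r):.3f}")
```

prints

```
2000 -> 1955
PC1 vs season |r| = 0.999
```

i.e. the filters removed exactly the 45 planted violations (15 per
filter) and the two harvest seasons separate almost perfectly along the
first principal component — the dominant trend these data are built to
show. The `examples/` directory walks through each capability the same
way (simulation, preprocessing + PCA, sPLS biomarker ranking, networks,
annotation); `examples/03_spls_biomarkers.py` for instance recovers all
20 planted astringency biomarkers within the top 50 features by VIP.

A thin CLI mirrors the stages:

```bash
sensomet simulate --seed 0 --out-dir data/
sensomet preprocess --table data/feature_table.csv --meta data/sample_metadata.csv \
    --out processed.csv --report report.json
sensomet run-all --seed 0 --out-dir run/          # full pipeline
```

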