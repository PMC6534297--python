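# zernmp

Zernike-polynomial characterisation of macular pigment (MP) distribution
maps.

Macular pigment — the carotenoids lutein and zeaxanthin concentrated at
the fovea — is thought to play a protective role in age-related macular
degeneration (AMD), and the *spatial pattern* of its distribution may
carry diagnostic information that scalar summaries (peak density, total
amount) miss. `zernmp` is for researchers working with 2-D MP
concentration maps (from fundus reflectance, autofluorescence or similar
modalities) who want a compact, analysable representation of the whole
map: it fits a truncated Zernike expansion over the unit disk,

    MP(ρ, φ) ≈ Σ_j C_j Z_j(ρ, φ),    Z_n^m(ρ, φ) = R_n^|m|(ρ) · {cos(mφ), sin(|m|φ)},

with J ≤ 105 coefficients (all radial orders n ≤ 13, OSA/ANSI index
j = (n(n+2)+m)/2, zero-based Noll also supported), and then analyses the
coefficient vectors:

- **classification** of subject groups (under-50 healthy / 50+ healthy /
  50+ AMD) with shrinkage LDA under leave-one-out and with a feedforward
  pattern-recognition network over repeated random splits;
- **feature ranking** by two-sample t-statistic with a leave-one-out mode
  consensus, each basis function categorised as a magnitude (m = 0),
  radial-asymmetry (|m| = 1) or peripheral-irregularity (|m| ≥ 2)
  descriptor;
- **one-way MANOVA** (Wilks' Λ) comparing the coefficient representation
  against the conventional (peak, total) baseline;
- a **synthetic phantom generator** producing group-structured cohorts so
  the entire pipeline runs and is testable with no external data.

## Worked example

```python
import zernmp as z

# synthetic three-group cohort: 30 subjects per group, 81x81 maps
manifest, maps, truths = z.make_cohort(n_per_group=30, seed=42)

# fit 105 Zernike coefficients to one map
fit = z.fit_zernike(maps[0], J=105)
print(f"nRMSE = {fit.nrmse:.4f}, C_0 = {fit.coefficients.values[0]:.4f}")

# whole-cohort coefficient matrix and group labels
X = z.fit_cohort(maps)
dataset = z.LabelledDataset(X=X, groups=manifest.table["group"].to_numpy(int),
                            subjects=manifest.table["subject"].to_numpy())

# age-matched disease test (groups 2 vs 3), LDA with leave-one-out
rep = z.lda_loo(dataset, "2v3")
print(f"accuracy {rep.accuracy:.3f}, sensitivity {rep.sensitivity:.3f}, "
      f"specificity {rep.specificity:.3f}")

# group separation: full coefficients vs (peak, total) baseline
lam, p = z.manova_wilks(X, dataset.groups)
lam_b, _ = z.manova_wilks(z.baseline_matrix(maps), dataset.groups)
print(f"Wilks' Lambda: coefficients {lam:.4f}, baseline {lam_b:.4f}")

# which coefficients discriminate 2 vs 3, and what patterns they encode
Xb, yb, _ = dataset.binary("2v3")
ranking = z.loo_consensus_ranking(Xb, yb)
print(ranking.indices[:5].tolist(), list(ranking.categories[:5]))
```

Output:

```
nRMSE = 0.0370, C_0 = 0.2848
accuracy 1.000, sensitivity 1.000, specificity 1.000
Wilks' Lambda: coefficients 0.0004, baseline 0.1215
[29, 53, 1, 40, 24] ['irregularity', 'irregularity', 'asymmetry', 'magnitude', 'magnitude']
```

Reading: the 105-term expansion represents the smooth phantom to ~4%
normalised RMSE; the age-matched disease groups are perfectly separable on
this synthetic cohort; the coefficient representation separates the three
groups far more strongly than the peak/total pair (smaller Λ); and the
top-ranked discriminating coefficients for the disease contrast are
dominated by peripheral-irregularity terms — the pattern the group-3
phantoms plant.

The same pipeline is scriptable from the shell:

```sh
zernmp simulate-cohort --n-per-group 30 --seed 42 --outdir cohort/
zernmp fit --manifest cohort/manifest.csv --outdir coeffs/
zernmp classify --test 2v3 --classifier lda-loo \
    --manifest cohort/manifest.csv --report report.json
zernmp rank --test 2v3 --manifest cohort/manifest.csv --out ranking.csv
zernmp manova --manifest cohort/manifest.csv --out manova.json
```

Real MP maps load from delimited-text matrices or 8/16-bit grayscale
images via `z.load_map`, with optional recentring of the disk onto the
smoothed MP peak (`z.recentre_on_peak`) since Zernike coefficients are not
translation invariant.

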