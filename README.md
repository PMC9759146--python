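# megnet

Band-wise functional-connectivity networks and weighted graph metrics for
resting-state MEG source ("virtual sensor") time series, with the group
statistics used to discriminate a cognitively impaired patient subgroup in
pediatric focal epilepsy (self-limited epilepsy with centrotemporal spikes,
SeLECTS).

## Who this is for

Clinical neurophysiology groups who have source-level MEG waveforms and
want a reproducible, tested pipeline for:

* cleaning (50 Hz notch, >6 pT amplitude-artifact exclusion, spike
  flagging, selection of a continuous 60 s spike-free window);
* seven-band decomposition (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–80 Hz,
  ripple 80–250, fast ripple 250–500 Hz);
* signed correlation networks thresholded by a t-type statistic at p < .01;
* weighted graph metrics — strength SA, degree DA, path length LA
  (edge lengths 1/w, unreachable pairs counted as 0) and geometric-mean
  clustering CA;
* three-group ANOVA with Bonferroni families of 21 (FC) and 84 (graph
  metrics) tests, logistic regression, and ROC discrimination.

Because patient MEG is rarely shareable, the package ships a synthetic
generator that emulates the recording conditions (120 s at 6000 Hz,
picotesla units, planted band-wise coupling with known expected correlation
ρ, group-level coupling deficits, spikes and artifacts), so every stage is
testable end to end against ground truth.

## The statistics at the core

For source signals X_a, X_b over a K-sample window, the edge statistic is

    R(X_a, X_b) = C(X_a, X_b) / (S_a S_b)          (Pearson correlation)
    TP          = R √(K − 2) / √(1 − R²)           (t-transform)

and an edge is kept when |TP| exceeds the two-sided Student-t critical
value at α = .01 with K − 2 df, carrying weight |R| and the sign of R.
Graph metrics on the positive-edge subnetwork:

    S_i = (1/N) Σ_j w_ij          SA = mean_i S_i
    d_i = #{j : w_ij > 0}         DA = mean_i d_i
    L_ij = shortest path, edge length 1/w_ij (0 if unreachable)
    LA  = (1/(N(N−1))) Σ_{i≠j} L_ij
    C_i = (1/(d_i(d_i−1))) Σ_{j,k} (ŵ_ij ŵ_jk ŵ_ki)^{1/3},  ŵ = w / max w
    CA  = mean_i C_i

Band-limited signals carry far fewer effective degrees of freedom than K;
a Bartlett/Pyper–Peterman effective-K policy is available (and used by the
pipeline's study configuration) — see `docs/methods.md`.

## Worked example

```python
from megnet import pipeline
from megnet.clinical_cohort import IMPAIRED, NON_IMPAIRED, compare_groups_ttest, load_cohort, summarize_group

cohort = load_cohort()                       # packaged 35-patient table
for group in (IMPAIRED, NON_IMPAIRED):
    s = summarize_group(cohort, group, "course")
    print(f"{group}: n={s.n}, disease course {s.mean:.2f} +/- {s.sd:.2f} months")
t = compare_groups_ttest(cohort, "course")
print(f"pooled t-test: t={t['t']:.2f}, p={t['p']:.1e}")

cfg = pipeline.load_config(overrides={
    "seed": 1,
    "simulation": {"n_per_group": {"impaired": 8, "non_impaired": 8, "control": 8}},
})
report = pipeline.run_all(cfg, "megnet_run")
for row in report["gt_comparisons"]:
    if row["band"] == "beta" and row["parameter"] == "CA":
        print(f"beta-band clustering: ANOVA p (Bonferroni x84) = {row['p_bonferroni']:.2g}; "
              f"group means: { {g: round(m, 3) for g, m in row['group_means'].items()} }")
```

prints

```
FSIQ<80: n=17, disease course 2.60 +/- 1.14 months
FSIQ>80: n=18, disease course 0.58 +/- 0.31 months
pooled t-test: t=7.21, p=2.8e-08
beta-band clustering: ANOVA p (Bonferroni x84) = 2.1e-08; group means: {'impaired': 0.417, 'non_impaired': 0.591, 'control': 0.568}
```

The cohort lines reproduce the published clinical summaries (note the
impaired-group SD of 1.14 — the published "±0.58" is a typesetting slip,
see `docs/methods.md`). The pipeline lines show a synthetic cohort in which
the impaired group's frontal beta coupling was scaled by 0.4: the
beta-band clustering coefficient comes out reduced in that group and
survives the 84-fold Bonferroni correction, and `report["roc"]` lists the
discriminating parameters with their AUC / sensitivity / specificity.

The same stages are available from a shell:

```bash
megnet init-config --demo cfg.yaml
megnet all --config cfg.yaml --seed 1 --out run/
# or stage by stage: megnet simulate|preprocess|connect|metrics|stats ...
```

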