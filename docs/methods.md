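# Methods

## Scope and model

`megnet` implements a resting-state MEG functional-connectivity (FC)
analysis at the source level. Its inputs are "virtual sensor" time series —
reconstructed source waveforms at a set of brain locations — together with a
clinical cohort table for a pediatric focal-epilepsy study design (children
with self-limited epilepsy with centrotemporal spikes, split at a full-scale
IQ of 80 into a cognitively impaired and a non-impaired group, plus healthy
controls). Source reconstruction itself (beamforming, MRI co-registration)
is out of scope: the pipeline starts at the waveforms.

The analysis chain is:

1. **Preprocessing** — zero-phase notch near 50 Hz; amplitude-artifact
   exclusion (any sample with |x| > 6 pT on any channel, padded ±0.5 s);
   automatic spike flagging on the 1–70 Hz band via robust z-scores
   (median/MAD, threshold 6); selection of the earliest continuous 60 s
   window free of flagged events; decomposition into seven bands
   (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–80,
   ripple 80–250, fast ripple 250–500 Hz).
2. **Connectivity** — Pearson correlation R of every source pair over the
   window; the t-type statistic TP = R·√(K−2)/√(1−R²) with K the sample
   count; an edge is retained when |TP| exceeds the two-sided Student-t
   critical value at α = .01 with K−2 df. Retained edges carry weight |R|
   and the sign of R (positive vs negative connections).
3. **Graph metrics** — node strength S_i = (1/N)Σ_j w_ij; degree d_i; path
   lengths with edge lengths 1/w and L_ij = 0 for unreachable pairs;
   geometric-mean weighted clustering with weights normalized by the
   network maximum. Network values SA, DA, LA, CA are plain means over all
   N nodes.
4. **Group statistics** — per band (and per parameter for the graph
   metrics) one-way ANOVA across the three groups, Bonferroni-corrected
   with family sizes 3 × 7 = 21 (FC) and 3 × 7 × 4 = 84 (graph metrics);
   post-hoc pairwise Student t-tests Bonferroni-corrected within each trio;
   Kolmogorov–Smirnov and Levene checks as warnings; Pearson/Spearman
   clinical correlations; single-predictor logistic regression and ROC
   analysis (Mann–Whitney AUC, Youden-optimal operating point) to
   discriminate the impaired group.

## Interpretive choices the formulas force

* In the correlation definition, the numerator term is read as the sample
  **covariance** of the two source signals — the only reading under which R
  is a correlation bounded by 1. The denominator is the product of sample
  standard deviations.
* The strength formula is read as the sum of w_ij over the partners j of
  node i, divided by N, matching its printed 1/N factor; the classic
  unnormalized sum is available via `normalized=False`.
* The unreachable-pair convention L_ij = 0 is applied **inside** the LA
  average, exactly as defined. This makes sparser networks look "shorter",
  which is counterintuitive but deliberate; interpret LA only jointly with
  DA and density.
* The weighted clustering formula lacks a normalization that would bound it
  by 1; weights are divided by the network's maximum weight first (the
  standard geometric-mean convention), so C_i ∈ [0, 1] and the binary case
  reduces to the unweighted clustering coefficient.
* Graph metrics are computed on the **positive-connection** subnetwork by
  default — the substantive group findings concern positive connections,
  and mixing signs inside geometric means is ill-defined. Absolute-value
  weighting is exposed via `edge_policy="absolute"`.
* Edge thresholding is two-sided: negative connections are real and are
  retained (with their sign) when |TP| crosses the critical value.

## Degrees of freedom of the edge threshold

The TP threshold treats the K samples of the window as independent. After
band-pass filtering they are not: a band of width B at sampling rate fs
carries roughly K·2B/fs independent values, so the nominal-K rule is far
too liberal on band-limited data (in our null simulations it retains ~60%
of pairs instead of 1%). The package therefore exposes two policies:

* `k_policy="nominal"` (module-level default): the rule exactly as
  defined, appropriate when samples are serially independent;
* `k_policy="bartlett"`: per-pair effective sample counts via the
  Pyper–Peterman/Bartlett formula
  1/K_eff = 1/K + (2/K)Σ_l (1−l/K)·r_a(l)·r_b(l), with channel
  autocorrelations estimated by FFT and the lag sum truncated at
  min(K−3, 10√K). Null edge density then recalibrates to ≈ α on
  band-limited data (0.9–1.0% in our checks).

The pipeline's study configuration uses the Bartlett policy; without it the
graph metrics are dominated by spurious edges and group effects planted in
the generator are barely recoverable.

## The synthetic-data generator

`synthetic_meg` emulates the study's recording conditions: 120 s at
6000 Hz (defaults), nominal picotesla units with a background SD of 0.5 pT
split evenly across the seven bands, optional spike transients (<100 ms,
biphasic, Poisson-timed) and >6 pT artifacts to exercise the cleaning
chain.

Each node's signal is a sum over bands of band-limited Gaussian components.
Per band, the target cross-node correlation matrix (identity plus planted
edges, after group multipliers and optional per-subject jitter) is imposed
exactly by Cholesky-mixing i.i.d. noises; for one planted edge this is the
shared-variance construction x_i = √ρ·z_common + √(1−ρ)·z_i, so the
expected band-filtered correlation equals ρ. Components are synthesized in
the frequency domain with a **spectral guard margin** of 5% of the band
width on each side. The margin matters: without it, energy at shared band
edges (e.g. theta/alpha at 8 Hz) leaks through the neighboring analysis
filter as independent variance and dilutes the recovered correlation by
several percent. With it, the analysis filter acts identically on shared
and private parts, E[R] = ρ holds (empirically within ±0.01 over 50
seeds), per-band variance is exact by Parseval normalization, and distinct
bands are exactly uncorrelated. Per-subject seeds derive deterministically
from the base seed and subject index; identical config + seed reproduces
recordings bit for bit.

What the generator does **not** emulate: 1/f spectra, neural forward
models, head geometry, sensor noise covariance, heart/eye artifacts, or
inter-regional leakage from source reconstruction. Passing recovery tests
therefore demonstrates the statistical machinery, not robustness to those
real-data features.

### Study conditions used in tests

The end-to-end recovery study uses group sizes 17/18/18 (impaired /
non-impaired / control), planted intra-regional coupling ρ = 0.6 among
4 "frontal" and 4 "PCC" nodes in every band (12 nodes total), per-subject
coupling jitter SD 0.05, and a multiplicative coupling deficit of 0.4 in
the impaired group on the affected (role-pair, band) combinations — by
default frontal–frontal in beta and PCC–PCC in ripple/fast ripple,
mirroring the direction (not the magnitude, which is unpublished) of the
study's findings. Simulations run at 2000 Hz with a 30 s analysis window,
keeping K = 60 000 samples per window and the full seven-band decomposition
while holding the whole replicate study to a few CPU-minutes; the full-rate
(6000 Hz, 60 s) configuration is the package default for single runs.

## Clinical cohort notes

The packaged 35-patient table reproduces the printed group summaries
exactly: 17/18 split; mean disease course 2.60 vs 0.58 months; mean seizure
counts 2.88 vs 1.56; mean ages 6.88 vs 8.11 (7.51 ± 1.60 overall); course
and seizure differences significant far below p = .001 by pooled t-test.
One published dispersion value is irreproducible from the table: the
impaired group's course is quoted as "2.60 ± 0.58", but the sample SD of
those 17 values is 1.14 — 0.58 is the *other* group's mean, evidently a
typesetting slip. The fixture is authoritative; the SD is reported as
recomputed.

The group comparison t-test defaults to the pooled (Student) form, with
Welch as an option. Sample SDs use the n−1 denominator throughout.

The study's contingency-table analysis of the spatial distribution of main
connections (Fisher's exact / chi-square) is not implemented: the published
description does not define what counts enter the table.

## Numerical details

* Filters: 4th-order Butterworth band-passes and a Q = 30 IIR notch, all
  applied forward–backward (zero phase, verified by pulse center-of-mass
  preservation). The first/last 0.5 s of the spike-detection z-scan are
  excluded as filter edge transients; flagged samples are padded ±0.5 s
  and intervals merged.
* Clean-segment tie-break: the earliest admissible window wins.
* Logistic fits that separate completely fall back to a small ridge
  penalty (warning emitted) because the ML estimate diverges.
* ROC orientation is chosen so AUC ≥ 0.5; ties in predictor values count
  1/2 in the pair-counting AUC; Youden ties resolve to the earliest cutoff.
* ANOVA/t degenerate cases: zero within-group variance with equal means
  yields F = 0 (t = 0), p = 1; with unequal means, p = 0.
* Regional FC is operationalized as the mean weight of retained positive
  edges incident to the nodes of a role ("frontal", "pcc"), since no
  regional statistic is defined in the source analysis.

## Known limitations

* The nominal-K threshold is anticonservative on band-limited data (see
  above); results produced with it should be read as descriptive.
* The effective-K estimate is itself estimated from the data and is
  slightly conservative for very narrow bands at short windows.
* The LA = 0 unreachable convention couples path length to density.
* Synthetic group effects are multiplicative on planted couplings only;
  no subject-level confounds (age, artifact load) are modeled.
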