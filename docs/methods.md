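# Methods

This note documents the models, estimators and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Growth-curve model (synthetic data)

Each well's OD650 trajectory follows a three-phase model: flat lag at
the inoculum density N_init, a pure exponential segment
N_init·e^{r(t−lag)}, and — once density reaches K/2 — a logistic
continuation K/(1+e^{−r(t−t_half)}) that is value-continuous at the
switch and saturates at the carrying capacity K. The pure-exponential
segment is exact by construction so that rate recovery on noiseless
curves can be verified to machine precision. Additive Gaussian read
noise is applied to OD and truncated at a positive floor.

Defaults (per well, chosen once as realistic for a pseudomonad in rich
KB medium at 28 °C and fixed thereafter):

| parameter | default | unit | rationale |
|---|---|---|---|
| `r_per_h` | 0.5 | 1/h | doubling ≈ 1.4 h in rich medium |
| `lag_h` | 1.5 | h | short lag after a fresh transfer |
| `n_init` | 0.01 | OD | a 1% transfer of a saturated (K ≈ 1) culture |
| `carrying_capacity` | 1.0 | OD | dense stationary culture |
| `noise_sd` | 0.01 | OD | 1% of K; plate-reader scale noise |
| `rate_cv` | 0.02 | — | lognormal replicate-to-replicate rate jitter |
| `od_floor` | 1e-4 | OD | truncation floor; values at the floor are excluded from fits |

The per-day, per-treatment **effect profile** multiplies the baseline
rate and encodes the qualitative response pattern: day 1 faster with
phage density (1.5×/1.7×/1.9× for the 1:10/1:2/1:1 ratios), days 2–3
slower (0.75–0.92×, the compensatory cost), day 4 back to 1×. The
magnitudes are package choices — only the pattern (direction, density
ordering, transience) carries meaning, and tests assert the pattern or
the truth table, never the magnitudes as external facts.

The generator does **not** emulate: dynamic carry-over between days
(each day's curves are generated independently from the truth table,
since the analysis treats days independently), lysis or phage
replication (the phage are inactivated), resistance evolution,
plate-position effects, or non-Gaussian reader artefacts (drift,
bubbles). Passing tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to every
plate-reader pathology.

## Doubling-time estimator

The exponential phase is detected by sliding a fixed-width window
across the log-transformed series and keeping the window with the
largest fitted slope; the doubling time is ln 2 / slope, which on the
window endpoints equals Δt·ln2/(ln N* − ln N₀).

Additive OD noise becomes heteroscedastic after the log transform
(variance ∝ 1/OD²), and maximising over hundreds of overlapping windows
selects upward noise excursions preferentially. Three numerical
safeguards address this, all of which vanish on noiseless data so that
the procedure degenerates to plain max-slope least squares there:

* **Inverse-variance weighting.** The within-window regression uses
  weights ∝ OD² (the delta-method inverse variance of ln OD), with the
  read-noise sd estimated robustly from second differences of the OD
  series: sd ≈ 1.4826·median|Δ²OD|/√6. Second differences cancel
  locally linear trend; the estimator returns exactly 0 on noiseless
  piecewise-linear data.
* **Adaptive detection limit.** Windows whose weighted mean OD is below
  `detection_k` (default 15) times the estimated noise sd are not
  eligible: readings that close to baseline carry almost no rate
  information but dominate the unweighted log-scale fit. If no window
  qualifies, all compete.
* **Lower-confidence-bound selection.** Among eligible windows the
  winner maximises slope − `selection_z`·se(slope) (default z = 2),
  with the model-based se = (Σ wᵢ(tᵢ−t̄)²)^{−1/2}. Penalising by the
  sampling uncertainty removes the systematic upward bias of
  max-over-windows selection.

Ties (e.g. the exact slope plateau of a noiseless exponential) are
broken toward the earliest window start within a relative tolerance of
1e-9, making the output deterministic and independent of floating-point
summation order.

The default window width is 12.5% of a curve's usable points (31 of
250, minimum 5). Narrower windows are noise-fragile; much wider ones
overrun the exponential span of the fastest (1.9×-rate) day-1 curves,
whose log-linear stretch covers about 4 h at the default grid. With
these defaults the estimator recovers true rates on the default design
with ≈2% median relative error at 1%-of-K noise and ≈3% at 2%-of-K
noise, and per-(day, treatment) mean doubling times stay within 10% of
their truth-table values at 2% noise — both checked by the test suite
at exactly these settings.

No OD-bias correction is applied when fitting plates: because smaller
cells depress OD, any size reduction makes the measured growth
acceleration an underestimate, i.e. the conservative direction. The
`od_bias_experiment` diagnostic quantifies the effect on known count
series (a size trend of factor s(t) shifts the observed log-slope by
d ln s/dt exactly).

## Bound-phage dilution model

Inactivated phage bind but never replicate, so the bound pool is only
redistributed. With each particle independently assigned to a daughter
with probability 1/2 (binomial rule, default), the total over an
untruncated lineage tree is conserved exactly per realization while the
per-cell mean halves each generation: load(n) = P₀/2ⁿ. The smallest n
with P₀/2ⁿ < 1 is 9 for P₀ = 500 and 10 for P₀ = 1000.

The quantity "initial bound phage per cell" is not uniquely
determined by the experimental densities (10⁶–10⁷ phage/ml against
~10⁴ inoculated cells, volumes partly unstated); the pipeline therefore
reports a configurable set of initial loads, default {100, 500, 1000}
(density/ml × 1 ml ÷ 10⁴ cells for the three ratios), and converts
divisions to hours using the mean fitted day-1 doubling time of the
exposed treatments. A `deterministic_half` rule (floor/ceil split,
alternating the extra particle) is kept for closed-form tests, an
optional per-generation survival probability models passive particle
degradation, and lineage growth beyond `max_cells` (default 4096) is
handled by uniform subsampling, flagged in the output; conservation
checks run untruncated at small n.

## Cytometry model and comparisons

Scatter values are lognormal per (day, treatment); "cell size" is
operationalized as forward scatter. The default truth table makes
exposed cells 2.5× smaller in mean FSC than the control on day 1,
attenuating through 2.0× and 1.6× to 1.3× on day 4 — smaller effects
over time but no full return to baseline — identically for the three
phage densities, with side scatter left unshifted. (Which scatter
channel best reflects the size change is genuinely ambiguous in this
kind of assay; the package reports both channels and takes forward
scatter as the size proxy without adjudicating.) The
assay default is 2×10⁵ events per sample; pipeline runs default to a
scaled-down 2×10⁴ with 10⁴-event subsamples in the permutation loop,
which keeps a full run in seconds at negligible loss of resolution for
mean ratios.

Distribution comparisons use the two-sample ECDF-supremum statistic
D = sup_x |F̂_a − F̂_b| with a label-permutation p-value — exact in
level for any sample size, no asymptotic approximation — computed with
add-one smoothing (b+1)/(m+1) so p is never reported as 0. The
permutation loop works on the sorted pooled values, where D is the
maximum |cumulative sum| of ±1/n increments evaluated at the last index
of each distinct value (midrank-safe under ties), so each permutation
costs O(n).

## Kruskal–Wallis test

Midranks over the pooled sample; H = [12/(N(N+1)) Σ R_i²/n_i − 3(N+1)]
divided by the tie correction 1 − Σ(t³−t)/(N³−N); df = k−1; the
upper-tail probability is the regularized incomplete gamma
Q(df/2, H/2). When all N values are identical the tie correction
degenerates and the statistic is defined as H = 0 with p = 1 — the
no-evidence limit — rather than an error, so batch pipelines keep
running. The permutation reference enumerates all distinct assignments
exactly when `n_permutations=None` (p = b/m including the observed
assignment) and otherwise Monte-Carlo samples with add-one smoothing.
Normality pre-screening is deliberately absent: the rank test is
applied unconditionally.

Calibration, checked by the suite: type-I error at α = 0.05 within
[0.02, 0.08] over 500 null simulations (4 groups of 10), χ² and
permutation p within 0.03 of each other for balanced null groups of 12,
and the χ² tail within 1e-8 of direct numerical integration for
df 1–10.

## Pipeline

`RunConfig` (YAML-round-trippable) fixes the seed, design, generator
truth, fitting and testing settings; `run()` executes generate → fit →
rank tests → cytometry → dilution, writes every intermediate as CSV,
and emits `report.json` validated against the bundled JSON schema
(a pydantic model; the shipped `report_schema.json` is its export).
Identical configuration and seed give byte-identical reports — no
timestamps; provenance carries the SHA-256 of the scientific
configuration (output path excluded), the seed and the package version.
Per-stage failures abort with the stage name and rename partial outputs
to `*.partial`. Standard errors in the growth summary are sd/√n over
replicates. Day-to-day correlation of a replicate line is ignored
(days are modelled and tested independently).

The numbered `analysis/` scripts are thin drivers over the same
library functions and form the command-line surface of the package.

## Known limitations

* The estimator's safeguards assume additive, roughly stationary read
  noise; multiplicative or drifting noise would call for different
  weights.
* Windowed rate estimation attenuates toward the mean when the true
  exponential span is shorter than the window; the default width is a
  compromise tuned to the default design's rate range.
* Cytometry ingestion expects pre-gated event tables; no compensation,
  doublet discrimination or scatter-to-micrometre calibration is
  attempted, so "2.5× smaller" refers to mean forward scatter, not
  physical width.
* The dilution model ignores phage detachment and assumes synchronous,
  symmetric division apart from the particle split itself.
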