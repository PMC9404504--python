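# Methods

This note documents the models, the numerical choices and the synthetic-data
design behind `hypnoeeg`, and what the tests do and do not demonstrate.

## Signal chain

Recordings arrive in two dialects, 178 Hz and 89 Hz (the latter carrying a
built-in monitor lowpass above ~25 Hz).  All recordings are brought to a
common 89 Hz grid by polyphase decimation with anti-aliasing (`resample_poly`;
the 178→89 path is an exact 2:1 decimation).  Filtering is always zero-phase
(forward–backward second-order sections), so event times never shift; the
price is a squared magnitude response, which the tests account for (a 4th-order
Butterworth applied twice attenuates by `1/(1+r⁸)` at the bilinear-prewarped
frequency ratio `r`).

Segments are 15 s, tiled four per minute without overlap, aligned to the
minute grid anchored at the LOC instant (minute −2 … the CeMax minute).  The
alignment and non-overlap are package conventions; nothing downstream depends
on sub-segment phase.  Visual artifact rejection is replaced by a reproducible
automated rule: samples beyond ±250 μV or first differences beyond 50 μV per
sample, padded by ±0.5 s, mark a segment not clean.  Clean segments are
averaged within each minute; a minute with no clean segment propagates as a
missing value (never interpolated), and subjects missing any stage minute are
later dropped listwise from the ANOVA.

Measure routing: LZc and PE are computed on the 25 Hz-lowpassed signal (so the
two dialects carry the same bandwidth), alpha power on the 8–12 Hz bandpassed
signal, and the Welch quantities on the unfiltered equalized segments.

## Measures

**LZc.** Median binarization (strictly above the median → 1; values equal to
the median → 0, a deterministic tie rule that is measure-zero for continuous
signals).  The LZ76 exhaustive-history parse counts words: each word is the
shortest extension of the current position not copyable from the prior
sequence (overlap allowed); a trailing copyable word still counts.
Normalization is `c(n)·log₂(n)/n` for the binary alphabet, which maps
i.i.d. noise near 1 and periodic signals near 0.  The parser is verified
exhaustively against a naive reproducibility-scan parser on all binary strings
up to length 12.

**PE.** Ordinal patterns of m = 5 consecutive points, delay 1, ranks assigned
by a stable ascending argsort (ties rank the earlier point lower).  Only the
induced pattern distribution matters; the entropy is normalized by ln(5!) so
PE ∈ [0, 1].  At 89 Hz one pattern spans 5 samples ≈ 56 ms.

**Alpha power.** Mean of |analytic signal|² with 0.5 s trimmed per side
against Hilbert edge effects.  For an in-band sinusoid of amplitude A this
equals A² (twice the band power); the convention follows the Hilbert-envelope
definition rather than a PSD integral, so values are reported in μV².

**Welch.** Hann windows of 4.5 s with 50% overlap inside each 15 s segment
(five windows).  Powers are per-bin (density × bin width) so their sum is
Parseval-consistent with the signal variance.  Total power sums bins below
30 Hz; SEF95 is the lowest grid frequency whose cumulative power reaches 95%
of that sub-30 Hz total (NaN when the range holds no power); band powers sum
[lo, hi) bins with δ = 0.5–4, θ = 4–8, α = 8–12, β = 12–25 Hz.

## Pharmacokinetics

The Schnider three-compartment model with effect site:
V1 = 4.27 L, V2 = 18.9 − 0.391(age−53) L, V3 = 238 L,
Cl1 = 1.89 + 0.0456(wt−77) − 0.0681(LBM−59) + 0.0264(ht−177) L/min,
Cl2 = 1.29 − 0.024(age−53) L/min, Cl3 = 0.836 L/min, ke0 = 0.456 min⁻¹, with
James lean body mass.  All constants are config-overridable; ke0 is the
plasma-effect-site equilibration constant of the effect-site-calibrated
variant and is documented as an assumption (TCI software differs on this).

The 4-state linear system (three amounts + Ce) under piecewise-constant
infusion is solved **exactly** per segment via eigendecomposition of the
system matrix (the matrix-exponential solution evaluated vectorized on the
whole grid).  This is the default because it is exact and fast; a classical
fixed-step RK4 integrator (dt ≤ 1 s) is provided as `method="rk4"` and both
are validated against an independent step-wise `scipy.linalg.expm` oracle to
0.1%.  Mass balance (infused = retained + eliminated) holds to 0.01%.

CeMax is located as the 1-min window (anchored at LOC) with maximal mean Ce,
ties toward the earlier minute; the instantaneous peak is reported alongside.

The monitor's proprietary suppression ratio is replaced by a documented
surrogate: the fraction of a trailing 63 s window spent in ≥ 0.5 s stretches
with amplitude envelope below 5 μV; onset is the first time this exceeds 1%.
The surrogate gates protocol simulation only — never the hypnotic measures.

## Stages and statistics

The five stages are LOC−2, LOC−1, LOC, the midpoint minute between LOC and
CeMax (round-half-even; collisions in short inductions are flagged and share
one value), and CeMax.  The elderly group is age ≥ 65.

The "mixed-effect ANOVA" is the classical split-plot decomposition: the group
effect is tested against subjects-within-groups, stage and interaction
against the subject × stage residual.  Sphericity uses Mauchly's W on the
orthonormal-contrast covariance pooled within groups, with the standard
chi-square approximation; when Mauchly rejects at α = 0.05 the within-effect
degrees of freedom are multiplied by the Huynh-Feldt ε (Greenhouse-Geisser ε
continued by the split-plot HF formula with N−g+1 in place of the subject
count; capped at 1; the one-group case reduces to the textbook expression).
Effect sizes are ω² = (SS_eff − df_eff·MS_err)/(SS_total + MS_err) with each
effect's own error stratum; values may be slightly negative when F < 1 and
are reported as computed.  The implementation is cross-checked against
pingouin on balanced and unbalanced designs and against a hand-computed tiny
dataset; pingouin is never the implementation.

Power analysis is exact via the noncentral t (df = 2n−2, noncentrality
δ/(σ√(2/n))), falling back to the normal limit where scipy's noncentral t
loses accuracy (very large df).  Group tables reproduce printed summaries via
`ttest_from_summary`; Welch is the default for raw data, Student for
reproducing pooled-variance tables.

## Synthetic cohort

The generator's defaults are the study conditions: 18 young (< 65, 178 Hz,
20–25 mg·kg⁻¹·h⁻¹) and 12 elderly (≥ 65, 89 Hz with monitor rolloff,
15 mg·kg⁻¹·h⁻¹); Ce-at-LOC thresholds N(4.82, 1.39) vs N(4.31, 0.48) μg/mL
(truncated at 2.5 so two pre-LOC minutes exist); Ce-at-suppression thresholds
N(5.8, 0.9) vs N(8.0, 1.1) μg/mL — group-specific because the published CeMax
pattern (elderly ≈ 8.3 > young ≈ 6.0 despite similar Ce at LOC) cannot arise
from a single shared threshold under the protocol, where the faster young
infusion would give *young* the larger post-stop overshoot; LOC quantized up
to the 30 s assessment grid; total power scales 364.5 vs 59.3 μV² with
lognormal between-subject spread (σ_log 0.55 vs 0.27) anchored so each
group's realized mean hits its scale.

EEG is built as `background + delta_env(Ce)·delta + alpha_env(Ce)·alpha`:

* background: spectrally shaped 1/f^χ Gaussian noise (flat below 1 Hz),
  χ ≈ 1.9 young vs 1.35 elderly (per-subject jitter 0.12).  The *young*
  spectrum is the steeper, oscillation-dominated one: this joint choice is
  what simultaneously gives the elderly group lower total power, higher SEF95
  and higher LZc, matching the published directionality (a steeper elderly
  background would push SEF95 and LZc the wrong way — SEF95 of f^−2 on
  0.5–30 Hz is ≈ 7.6 Hz vs ≈ 16.7 Hz for f^−1.5).
* delta: 0.5–4 Hz bandpassed noise with amplitude `base + rise·Ce`
  (monotone "delta takeover" at depth).
* alpha: 8–12 Hz bandpassed noise with a Gaussian amplitude bump in Ce
  centered near the group-typical Ce at LOC (width 1.8 μg/mL) — the biphasic
  rise-then-fall alpha trajectory.
* suppression: above the subject's suppression threshold the signal
  alternates bursts and near-isoelectric epochs (amplitude × 0.02) whose
  suppressed fraction grows with the Ce overshoot, with soft 50 ms edges.
  The protocol stop is the first Ce crossing of that threshold, floored so
  suppression never intrudes into the LOC minute (mirroring the stop rule,
  under which suppression is marginal until after the analysis windows).
* the 89 Hz dialect receives an extra 4th-order 25 Hz lowpass emulating the
  monitor's built-in filtering.

The overall amplitude is scaled so the LOC-minute Welch total power matches
the subject's target.  A surrogate BIS (monotone sigmoid of per-minute Ce,
ceiling ≈ 97.5 at Ce = 0, plus noise and a configurable group offset, +15 for
elderly by default) exercises the external-index plumbing; it makes no claim
to reproduce the proprietary index.

One seed drives a `SeedSequence` tree: per-subject parameter and noise
substreams plus a group-level total-power stream, so components vary in
isolation and a fixed seed reproduces the cohort bit-exactly.

Two calibration presets support the simulation studies: `CohortSpec.null()`
makes the two groups label-exchangeable (shared rates, thresholds, spectra
and dialect; only the ages, hence the labels, differ — residual age-driven PK
differences are the one group-linked input, and the realized type-I error of
the group effect stays within the binomial band around 5%), and
`CohortSpec.with_lzc_effect()` shifts the elderly background exponent by
−0.45, a designed complexity difference that realizes ≈ 1.7 pooled SD at LOC
with n = 18/12.

### What the generator does not emulate

It is a linear-noise surrogate, not a neural-mass model.  Known gaps: PE and
LZc are tightly coupled to the background spectral slope here, so the
generator does *not* reproduce the study's age-independence of PE (its
defaults give the elderly group higher PE along with higher LZc); absolute
alpha-power magnitudes are inflated relative to the published table because
the 1/f background contributes substantially to the 8–12 Hz band; artifacts
beyond simple injected spikes, eye movements, and electrode drift are absent;
and no baseline (pre-infusion) spectral claims are made — baseline parameters
are free design choices.  Passing tests therefore demonstrate pipeline
correctness and statistical calibration under the stated model, not clinical
generalizability.

## Problem sizes and runtimes

Replicated simulation studies (type-I calibration: 400 cohorts; power: 200
cohorts) run the reduced pipeline — the measure under test only, stage or LOC
minutes only — which computes identical values to the full pipeline on those
cells (asserted by test); everything else runs the full chain on study-sized
cohorts (30 subjects, full measure set).
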