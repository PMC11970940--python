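# Methods

This note documents the models, conventions and design choices behind
`ppgstress`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal conditioning

The raw PPG sample stream (nominally 100 Hz) carries a large DC level and
slow baseline wander from respiration and motion, both below ~0.5 Hz,
while the cardiac pulse fundamental lies at 0.8–2 Hz. A second-order
Butterworth high-pass at 0.5 Hz separates them. The filter is applied
forward–backward (`sosfiltfilt`), which squares the magnitude response and
cancels phase: beat timing is the quantity of interest downstream, so the
filter must not displace peaks. Reflective padding suppresses startup
transients inside 30-s windows.

A complementary zero-phase low-pass (default 10 Hz, `lowpass_hz=None` to
disable) removes broadband sensor noise above the band where PPG carries
energy. Without it, wideband noise superimposed on the rounded systolic
peak shifts the integer-sample argmax by tens of milliseconds; with it,
the residual in-band noise perturbs peak timing by only a few
milliseconds. This band-limiting step is a deliberate addition to the
minimal high-pass-only conditioning chain and is documented here because
it affects reported RR precision.

**Normalization.** Each window is divided by its maximum absolute value,
giving amplitudes in [−1, 1]; the source design documents describe the
normalized range inconsistently (−1..1 in the methods text, 0..1 in a
figure), and this package follows the methods text: divide by max |x|, and
apply the 0.5 peak threshold on that scale. Normalization is always *per
30-s window*: a single noise excursion then inflates the scale of one
window only, rather than depressing every peak of a long record below the
fixed threshold. `ppg_to_rr` exposes exactly this windowed path for whole
records.

Degenerate (all-zero) windows are flagged invalid rather than normalized;
no NaN ever propagates.

## Beat detection and RR extraction

A beat is a local maximum with normalized amplitude ≥ 0.5 separated from
the previous beat by a refractory period of 250 ms (capping detectable
heart rate at 240 bpm and suppressing double-detection on secondary
oscillations). Peak positions are integer sample indices; no sub-sample
interpolation is applied, so RR intervals are quantized to one sample
(10 ms at 100 Hz). This quantization is accepted and shows up in the
tests' tolerance bounds (e.g. detected mean RR within one sample quantum
of truth).

Windows are processed independently; no RR interval spans a window
boundary, matching a 30-s recompute cycle. Optional artifact rejection
(`clean_rr`, bounds 300–2000 ms) is off by default in the end-to-end
pipeline.

Two pairing utilities serve device-agreement analyses: `align_rr_pairs`
applies a ±5-beat integer lag search (for two independently started
recordings), while `match_rr_by_time` pairs intervals whose opening *and*
closing beats coincide within 200 ms on a shared clock — a dropped beat
then excludes only the affected interval instead of shifting every
subsequent index pair.

## The 34 HRV parameters

Conventions differ across HRV tooling; the ones fixed here are:

| choice | value | rationale |
| --- | --- | --- |
| SD denominator | n − 1 (sample SD) for SDNN, SDSD and relative versions | dominant convention in HRV software |
| kurtosis | Fisher excess, biased moment estimator | normal → 0; matches common `kurtosis` defaults |
| skewness | biased moment estimator | consistency with kurtosis |
| HR | 60000 / mean RR | keeps `hr × mean_rr = 60000` exactly |
| pNNxx | 100 · fraction of successive differences strictly above xx ms | strict inequality, so pNN25 ≥ pNN50 always |
| relative normalization | u = RR/mean(RR) − 1 | makes `rel_mean_rr ≡ 0` and the rest scale-free |
| TF | VLF + LF + HF (0.003–0.4 Hz integral) | band percentages sum to 100 |
| normalized units | 100 · band / (TF − VLF) | `lf_nu + hf_nu = 100` whenever LF+HF > 0 |

**Spectral estimation.** The tachogram (RR in ms against cumulative beat
times) is cubic-spline interpolated onto a uniform 4 Hz grid,
mean-removed, and passed to a Hann-windowed Welch estimator: one
full-length segment for short windows, 120-s segments with 50 % overlap
for records longer than that. 4 Hz comfortably exceeds twice the HF upper
edge (0.4 Hz). Band powers are trapezoidal integrals with the density
linearly interpolated at the exact band edges, so adjacent bands partition
the spectrum without gap or overlap. The integral of the density over
[0, Nyquist] approximates the resampled tachogram variance (tested at 5 %).

Inside a 30-s window the VLF band cannot be resolved (the window is far
shorter than one 333-s cycle at the 0.003 Hz band floor); VLF is
integrated anyway for fidelity to the windowed pipeline, and the feature
vector carries a `vlf_unresolved` flag.

**Nonlinear parameters.** Sample entropy follows the Richman–Moorman
construction: both template counts run over the same n − m templates,
self-matches are excluded, the Chebyshev criterion is strict (< r), with
m = 2 and r = 0.2 · sample SD by default (m and r are configurable since
conventions vary). No matches at length m + 1 makes the statistic
undefined; the feature extractor reports 0 with a `sampen_no_matches`
flag. Higuchi's fractal dimension is computed on the beat-indexed RR
sequence (not the resampled tachogram) with kmax = 8, suited to ~35-beat
windows; the dimension is the negative slope of ln L(k) on ln k by least
squares. Its theoretical limits — 1 for smooth curves, 2 for uncorrelated
noise — are verified by test.

**Degenerate inputs.** A window with fewer than 10 beats is invalid (no
NaN-filled rows). A constant RR series zeroes the dispersion statistics,
sets the shape statistics to 0 and flags the vector; zero band power zeroes
the spectral ratios with flags. Ratios never divide by zero.

## Stress classifier

A CART tree with maximum depth 10, minimum 10 samples per split, minimum 5
per leaf, and Gini impurity — deliberately small and interpretable, suited
to a 30-s real-time recompute cycle. Growth is delegated to
scikit-learn's `DecisionTreeClassifier` with a fixed `random_state` for
determinism; prediction runs an explicit root-to-leaf descent over the
exported node arrays so a freshly fitted model and one loaded from its
JSON archive share one code path, with leaf ties resolved toward the lower
class index. The archive stores the node arrays, the canonical 34-feature
order and a hash of both, so a feature-order mismatch at predict time
fails loudly instead of silently permuting inputs. Non-finite features are
rejected at both fit and predict time; nothing is imputed.

No class-imbalance handling is applied (the synthetic tables are balanced
by construction).

## Synthetic data: what it emulates and what it does not

The RR generator is sinusoid-plus-noise:

    rr_k = mean + A_LF·sin(2π·0.1·t_k) + A_HF·sin(2π·0.25·t_k) + N(0, σ)

advancing cumulative beat time until the requested duration. It places
controllable power exactly at the two modulation frequencies the spectral
features must recover (Mayer-wave range and respiratory range), which is
what makes band-recovery tests sharp. It is *not* an integral
pulse-frequency-modulation model: real tachograms have broadband 1/f-like
structure, respiratory nonstationarity, and amplitude–frequency coupling
that this generator omits. Consequently, passing tests demonstrate that
the pipeline recovers known spectral structure, not that it handles every
property of real physiological data.

PPG rendering places a unit-peak gamma-shaped pulse (fast rise, slow
decay; shape 2.5, support equal to the configured pulse width) at each
beat time, then adds DC offset, sinusoidal baseline wander and white
noise. Dicrotic notches and pulse-amplitude variability are not modeled.
In heart-rate sweeps the pulse width tracks the interval
(min(0.30 s, 0.35 · RR)), reflecting the physiological shortening of
systole at higher rates.

Stress classes are encoded through the two most robust directions of real
stress responses — mean RR falls, LF:HF amplitude balance rises — with
class centres 800/20/40 ms (none), 760/35/30 (moderate), 720/50/18
(severe), RR noise 10 ms, ±30 ms draw jitter on the mean and ±10 % on the
amplitudes. All other 32 features vary only as consequences of the
generated physiology. The six-phase protocol plan mirrors a standard
stress-induction session: Rest 1 (5 min), Stroop 1 (5 min, class 1),
Rest 2 (10 min), Stroop 2 (5 min, class 2), Rest 3 (10 min), Relax
(10 min). For questionnaire regressions, a subject's resting profile can
be tied monotonically to a DASS-21 stress score (0–42): mean RR
800 → 740 ms and LF:HF amplitudes 20:40 → 40:25 ms across the scale.

Every generator is bit-reproducible given its spec and seed.

## Protocol statistics

Per-phase scores are reported both as raw sums of window labels and
normalized by the valid-window count (the normalized score lives on the
same 0–2 scale as a single label). Questionnaire regressions use raw sums.
Adjacent phases are compared with the paired two-sided Wilcoxon
signed-rank test — HRV quantities are skewed, so a rank test is the safer
default — with a paired t-test available; below 6 pairs the exact null
distribution is used and noted in the output. No multiple-testing
correction is applied by default; a Holm step-down option exists. The
test's type-I calibration at α = 0.05 is itself verified by simulation in
the acceptance suite.

## Problem sizes

The shipped tests and the acceptance script use: 100 random RR series for
oracle agreement; 5-minute records at six heart rates (50–120 bpm) for the
detection sweep; 300-s series for spectral recovery; 600 windows
(200/class) for classifier training with a stratified 70/30 split; 25
simulated subjects × 45-minute sessions for the protocol analyses; and
1000 replicates for the Wilcoxon calibration. These sizes were chosen to
match the scale of the emulated study design (5-minute measurements,
25 participants) while keeping a full run inexpensive.

## Known limitations

- RR precision is bounded by the 10-ms sample quantum at 100 Hz; no
  sub-sample peak refinement is attempted.
- The VLF feature inside 30-s windows is reported but physically
  unresolved (flagged).
- Printed relative-statistic conventions differ between published tables
  and any simple normalization (e.g. a relative skewness cannot flip sign
  under a positive affine map); this package's relative definitions are
  the documented u = RR/mean − 1 family.
- The synthetic stress classes are far better separated than field data;
  the classifier-recovery result is a correctness check of the pipeline,
  not an expected field accuracy.
- Motion artifacts, arrhythmia, and sensor saturation are out of scope of
  both the generator and the detector.
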