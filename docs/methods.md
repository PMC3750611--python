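# Methods

`radcomp` evaluates radiotherapy treatment plans radiobiologically from
their dose-volume histograms (DVHs) and compares two dose-calculation
algorithms — a pencil-beam-convolution-like engine ("PBC") against an
anisotropic-analytical-algorithm-like engine ("AAA") — on paired plans,
one pair per patient. This note records the models, the conventions
the implementation fixes where the literature leaves them open, what
the synthetic cohorts do and do not emulate, and the known limitations.

## DVH representation and conventions

A differential DVH is a uniform grid of dose bins (default step
0.25 Gy, the customary export resolution of clinical planning systems;
configurable) with the relative volume fraction per bin. The dose of a
bin is its centre; all radiobiological operations require normalized
volumes (summing to 1), with absolute volumes carried as metadata only.

Conversion to the cumulative form treats each bin's volume as
concentrated at the bin centre: the curve of "volume receiving at
least dose d" drops near-vertically (over 1 nGy) at each occupied
centre. This choice makes a uniformly irradiated structure behave
exactly like one: D2% = D95% = Dmedian and an inhomogeneity index of
zero, rather than an artefactual (D2%−D95%) of about 0.93 bin widths
that a drop smeared across the bin would produce. The cumulative value
at a bin's lower edge still equals the tail sum from that bin upward.

Dose-volume indices interpolate the cumulative curve linearly between
samples. Dx% returns the midpoint of the set of doses at which the
curve crosses the x% level, so a level landing on a plateau (e.g. the
median of a half-at-20 Gy / half-at-60 Gy distribution) resolves
deterministically to the plateau midpoint (40 Gy). Levels above the
first sample clamp to dose 0's volume (100%); levels below the last
sample clamp to the maximum tabulated dose. Vx is the interpolated
cumulative volume at x Gy, 0% beyond the maximum dose.

Rebinning spreads each source bin's mass uniformly over the bin and
reassigns it to destination bins by overlap proportion; total volume
is conserved exactly and the mean dose moves by less than half the new
bin width.

The inhomogeneity index is II = (D2% − D95%)/Dmedian: 0 for a uniform
target dose, invariant under uniform dose scaling.

## Dose-response models

**EQD2.** Each bin dose D is converted to its equivalent in 2 Gy
fractions with the linear-quadratic model, EQD2 = D·(d + α/β)/(2 + α/β),
with per-bin fraction dose d = D/n_fractions (all fractions assumed
identical). Organ-at-risk DVHs use α/β = 3 Gy; the correction is
applied only when a plan's fraction dose deviates from 2 Gy by more
than 0.01 Gy (e.g. the 69.96 Gy / 33-fraction simultaneous-integrated-
boost scheme, 2.12 Gy/fraction). The transformed DVH is re-deposited
on a uniform grid with the input's step phase, which makes the
transform exactly the identity at 2 Gy/fraction at the cost of at most
half a bin of dose quantization elsewhere.

**gEUD / Kutcher-Burman reduction.** The generalized equivalent
uniform dose is gEUD = (Σᵢ vᵢ·Dᵢ^(1/n))ⁿ: n = 1 gives the mean dose
(parallel organ), n → 0 the maximum dose (serial organ). It is
evaluated in log space (logsumexp), so exponents of order 1/n cannot
overflow; n below 10⁻⁴ short-circuits to the maximum occupied bin
dose. The equivalent effective-volume reduction
v_eff = Σᵢ vᵢ·(Dᵢ/D_max)^(1/n) at reference dose D_max satisfies
D_max·v_effⁿ = gEUD and is kept as an independent route: the two paths
agree in NTCP to better than 10⁻⁹ and are cross-checked in the tests.

**LKB NTCP.** NTCP = Φ(t) with t = (gEUD − D50)/(m·D50), Φ the
standard normal CDF. Note the probit form has a nonzero intercept: at
zero dose it leaves Φ(−1/m), which is negligible for m ≲ 0.2 but
reaches ~1.3% for the steepest published slope (m = 0.45). This is a
property of the model, not of the implementation.

**Relative seriality NTCP.** Per-bin Poisson response
P(D) = 2^(−exp(e·γ·(1 − D/D50))) combined as
NTCP = [1 − Πᵢ(1 − P(Dᵢ)ˢ)^(vᵢ)]^(1/s); s → 1 is a serial organ,
s → 0 parallel. Uniform whole-organ irradiation collapses to
NTCP = P(D) for any s (verified algebraically and numerically). The
product is accumulated in log space with a stable log(1−eˣ); s below
10⁻⁶ is rejected rather than approximated by a parallel limit (the
smallest published value is 0.0061).

**LQ-Poisson TCP.** TCP = Πᵢ P(Dᵢ)^(vᵢ) with the same Poisson response
using γ50/D50, computed on the EQD2-corrected target (CTV) DVH. The
literature on the comparison this package supports states only the
α/β ratios (10 Gy generally; 1.49 and 10 Gy bracketing the prostate
debate), not D50/γ50, so absolute TCP values are run configuration:
the defaults (γ50 = 2 and D50 = 40/48/56 Gy for breast/lung/head-and-
neck; 62 and 51.5 Gy for the two prostate α/β settings) were chosen
once so that uniform irradiation at each site's prescription yields a
plausible control probability, and are documented as package defaults,
not published constants.

**Reporting floor.** Probabilities below 0.1% are reported as zero, at
output time only; raw values are retained in the machine-readable
tables.

## Parameter library

All 25 published NTCP parameterizations (6 heart, 8 lung, 3 parotid,
7 rectum, 1 femoral head) ship in a versioned YAML file with organ,
endpoint, citation label, volume-convention note, and — for the two
De Jaeger lung rows — the dose-engine basis (equivalent-pathlength vs
convolution-superposition) that distinguishes them. Sources with
several rows carry a variant tag so every set has a unique key. A
second, independently transcribed copy of the tables lives in the test
fixtures as a double-entry guard. When a parameter set's volume
convention (e.g. "rectal wall") disagrees with the convention label of
the structure supplied, the pipeline computes anyway and emits a
warning. The Gagliardi lung set is evaluated per lung when separate
left/right lung structures are present, per its "separate organs"
note; on a single combined lung structure it is reported once.

## Synthetic paired cohorts

No patient DVHs are deposited with the study this package re-examines,
so a seeded generator produces paired cohorts whose *systematic
differences* emulate the published PBC-vs-AAA patterns. Each patient
is one latent draw of structure-shape parameters; the AAA-like plan is
derived from the *same* draw by a deterministic algorithm effect, so
pairs are positively correlated as the paired t-test assumes.
Per-patient random substreams are spawned from the master seed by
patient counter: growing a cohort never reshuffles earlier patients.

Shapes: targets are near-Gaussian dose peaks (mean, spread); organs at
risk are two-component mixtures — an irradiated fraction near a
shoulder dose plus a low-dose bath. Algorithm effects shift the target
mean down and inflate its spread (broadened penumbra: lower D95%,
higher II, lower TCP), shift the organ-at-risk high-dose shoulder, and
move the irradiated volume fraction.

Template magnitudes were read off the published mean per-metric
differences (e.g. breast: lung D2% −3.9 Gy, mean lung dose +1.8 Gy,
target mean −1.2 Gy; lung: D2% −3.6 Gy; head-and-neck: parotid mean
−1.2 Gy; prostate: rectal D2% −2.7 Gy), and inter-patient variability
loosely to the printed standard deviations. Two deliberate deviations:
the published lung-site table shows a slightly *higher* mean lung dose
under AAA alongside uniformly lower pneumonitis NTCP — a combination
that depends on patient-level DVH detail that is not recoverable — so
the lung template applies a small negative mean-lung effect, making
the NTCP direction hold patient by patient; and the synthetic lung
site ships one combined lung structure, so the "separate organs"
NTCP variant does not appear in its report.

What passing the directional tests shows: the full chain (generation →
DVH algebra → EQD2 → NTCP/TCP → paired statistics) reproduces the
published *signs* — NTCP_AAA > NTCP_PBC for pneumonitis after breast
irradiation (parallel lung, mean-dose driven), NTCP_AAA < NTCP_PBC
everywhere else (with the prostate effect strongest for the most
serial, smallest-n rectal parameter sets), TCP lower under AAA. What
it does not show: agreement with the published absolute means/sds,
which derive from 80 real patients' DVHs; the synthetic two-component
organ shapes are far simpler than clinical DVHs (no ramped rectal
curves, no multimodal lungs), and NTCP magnitudes agree with the
printed tables only to within a factor of a few.

## Statistics

Per metric and parameter set, the comparison reports the mean and
sample standard deviation (N−1) per algorithm and a two-tailed paired
Student t-test, t = mean(d)/(sd(d)/√N) on the per-patient differences,
p from the t distribution with N−1 degrees of freedom, computed on
complete pairs only. Zero-variance differences are flagged degenerate
(p = 1 for identical samples, p = 0 for a constant nonzero shift)
instead of dividing by zero. No multiple-testing correction is applied
— each metric is judged at a raw two-sided 0.05, which the report
marks with an asterisk; human-readable tables round to one decimal
(probabilities in percent), machine-readable output keeps full
precision.

## Numerical choices and degenerate inputs

- Empty structures (zero total volume) raise; unnormalized DVHs are
  rejected by operations requiring normalization.
- Cumulative inputs must be non-increasing and start at dose 0 with
  volume 1; cumulative exports in percent are rescaled on read.
- All probability products (RS, TCP) accumulate in log space.
- The near-vertical cumulative drop half-width is 5×10⁻¹⁰ Gy; the II
  of a uniform DVH is therefore ~2×10⁻¹¹ rather than exactly 0, far
  below any reported precision.
- Problem sizes: the packaged analyses use 20 patients per site (the
  size of each published site group) at 0.25 Gy binning; a full
  four-site comparison runs in a few seconds on one CPU.

## Known limitations

- No DICOM-RT parsing; DVHs enter via the text dialect or the API.
- NTCP parameters are applied, never fitted; no confidence intervals.
- TCP absolute values depend on configured D50/γ50 (see above).
- The generator models DVH shapes, not dose deposition physics; it
  cannot answer questions about specific beam arrangements or
  heterogeneity corrections.
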