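# Methods

## Optical model

The pseudophakic eye is modelled as two thin refracting elements in a
homogeneous medium of index `n` (default 1.336, used for both aqueous and
vitreous): the cornea, a single surface of power `Dc` at the vertex, and
the IOL, of power `P` at the effective lens position `d` behind the
cornea. The retina sits at the axial length `L`. The Haigis ELP model
predicts `d = a0 + a1·ACD + a2·AL` from the preoperative anterior chamber
depth and axial length only — `d` does not depend on K, which is what makes
the corneal-power inversion closed-form.

All vergence arithmetic is done in metres and diopters; millimetre inputs
are converted at the API boundary. The three closed forms are:

* predicted spectacle refraction:
  `z = n/(d + n/(n/(L−d) − P))`, `Rc = z − Dc`, `Rx = Rc/(1 + Rc·dx)`;
* IOL power for a target `Rx`:
  `z = Dc + Rx/(1 − Rx·dx)`, `P = n/(L−d) − n/(n/z − d)`;
* refraction-derived corneal power (Krd):
  `Krd = z − Rx/(1 − Rx·dx)` with `z` as in the first form.

The second and third are exact algebraic inverses of the first; the
round-trip identities (|error| < 1e−9 D over tens of thousands of sampled
states) are treated as the normative contract, which pins down the
vertex-distance sign convention without transcription risk — the classic
± vertex bug cannot survive the identity test. The closed forms are
additionally cross-checked against two independent numerical oracles (a
stepwise forward vergence trace root-solved for the spectacle power, and a
bisection search over corneal power) to 1e−6 D.

Degenerate optics (a vanishing vergence denominator, ELP outside
`(0, AL)`) raise typed errors naming the offending step or constants
rather than returning NaN.

### Keratometric handling

Scheimpflug total-power maps (TCRP, TRP 4.0 mm zone) are treated as true
corneal powers and entered directly (`k_mode = "direct"`, the default). A
`reindex` mode is provided for K values quoted with the keratometric index
1.3375 when the classical Haigis convention (1.3315) is wanted:
`r = 337.5/K`, `Dc = 331.5/r`, i.e. a rescale by 331.5/337.5.

### Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `a0, a1, a2` | — | user-supplied | lens-model-specific; example ULIB-style triple (−1.302, 0.210, 0.251) for a one-piece acrylic monofocal ships for simulation/demo only |
| `n_aqueous` | — | 1.336 | standard aqueous/vitreous index of the Haigis model |
| `vertex_distance` | mm | 12 | spectacle-plane convention; manifest-refraction vertex distances are rarely recorded, so this is configuration, not truth |
| `iol_step` | D | 0.5 | clinical labelling step; exact powers are computed first, rounding is a separate utility (ties round to the higher power, the more myopic outcome); evaluation uses unrounded predictions by default |

## Calibration

Per-eye pairs `(K_measured, Krd)` are fitted by unweighted ordinary least
squares (scipy's `linregress`), with the Pearson product-moment r and both
coefficient standard errors attached. No outlier rejection, no
errors-in-variables correction — the shipped published presets were derived
the same way, and a plain OLS keeps the calibration auditable. Per-point
weights are accepted for forward compatibility. A constant-`y` fit reports
r = 0 (correlation undefined, no association) rather than NaN; a
constant-`x` input is a degenerate-fit error.

One documented inconsistency in the published calibration: evaluating the
printed TCRP line at the printed mean K (0.989·39.24 + 0.179 ≈ 38.99 D)
does not reproduce the printed mean Krd of 38.74 D. This is consistent
with coefficient rounding in the source; the printed coefficients are
treated as normative and no reconciliation is attempted.

## Evaluation protocol

Prediction error is achieved minus predicted spherical equivalent, so a
positive PE is a hyperopic surprise. Within-threshold percentages use
inclusive bounds (|PE| ≤ 0.50 D counts as "within ±0.5 D"); the summary
carries both mean and median absolute PE because clinical reports compare
either. Method comparison on a paired eyes × methods matrix emits:
one-sample t per method (mean PE vs 0), pairwise two-sided variance-ratio
F tests plus a one-way ANOVA omnibus on numeric PE (the conventional
"ANOVA … F-test" phrasing is ambiguous, so both are reported), a Friedman
omnibus on absolute PE (Wilcoxon signed-rank when only two methods are
present) with Wilcoxon post hocs, and McNemar tests (exact binomial) on the
±0.5 D and ±1.0 D indicators. All pairwise p-values are Bonferroni-adjusted
(multiplied by the number of pairwise comparisons, capped at 1) and flagged
at α = 0.05. Degenerate inputs — constant columns, no discordant McNemar
pairs, all-tied differences — produce explicit "not computable" notes
instead of exceptions.

## Synthetic cohorts

The generator emulates post-myopic-LASIK eyes presenting for cataract
surgery. Defaults reproduce the calibration group of the published
cohorts: AL 28.08 ± 2.50 mm on (22.55, 31.62), ACD 3.63 ± 0.34 mm on
(2.83, 4.3), TCRP K 39.24 ± 2.38 D and TRP K 39.13 ± 2.49 D on
(34.45, 45.96); a validation-group preset (n = 30, AL 28.21 ± 2.24 mm,
ACD 3.61 ± 0.32 mm, K 38.83 ± 2.94 D) is also provided. Sampling is from
truncated (not clipped) normals, so there are no boundary atoms and every
generated eye passes the biometry validators; quoted means/SDs are the
pre-truncation parameters, and the moment tests compare against the exact
truncated moments.

Each eye receives a hidden true effective corneal power
`K_true = slope·K_measured + intercept + N(0, σ)`; the implanted power is
chosen by the Haigis formula from the **measured** K for a −0.5 D target
and rounded to 0.5 D steps (so nonzero target-vs-achieved differences
arise even noise-free, as in clinic); the postoperative SE is then pure
forward optics of `K_true` plus optional measurement noise (default 0).
Because the refraction is produced by the same physics the back-calculation
inverts, a noise-free cohort returns its hidden truth to float precision —
the end-to-end consistency test of generator and engine.

The residual SDs are derived, not tuned: for a straight line with slope β
fitted to x with SD σ_K, the population correlation satisfies
`r² = β²σ_K²/(β²σ_K² + σ²)`, so `σ = |β|·σ_K·√(1/r² − 1)`. With the
published (β, σ_K, r) this gives σ ≈ 1.315 D (TCRP) and σ ≈ 1.188 D (TRP);
the computation lives in `residual_sd_from_correlation` and is executed at
import, never stored as a magic number.

Design choices that were genuinely open:

* **One K source per cohort.** No joint TCRP/TRP distribution is published,
  so a cohort is driven by a single selected map (its marginal and its true
  line); the other K field is left unmeasured. Fabricating a correlation
  between the two maps would have implied fidelity the sources do not
  support.
* **Independent AL/ACD/K draws.** No covariance structure is published;
  draws are independent, which understates the real AL–K anticorrelation
  in post-myopic eyes. This limits realism of joint tails, not of the
  calibration recovery the generator exists to test.
* **What passing tests show.** Parameter recovery on synthetic cohorts
  demonstrates that the engine + calibration chain is self-consistent and
  unbiased under the stated generative model. It does not validate the
  published regression against real eyes — the clinical validation numbers
  (e.g. 60%/90% within ±0.5/±1.0 D) come from 30 undeposited patient
  records and are not reproducible from code.

## Problem sizes and numerics

Round-trip identities are asserted on 10,000 sampled states at 1e−9 D;
oracle agreement on 1,000 random cases at 1e−6 D; calibration recovery on
20,000-eye cohorts, judged within 3 fitted OLS standard errors (≈ ±0.012
on slopes, ≈ ±0.5 on intercepts at the derived residual SDs); marginal
moments on a 50,000-eye cohort within 3 standard errors of the exact
truncated-normal moments. Ties in IOL rounding go to the higher power.
Suspicious back-calculations (|Krd − measured K| > 5 D) warn but do not
fail, since the record may be genuine.

## Known limitations

* Thin-lens optics with a single refractive index; no thick-lens or
  ray-traced IOL model, no toric/meridional powers.
* Only the Haigis ELP model; SRK/T-, Holladay- or Olsen-style ELPs are out
  of scope.
* The correction presets were derived from myopic-ablation eyes; eyes with
  hyperopic corrections are outside the calibrated domain.
* Cylinder sign convention is deliberately uninterpreted — only the
  spherical equivalent is consumed.
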