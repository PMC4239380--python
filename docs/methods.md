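# Methods

## Growth law

Every lesion (primary tumour and metastases) grows deterministically along a
Gompertz curve

    x(t) = exp(ln(b) · (1 − e^{−a (t + t0)}))

with `a` the growth-rate constant (day⁻¹), `b` the saturation size (cells) and
`t0` a time offset encoding the start size. This parameterization is the
standard one used in metastatic-colonization modelling; under it the study's
printed inputs (mean weight 1.23 g at 49.9 days, b = 4.5 g, x0 = 10⁴ cells,
10⁹ cells per gram) invert exactly to the printed growth constant
0.0462 day⁻¹, which is the anchor test tying the functional form to the data
(`tests/test_growth.py::test_functional_form_anchored_to_printed_constants`).
The offset for a start size `x0` has the closed form
`t0 = −ln(1 − ln x0 / ln b)/a`; a single-cell start gives `t0 = 0`. The
inverse `t(x)` is also closed-form, so no root-finding enters the growth
model. `a = 0` is allowed only as a degenerate no-growth case.

Mass–cell conversion is fixed at 10⁹ cells/g throughout; it is what makes the
printed constants reproducible and is the conventional rounding of typical
tumour-cell densities.

Metastases share the primary's saturation `b`. At the ≤10³–10⁵-cell sizes
reached within the experiment horizons the choice is irrelevant (the curve is
indistinguishable from exponential growth there).

## Seeding

Founders are shed by the primary at the colonization rate `β(x) = m·x^α`
(α = 0.663, superficial vascularization; exposed as a parameter). β counts
only cells that would successfully found a metastasis; deaths from causes
other than NK killing are folded into `m` and not modelled separately.
Consequently killed founders are removed, never resampled.

The expected founder count `Λ(T) = ∫₀ᵀ β(x(t)) dt` is computed by adaptive
Gauss–Kronrod quadrature (relative tolerance 10⁻⁹; non-convergence raises,
never returns silently). Tests pin the quadrature against an independent
10⁶-step midpoint Riemann sum at ≤10⁻⁴ relative error.

## Event engine

The simulation is a discrete-event loop over a priority queue ordered by
(time, insertion sequence) — FIFO on ties, which makes runs bit-reproducible
per seed. Event kinds: intravasation, snapshot, end.

Arrival times follow the non-homogeneous Poisson inversion scheme: given the
current time `t`, draw `E ~ Exp(1)` and solve `Λ(t') − Λ(t) = E`. For speed
the engine precomputes `Λ` once per scenario on a dense grid (16 385 nodes,
composite Simpson) and inverts by monotone interpolation; the public sampler
also offers a quadrature + Brent root-finding path, and a test pins the two
to 10⁻⁶ days. A sampled-path test confirms the arrival counts match `Λ(T)`
within Monte-Carlo error, and a frozen-growth configuration (a = 0, constant
β) passes a chi-square goodness-of-fit against the homogeneous Poisson law.

Blood transit is instantaneous: the NK kill/extravasation Bernoulli draw is
resolved at the intravasation instant. No blood residence time is fitted or
reported by the study, and with a fixed kill probability a dwell time would
only shift founding times by the (unspecified) transit delay. Founders are
conserved exactly: founders = killed + extravasated in every replicate.

Each extravasated cell founds a metastasis growing from one cell at
`factor × a_primary` with factor ∈ {1/3, 1/2, 1}. Metastases never emit
intravasation events (metastasis-from-metastasis seeding is out of scope; the
deposits stay far too small over these horizons).

Snapshots record time, primary size, metastasis count, total metastatic cell
burden and a log-binned size histogram: a dedicated {1} bin for DTCs, then
half-open decades (1,10], (10,100], … with sizes floored to whole cells
before binning (so 10 cells falls in (1,10]). Replicate `i` uses seed
`base_seed + i`; per-bin means and sample SDs are aggregated over replicates
(SD defined as 0 for a single replicate). The default snapshot interval is
1 day; the heavy preset scenarios snapshot only at the horizon since only the
final state enters the summaries.

## Dormancy

*Dormancy*: on founding, a duration `t_d` is drawn `N(mean, sd)` truncated at
0 (negative durations are meaningless; truncation rather than resampling is
the simplest measurable convention and shifts the effective mean by <2 % at
the 30 ± 7 d setting). The lesion reports size 1 until `t_d` elapses, then
grows on the plain curve — `t_d` is a pure time shift, so the dormant curve
never exceeds the plain one.

*Late dormancy*: on founding, a trigger size is drawn `N(55, 22.5)` clipped
to [10, 100] cells — the clipped normal reconciles a mean/SD parameterization
with a hard 10–100-cell range — and an arrest duration `t_ld ~ N(30, 7)`
truncated at 0. The time the lesion reaches the trigger size comes from the
closed-form growth inverse; during the arrest the queried size is exactly the
trigger size, afterwards the plain curve applies shifted by `t_ld`.

## Calibration

All four constants chain from printed cohort summaries:

| constant | method | value |
|---|---|---|
| a (pfp/rag2) | closed-form Gompertz inversion, (1.23 g, 49.9 d) | 0.0462 day⁻¹ |
| a (rag2) | same, (1.16 g, 69.4 d) | 0.0326 day⁻¹ |
| m | linear inversion of Λ(49.9) against 788 metastases | 5.19·10⁻⁵ (cell·day)⁻¹ |
| p_kill (rag2) | 1 − 209/Λ(69.4) with the shared m; grid-scan cross-check | 0.80 |

The colonization fit uses the count 788 (the value used for fitting, not the
cohort mean 789). The kill-probability fit returns both the closed form and
the best value on a 0.05-step simulated grid (100 replicates per value); the
two must agree within one grid step or the fit raises. The histology
whole-lung estimate is `mean count per section × number of sections × 0.8`
(the 20 % reduction corrects for deposits spanning adjacent sections; the
multiplicative reading of the correction is a modelling choice).

## Synthetic cohorts

`metasim.cohort` generates per-mouse observations by running one simulation
replicate per mouse: sacrifice day = horizon plus optional integer-day
normal jitter, observed weight = model weight × lognormal noise with mean 1
and configurable CV, deposit sizes from the final snapshot. Defaults are
noise-free; the recovery tests use CV 0.2 and 3-day jitter as conservative
values for xenograft cohorts. The generator reproduces the statistical
structure the calibration assumes (deterministic growth, Poisson counts); it
does **not** emulate inter-mouse growth-rate heterogeneity, engraftment
failures, or the detection limits of histological counting, so passing
recovery tests demonstrate correctness of the pipeline, not robustness to
biological heterogeneity.

Recovery deliberately mirrors the study's procedure — strain means in,
closed-form fits out. Noiseless cohorts return the truth to the printed
precision of each constant; `m` and `p_kill` retain the Poisson noise of
per-mouse counts (SE ≈ √(count/n_mice)), and the recovery-error test checks
that the median error shrinks with cohort size.

## Numerical choices and problem sizes

* Quadrature: `scipy.integrate.quad`, epsrel 10⁻⁹, failure raises.
* Cumulative-intensity grid: 16 385 Simpson nodes over the horizon
  (interpolation error ≪ 10⁻⁶ relative, pinned by test).
* Scenario summaries use 100 replicates, matching the study design; the
  mortality grid scans 21 probabilities × 100 replicates. The full default
  test suite runs in under a minute on one core.
* Ties in the event queue break FIFO; replicate seeds are `base + i`.
* Degenerate inputs (x ≥ b, negative times, kill probability outside [0,1],
  empty cohorts) raise `ValueError` before any event is processed.

## Limitations

Point estimates only — the calibration has no uncertainty quantification, as
the fits invert cohort means. Immune dynamics reduce to one fixed kill
probability; CTC blood concentrations are not predicted. The dormancy-duration
and trigger-size distribution families are modelling choices constrained only
by their means/SDs and ranges.
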