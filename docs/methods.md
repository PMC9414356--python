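# Methods

This note records the models implemented, the numerical choices behind
them, and what the synthetic-data generators do and do not emulate.

## Units and conventions

Internal units are kelvin, seconds and J/g.  The heating rate φ is carried
in K/min — the unit instruments and published kinetics tables use — and
converted to K/s wherever a time or a power is formed (e.g. the t =
(T−T0)/φ transform, enthalpy integration).  Heat flow is stored
exothermic-up; exo-down files are negated on load.  Rate constants of the
Avrami models dimensionally carry s⁻ⁿ; they are reported numerically with
the exponent alongside, matching the loose but universal "s⁻¹" labelling
of published tables.  Fixed constants: R = 8.314 J/(mol·K),
ε₀ = 8.8541878128×10⁻¹² F/m, and τ_α = 100 s as the dielectric
glass-transition criterion.

## DSC processing

*Glass transition.*  Linear baselines are fitted to the outer quarters of
the search window; the step must exceed 3× the local noise sd (residual sd
of the pre-baseline fit) or detection fails.  T_g is reported as the
half-ΔC_p midpoint — the dominant DSC convention — with onset/end from the
steepest-tangent construction.  ΔC_p is the baseline separation at T_g
divided by φ in K/s.

*Crystallization peak.*  The baseline is the straight line through the
window endpoints; a sigmoidal baseline is a known limitation, acceptable
because X(T) is invariant to affine offsets of the signal.  T_p is the
maximum of the baseline-subtracted signal with parabolic sub-grid
refinement.  Two distinct onsets are kept deliberately: T0/T∞ (bounds of
the X(T) integration) are the outermost 0.5%-of-peak-height crossings — a
relative threshold is noise-robust where no published definition exists —
while T_o (the Augis–Bennett onset) is the intersection of the steepest
ascending tangent with the baseline, which lands well inside the rising
flank, consistent with how published onsets sit relative to peaks.  The
enthalpy integrates the whole baseline-subtracted window rather than
[T0, T∞], because the 0.5% bounds would clip ~0.1% of a Gaussian-shaped
exotherm's tails.  Windows with two local maxima within 20% of each other
are rejected as ambiguous rather than silently picking one.

*Crystallinity.*  X(T) is the normalized cumulative trapezoid of the
clipped, baseline-subtracted exotherm; endpoints are pinned to 0 and 1 and
the curve clipped to [0,1].  The time axis is (T−T0)/φ with φ in K/s.

## Crystallization kinetics

Fits are unweighted least squares on X(t) directly (no error model is
available for X), restricted to X ∈ [0.03, 0.97] by default because the
tails are baseline-dominated.  Initialization comes from OLS on the exact
Avrami linearization ln(−ln(1−X)) = ln k + n ln t.  The two-stage model is
initialized from the single-stage fit (k₁=k₂=k̂, n=m=n̂) with a
multi-start over x ∈ {0.25, 0.5, 0.75}; bounds are 0<x<1, k>0,
0.5 ≤ n,m ≤ 8.  The second-stage exponent m is structurally
poorly identified on sigmoidal data; it is reported but flagged
(`m_unreliable`) when m > 6 or σ_m/m > 0.5, and never interpreted.
Parameter uncertainties come from the Gauss–Newton covariance at the
solution.  Model selection uses AICc (k = 2 vs 5 parameters) with a
two-unit band favouring the single-stage model; on noiseless single-stage
data both models are near-exact and the band resolves the tie toward
simplicity.

Note that a thermogram whose exotherm is Gaussian in temperature yields an
X(t) that is a normal CDF, which is *not* an Avrami curve; on such data
the selector legitimately prefers the more flexible two-stage model.
Recovery tests therefore plant Avrami truth directly when testing the
kinetics fits, and plant Gaussian peaks when testing peak location.

## Activation energy

Both linearizations are ordinary least squares on 1/T_p with natural
logarithms; E_cr = −slope·R, reported in kJ/mol with the regression
standard error (reports additionally echo the conventional 5% error bar).
The heating-rate unit affects only the intercept; tests pin the
unit-invariance of E_cr to 1e−10 relative.  Regressions on the packaged
published flutamide–PVP table give 122.5 (Kissinger) and 96.2 kJ/mol
(Augis–Bennett) for the neat drug.  The source study quotes ~200 and
~150 kJ/mol for the same system; those values are not reproducible from
its printed temperatures by either regression, suggesting the published
figure used a different onset/peak assignment than the table.  This
package surfaces the table-derived numbers and makes no attempt to tune
toward the quoted ones; the quoted values are used only as *planted*
truths in recovery tests (series constructed to satisfy each relation
exactly at 200/150 kJ/mol must refit to ≤0.01%).

## Dielectric relaxation

*HN fits* minimize residuals in log ε″ so the power-law wings — which span
decades and determine the shape exponents — carry weight comparable to the
peak.  σ_DC is fitted inside the model (log-parametrized with a floor that
maps to exactly zero when pinned).  τ_α follows from the HN parameters via
the standard peak-position formula; the identity ω_max·τ_α = 1 is verified
against dense-grid peak searches.

*KWW loss* is the one-sided Fourier sine transform of −dφ/dt with
φ = exp(−(t/τ)^β), computed by adaptive quadrature in two regimes: for
ωτ < 1 integration by parts gives ωτ·∫exp(−u^β)cos(ωτu)du, evaluated by
the finite-interval oscillatory (Clenshaw–Curtis) rule; for ωτ ≥ 1 the
singular head is transformed by v = u^β, the steep envelope region up to
u = 1 is summed decade-by-decade with the sine-weighted rule, and the
smooth tail uses the infinite-interval Fourier rule.  Against an
independent convergent-series evaluation the scheme is accurate to ≤2e−8
relative for β ≥ 0.25 over ωτ ∈ [1e−8, 1e8]; the KWW fit bounds β to
[0.25, 1] accordingly (α-peaks broader than β ≈ 0.3 do not occur in
practice).  KWW fitting assumes a conductivity-free or
conductivity-subtracted spectrum (subtract using the HN-fitted σ_DC),
since the stretched-exponential description addresses peak shape only.

*VFT* is fitted in ln τ with a multi-start over T₀ ∈ {0.7, 0.8, 0.9}·T_min
and requires ≥4 points spanning ≥2 decades.  Near-Arrhenius data drive T₀
to its floor; the fit is then flagged degenerate and only the product
D_T·T₀ (an activation temperature) is meaningful.  T_g solves τ_α(T_g) =
100 s in closed form: T_g = T₀(1 + D_T/ln(100/τ_VFT)).

*Crystallization onset.*  Crystallization removes relaxing dipoles, so Δε
(default; peak height also supported) drops when the drug crystallizes
during the BDS temperature ladder.  A linear trend is fitted to the
lower-temperature half of the series; the onset is the first temperature
persistently below 90% of the trend.  The threshold is a configurable
design choice — the phenomenon is only described qualitatively in the
literature — and the persistence clause guards against single noisy
points.  With a 2 K ladder the detected onset lags the true decay start by
up to (0.1/slope) K; tests account for this bias explicitly.

## Synthetic data

Generators are pure functions of (truth, seed) and bit-identical on
repeat.  Thermograms are a linear baseline + ΔC_p sigmoid step + Gaussian
exotherm (time-domain area = ΔH_c) − Gaussian endotherm + i.i.d. Gaussian
noise.  Defaults ΔC_p = 0.35 J/(g·K) and ΔH_c = 50 J/g are typical
small-molecule-glass magnitudes (no published values exist for this
system); heating rates default to the 5–30 K/min range of the study.
Heating-rate series solve ln(φ/T_p²) = C_K − E_cr/(R·T_p) for T_p by
bracketed root-finding polished to 1e−10 K.  Loss spectra use the same HN
and KWW evaluators as the analysis side, with the α amplitude decaying
linearly in T above a planted onset (the simplest detectable structure
for a qualitative phenomenon) and the default two-stage exponent m = 4
(withheld as unreliable in the source study, so the generator must fix
one).

What the generators do *not* emulate: instrument drift and curved
baselines, asymmetric exotherms, overlapping thermal events, electrode
polarization and secondary (β/γ) relaxations, moisture effects.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated forward models, not robustness to every artifact of real
instrument data.

## Problem sizes

Recovery tests use 150–300-point crystallinity curves, 40–60-point
spectra, 8-point τ_α tables and 100-replicate Monte-Carlo checks — sizes
chosen to match typical instrument exports while keeping the full suite
fast on a single CPU.
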