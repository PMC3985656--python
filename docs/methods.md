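# Methods

This note records the models implemented in `g4ionx`, the assumptions behind
them, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that affect
results.

## The three-state stepwise cation-exchange model

An intramolecular three-tetrad G-quadruplex holds two inner-channel cations.
Titrating K⁺ into the Na⁺-folded form is modelled as two sequential
replacement equilibria

    a + K⁺  ⇌  b        (K₁)
    b + K⁺  ⇌  c        (K₂)

where *a* is the di-Na⁺ form, *b* the mixed Na⁺·K⁺ intermediate and *c* the
di-K⁺ form. At free K⁺ concentration *x* the species fractions are

    fa = 1/D,   fb = K₁x/D,   fc = K₁K₂x²/D,   D = 1 + K₁x + K₁K₂x²

which conserve fa+fb+fc = 1 for all x ≥ 0, make fa strictly decreasing and
fc strictly increasing, and put the intermediate maximum at x = 1/√(K₁K₂).
The model assumes free ≈ total added K⁺ (K in the tens per molar regime and
DNA in the 0.1–1 mM range, so ligand depletion is negligible) and ignores
Na⁺-concentration dependence: the Na⁺ background is constant during the
titration and its effect is absorbed into the apparent constants.

**Observables.** The Na⁺-form imino intensity of a residue tracks fa and the
K⁺-form intensity tracks fc, both on a normalized fractional scale. The
intermediate is not directly observed; `intermediate_population` recovers it
by mass balance, fb = 1 − fa − fc, clipping to [0, 1] with the clip count
reported rather than silently.

**Fitting.** `fit_exchange` minimizes the pooled squared residuals of fa
against the Na⁺-form series and fc against the K⁺-form series over
(log₁₀K₁, log₁₀K₂), with multi-start initialization on the grid
K ∈ {0.1, 1, 10, 100, 1000}² and bounds 10⁻³–10⁴ per molar. Sums of binding
terms are nearly bilinear in log space and single starts stall; the grid is
coarse but covers every identifiable regime for a 0–150 mM titration.
Standard errors come from the Gauss–Newton covariance at the optimum, mapped
from log space by the delta method. Estimates within 0.05 log₁₀ units of a
bound are flagged `K*_at_bound` (the TRF optimizer stops near, not on,
bounds for unidentified parameters). A `separate` mode fits K₁ from the
disappearance curve alone and then K₂ from the appearance curve given K₁,
mirroring fitting the two curves one at a time; on clean data it agrees with
the joint fit.

**Units.** Concentrations are stored in the series' declared unit (mM by
default) and converted to molar for fitting, so K₁, K₂ are reported per
molar. With K₁ ≈ 60 M⁻¹ the first transition midpoint sits near 17 mM,
consistent with a titration that completes by 150 mM.

## Intensity normalization

Raw imino intensities are put on the fractional scale by anchoring the
measured zero-titrant point and a *fitted* plateau (one-site binding profile
with the linear subproblem solved exactly and a bounded 1-D search over the
midpoint), rather than the last measured point, so an unfinished titration
does not bias the scale. Disappearing signals map 1 → 0, appearing signals
0 → 1. The model family is closed under affine transforms of the intensity
axis, which makes normalization idempotent and invariant to detector
scaling. Peak height (not integral) is assumed throughout; the anchoring
choice matters only when the plateau is poorly sampled. Note the published
K⁺-form appearance curves need not reach their plateau inside the titration
window — the generator emits true fractions, and `fit_exchange` therefore
expects already-fractional series and never renormalizes.

## Exponential kinetics

HDX decays, hybridization-trap decays and real-time CD conversion traces are
fitted with offset exponentials:

    mono:  S(t) = offset + A·exp(−t/τ)
    bi:    S(t) = offset + A·(f₁·exp(−t/τ₁) + f₂·exp(−t/τ₂)),  τ₁ < τ₂

The sign of A is free, so rises and decays are handled identically; the
source text does not state the fitted equation and these are the standard
forms. Points before the declared dead time are excluded, not extrapolated —
no information exists there. Amplitudes are reported as percentages of the
total amplitude. R² is computed on the fitted range.

The bi-exponential fit uses variable projection: for each (τ₁, τ₂) the
offset and both amplitudes are solved by linear least squares, and the
nonlinear search runs over (log τ₁, log τ₂) from a 4×4 grid of spans and
ratios. This is robust against the local-minimum structure of sums of
exponentials; agreement with an exhaustive 100×100 log-grid oracle is part
of the test suite. Fits with τ₂/τ₁ < 1.5 or a vanishing/negative amplitude
are flagged degenerate — the data support only one phase.

Condition summaries are arithmetic means with sample SD over per-residue τ;
fold differences between conditions propagate those SDs to first order
(σ_ratio/ratio = √((σ_a/μ_a)² + (σ_b/μ_b)²)), validated against Monte Carlo
in the tests.

A note on precision: with a free baseline, 50 uniformly spaced points and 2%
noise, the mono-exponential τ carries ≈2.5% relative error, so a 5% bound is
only ~2σ. The recovery property test therefore samples log-spaced time
points — the standard design for exponential kinetics, concentrating points
where the signal is informative about τ.

## NOE buildup and r⁻⁶ distance calibration

In the initial-rate (isolated spin pair) regime, NOESY cross-peak intensity
grows linearly with mixing time at a rate ∝ r⁻⁶. Distances are calibrated
against the thymine H6–CH3 pair at its fixed 2.99 Å separation:

    r = 2.99 Å · (slope_ref / slope)^(1/6)

The initial slope is the origin-constrained regression Σ tI / Σ t² over the
standard 50/100/150/200 ms series. Because cross-relaxation saturates at
long mixing times, a curvature guard drops trailing points while the
relative residual of the origin line exceeds 5% (down to two points); for a
buildup saturating with a 300 ms time constant this keeps the estimate
within 15% of the true initial rate. A single mixing time (the D₂O
nonexchangeable-proton experiment is recorded at 200 ms only) yields I/t
with a `single_point` flag. The 1/6 power makes distances forgiving:
calibration is exact under any global intensity rescaling, and a 64-fold
intensity ratio corresponds exactly to a factor of two in distance.

Group comparisons between cation conditions use Welch's two-sample t-test
(two-sided, α = 0.05); Welch rather than Student because the published
group SDs differ by up to 3-fold and equal variance cannot be assumed.

No spin-diffusion (full relaxation matrix) correction is applied; the
curvature guard and the mixed-sample control condition are the only
protections, which is a known limitation for long distances.

## Topology inference

The fold is reconstructed from three layers of evidence:

1. **Tetrads.** Guanine imino(H1) → aromatic(H8) NOEs define directed edges;
   a tetrad is a directed 4-cycle whose members lie in four distinct
   G-tracts (enumerated with networkx, checked against brute-force
   enumeration in the tests). Peaks below 10% of the median tetrad-peak
   intensity are excluded first, so minor-conformation signals cannot seed
   spurious cycles.
2. **Glycosidic conformations.** Intra-residue H1′–H8 distances below 3.3 Å
   are called syn, above anti. The threshold is the midpoint between the
   canonical syn (≈2.4–2.6 Å) and anti (≈3.6–3.8 Å) separations, so calls
   are stable over a wide threshold sweep; residues without an intra-residue
   peak are reported uncalled rather than failing the run.
3. **Orientations.** Within one tetrad, guanines on parallel strands share
   the glycosidic conformation and an antiparallel strand carries the
   opposite one. Each tetrad contributes same/opposite parity constraints
   between tracts; the constraint graph is 2-colored, contradictions raise
   with the conflicting tract pairs listed, and the majority color is
   labelled "up" (a 2–2 tie takes the 5′-most tract as up).

**Layers.** Tetrads are ordered along the stack by the tract position of
their first-G-tract member — each tetrad contains exactly one guanine from
the first tract, so this rank never ties (a mean rank over all four members
ties exactly for alternating folds). Inter-tetrad H1–H1 stacking NOEs, when
present, independently identify the central tetrad and any contradiction
raises.

**Sense.** Each cycle traverses the tetrad square in one of two rotational
directions. Absolute chirality is not derivable from connectivity, so the
majority direction is labelled "clockwise" by convention; on the Tel23
evidence this reproduces the published anticlockwise top / clockwise middle
and bottom labels.

**Loops and label.** With the square arrangement taken from the detected
cycles, a loop joining parallel adjacent tracts is double-chain-reversal,
antiparallel adjacent lateral, antiparallel diagonal diagonal. The final
decision table over (number of antiparallel tracts, loop sequence) assigns:
propeller (0 down, three reversal loops); hybrid-I vs hybrid-II (one down;
reversal loop first vs last); basket ([lateral, diagonal, lateral]), chair
(all lateral) or (2+2) (a reversal loop present) for two down. Anything else
is labelled `unclassified` with diagnostic notes — the rule set is a
formalization of expert practice and folds outside the five canonical
fixtures are not guaranteed classifiable.

## CD melting

The generator and the analysis both treat the 295 nm melt as a two-state
transition between linear baselines. `extract_tm` fits lines to the
terminal 10% temperature windows, subtracts the folded baseline, smooths
with a Savitzky–Golay filter (5 °C window, quadratic) and reads Tm as the
extremum of the first derivative, refined by parabolic interpolation around
the peak — the derivative-peak reading of "first derivative zero points"
(the peak of dθ/dT is the zero of the second derivative). A transition is
required to exceed 3× the derivative noise estimated in the baseline
windows; strictly linear curves raise `NoTransitionError`. `fit_two_state`
fits the full sigmoid-plus-baselines model as an independent cross-check;
the two methods agree within 0.3 °C on clean curves. Tm is invariant under
affine transforms of the ellipticity axis and stable under grid refinement.

## Synthetic data: what it emulates, and what it does not

Generator defaults are the study conditions: G22 constants K₁ = 59.7,
K₂ = 2.7 M⁻¹ on a 0–150 mM grid in 5 mM steps; CD conversion τ = 80/930 s
with an 89% fast phase sampled every 5 s to 3600 s; HDX means 14 min (Na⁺,
sampled every 5 min to 120 min) and 136 min (simultaneous Na⁺/K⁺, every
10 min to 600 min) for four central-tetrad protons; hybridization 127 min
(simultaneous) with the Watson–Crick rise sharing the decay constant;
melting midpoints 59.3/68.9 °C on 25–95 °C at 0.5 °C with a 3 °C logistic
width (the ~12–15 °C transition breadth typical of quadruplex CD melts) and
gently sloping baselines; NOESY intensities obeying the r⁻⁶ law exactly
with linear buildup over 50–200 ms, distance classes drawn at the published
means/SDs (n = 12 per class), and connectivity patterns for five canonical
folds built on the Tel23 scaffold. Noise, where enabled, is i.i.d. Gaussian
at a default 2% of amplitude (the real noise magnitudes are unreported).

The generators do **not** emulate: chemical-shift positions or peak overlap
(assignment is taken as given); spin diffusion or saturating buildup curves
(intensities are exactly linear in mixing time unless a saturating fixture
is constructed explicitly); correlated or heteroscedastic noise; minor
conformations beyond a simple intensity floor; ligand depletion or activity
corrections in titrations; non-two-state melting. Passing tests therefore
demonstrate correctness of the estimators on data satisfying the models'
assumptions, not robustness to every pathology of real spectra.

The HDX presets give every trace the condition-mean time constant; the
published ±5/±28 min are across-residue scatter and can be enabled through
the config, but default to zero so that noiseless runs reproduce the
printed condition means exactly.

## Degenerate inputs and tie-breaks

Constant kinetic traces and τ beyond 10⁴× the sampled span return a
`no_decay` flag instead of a number; constant titration series raise a
degenerate-series error; all-zero buildups return slope 0 with a flag;
glycosidic calls missing for a tetrad guanine block orientation inference
with the residues named; tetrad cycles that do not share one square
arrangement, contradictory parity constraints, and stacking NOEs that
contradict the layer order all raise `TopologyError` rather than guessing.

## Problem sizes

Default problem sizes (31-point titrations, 25–121-point traces, 141-point
melting curves, ≤ 200-replicate property studies, 200² brute-force oracle
grids) were chosen so every analysis is comfortably identifiable while the
full suite runs in well under a minute per module on one CPU.
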