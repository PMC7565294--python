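# Methods

This note documents the models, conventions, defaults and known limits of
`tddc`. Units are SI internally (s, m, T, m²/s); tables and configs use
ms/μm where stated.

## Forward model

The stimulated-echo attenuation of a multi-pool sample is

    E/E0 = exp(-2τ/T2)·exp(-t_m/T1) · Σᵢ pᵢ·exp(-b·Dᵢ) + y0,
    b = (γGτ)²(t_m + 2τ/3).

* γ defaults to the CODATA proton value 2.6752×10⁸ rad s⁻¹ T⁻¹ and is
  overridable; with G = 24 T/m and the default grids this reproduces the
  instrument's printed b-range (0–5.97×10¹¹ s m⁻²) within 1%.
* Normalization: experimental data are normalized to the echo at
  (τ_min, t_m_min). `forward_attenuation(..., reference_normalized=True)`
  divides by the model value at that reference point; the generator uses the
  same convention, with the reference evaluated at the *earliest* mixing
  time's pool fractions, as an instrument would.
* Molar fractions are **not** constrained to sum to one in general: the
  apparent fraction of each pool decays with mixing time (water exchange),
  so only the equilibrium fractions of a fully detected sample form a
  simplex. `fit_attenuation` offers a `unit_sum` simplex mode for static
  two-pool fits and a free-amplitude mode (default) whose fitted amplitudes
  track the decaying fractions; the free amplitudes also absorb the ~1.7%
  scale of the global reference normalization, which cancels in every
  derived quantity except a uniform offset in p̂ (irrelevant to lifetimes).

## Per-mixing-time fitting

Model classes: model 0 (two pools, full range), model 0B (two pools on a
b-window), model 1 (two pools + intercept y0), model 2 (three pools). All are
bounded nonlinear least squares (`scipy.optimize.least_squares`) on
parameters (log₁₀Dᵢ, pᵢ, y0) with bounds D ∈ [10⁻¹³, 10⁻⁸] m²/s, p ∈ [0, 1],
y0 ∈ [0, 0.5]; residuals are unweighted on E/E0 (the noise model is additive
on the normalized magnitude). Initialisation is a deterministic log-linear
peeling of the curve from its large-b tail; no random restarts are used, and
matched-class noiseless curves are recovered to machine precision.
Information criteria use the Gaussian least-squares forms
AIC = N·ln(RSS/N) + 2k and BIC = N·ln(RSS/N) + k·ln N (AICc behind a flag);
a fitted coefficient pinned at an optimizer bound is flagged (`at_bound`)
and excluded from downstream traces.

**Window selection.** For mixing times where the extracellular pool is
partially extinguished, the fitted window starts at the first τ index where
that pool's simulated single-pool attenuation falls below ε (default 0.02,
the smallest signal drop distinguishable at the instrument's SNR). On the
default protocol this excludes 2–4 leading points.

**Interval strategy** (`interval_strategy_series`): short mixing times
(≤ 2 ms) are fitted with model 2 on the full range — first freely, then with
D1 frozen at the median of the free fits (freezing one parameter is the
standard cure when the points-per-parameter ratio is low); longer mixing
times use model 0B on the ε-window with the physical bound D ≤ D1 (both
remaining pools are slower than the excluded extracellular water). Pool
identity is maintained by descending D: ranks map to compartments 1–3 at
short times and 2–3 on the windows. If a windowed fit parks a pool at a
bound, the two-pool split failed there and both pools are dropped at that
mixing time, leaving a gap.

## TDDC analysis

* **Region I:** D(t) = D0·[1 − 4/(3W√π)·(S/V)·√(D0·t)], linear in √t and
  solved in closed form. W defaults to 3 (the standard 4/(9√π) prefactor);
  note that fitting W = 3 to a 2D simulated disk yields S/V ≈ 3/R, i.e. the
  sphere convention R = 3/(S/V) still recovers the disk radius.
* **Region II:** log-log OLS of D = A·tᵏ. The pipeline default pins k = −1
  (the impermeable-confinement law; the A → R conversion
  R = √(A·d(2+d)) is only defined at that exponent), with a free-k mode to
  quantify permeable-boundary deviations.
* **Crossover:** the branches' meeting time is the first bracketed root of
  D_Mitra − D_ES (bisection, 10⁻⁶ relative). Because the 1/t branch diverges
  at t → 0 the curves may cross twice; `prefer="descending"` selects the
  crossing where the Mitra branch descends through the 1/t law — the switch
  that keeps a short-time-then-localization composite monotone. Without any
  root the closest-approach grid point is returned, flagged inexact;
  identical curves return the leftmost point, flagged degenerate.
* **Lifetimes:** p(t) = Σⱼ p0ⱼ·exp(−t/τⱼ) with one or two components
  (reported by ascending τ); a decay below 0.1% over the observed span is
  reported as τ = ∞ with p0 the mean. For bi-exponential organelle
  fractions the *slower* component enters P_d = R/(3τ) — it reproduces the
  vacuolar permeability arithmetic, whereas the fast component reflects
  nuclear water that joins the cytoplasm pool within ~1 ms.
* **Analysis regions** are explicit configuration. The yeast defaults
  (`default_yeast_plan`): compartment 1 is unrestricted, D0 averaged over
  0.2–1 ms; compartment 2: region I 0.2–5 ms, region II 8–40 ms;
  compartment 3: region I 0.2–2 ms, region II 2.8–40 ms. The region-II
  windows start beyond each compartment's branch transition (≈6.9 ms and
  ≈2.6 ms for the default truth) so the fixed-exponent fit sits on the 1/t
  branch.

## Synthetic truth and generator

The default three-pool yeast truth carries the study's fitted parameter set:

| pool | D0 (10⁻⁹ m²/s) | S/V (μm⁻¹) | R (μm) | p0 | τ (s) |
|------|---------------|-----------|--------|--------|-------|
| 1 extracellular | 1.64 | — | — | 0.2188 | 0.201 |
| 2 cytoplasm | 0.692 | 1.28 | 2.252 | 0.6985 | 0.390 |
| 3 organelles | 0.095 | 7.22 | 0.277 | 0.070 | 0.039 |

Each restricted pool's D(t_m) follows the Mitra branch at short times and the
localization branch at long times. For pool 3 the branches cross (the
descending root, ≈2.6 ms) and the switch is exact; for pool 2 the printed
parameters give branches that never intersect (closest approach ≈6.9 ms,
ratio ≈1.19), so a hard switch would jump discontinuously — the truth
bridges 5–8 ms log-log-linearly instead, which keeps D(t_m) continuous and
non-increasing while remaining exactly on each branch inside the analysis
regions. Fractions decay mono-exponentially with the lifetimes above.

The generator evaluates the forward model on the default protocol (20 τ
linearly spaced 0.02–0.6 ms; 15 t_m log-spaced 0.2–40 ms — the instrument
publishes only the endpoints and count, and log spacing matches how such
TDDC series are sampled and displayed; T2 = 29.2 ms, T1 = 215 ms), adds
additive zero-mean Gaussian noise (default σ = 0.005, representative of
128-scan magnitude data at high SNR; a Rician treatment would only matter at
SNR of order one) and clips at 10⁻⁶. What it does **not** emulate: relaxation
dispersity (single scalar T1/T2), exchange between pools beyond the
first-order fraction decay, Rician noise floors, and τ-dependent diffusion
during encoding (the t_m ≫ τ idealisation) — recovery results on synthetic
data are therefore a best case with respect to those effects.

## Identifiability limits

At σ = 0.005 on this protocol the slow pool's single-curve coefficient is
weakly identified: its amplitude is ~0.07 and it attenuates by at most ~⅓
across the b-range, giving Fisher-information (Cramér–Rao) minimum relative
SEs of ≈1.9, 1.3, 0.9, 0.6, 0.4, 0.3, 0.3 at the seven mixing times ≤ 2 ms.
Propagated optimally into the short-time intercept this bounds the relative
SE of D03 at ≈0.38 — no per-mixing-time estimator can do better, and the
implemented pipeline sits essentially at this bound (median |error| ≈ 0.3,
signed median ≈ +0.04). D02 (≈7%), R2 (≈0.6%) and R3 (≈6%) are by contrast
comfortably determined; likewise τ2 ≫ t_m,max makes single-run cytoplasmic
lifetimes (and hence P_d2) scatter strongly. Report medians over seeds, or
use the per-fit standard errors.

## Random-walk simulator

2D, fixed-length steps σ = √(4·D0·t_s) (t_s = 5 μs default) in uniform
random directions; boundaries are completely reflecting and non-exchanging,
implemented as specular reflection of the crossing segment (iterated for
multi-boundary regions, with a radial clamp as a last resort — exercised
only at grazing incidence). The default geometry is one cell (R = 2.35 μm,
wall 0.13 μm) in a 10 μm box with a nucleus (1 μm), vacuole (0.5 μm) and
mitochondrion (0.25 μm) on a fixed disjoint layout; per-region D0 follow the
literature values carried in the geometry table. The exterior is simulated
unbounded.

Seeding is uniform by default. Displacements are recorded relative to each
walker's start, so in a bounded region the uniform-start MSD saturates at
*twice* the stationary second moment; seeding at the region center
(`seed_mode="center"`) makes the plateau equal the stationary moment itself
(radial R²/2, per-axis R²/4 in a disk), which is the convention under which
the localization-regime size inversion and the ⟨Z²⟩ = 2R²/(2+d) relation
hold. Validation and size-recovery runs therefore use center seeding;
short-time (Mitra) runs use uniform seeding, where the boundary layer of the
stationary ensemble produces the √t fall-off. Free diffusion and plateau
statistics at 3000–5000 walkers carry ~1–2% standard errors; the walk is
bit-reproducible for a given seed.

## Geometry theory

Sphere/shell volumes from literature sizes and counts (the "size" column of
the source anatomy is a radius — the only reading consistent with every
printed volume, e.g. 4.19 μm³ = (4/3)π·1³ for the nucleus, even though prose
sometimes quotes vacuole diameters). The intracellular reference volume is
the sphere of radius R_cell − wall thickness, giving 93.9–104 μm³ across the
wall-thickness range 0.0792–0.180 μm. Expected compartment fractions split
1 − p01 proportionally to summed volume fractions under an explicit
assignment map (short-time map: nucleus + wall + mitochondria → slow
compartment). The exact weighting behind the source's quoted weighted mean
size (0.422 μm) and expected fractions (0.69/0.11) is not recoverable from
the text; `weighted_mean_size` and `expected_molar_fractions` log their
inputs and make no claim to reproduce those two numbers.

## Pipeline and formats

Attenuation tables are CSV with unit-bearing headers
(`tm_ms, tau_ms, b_per_m2_s, E_over_E0`, written at 17 significant digits so
write→read round trips are value-exact) plus a YAML sidecar with protocol,
truth (for synthetic data) and seed. `run_pipeline` chains
synth → fit → tddc → theory, persists per-stage outputs and a run log with
seed, config hash and timings, aborts on the failing stage by name, and is
byte-reproducible for a given config and seed. Problem sizes throughout
(100-seed recovery studies, 5000-walker/8000-step simulations) run in
seconds to a few minutes on one core.
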