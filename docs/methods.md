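# Methods

This note records the models implemented in `sfekin`, the defaults they
ship with, and the reasoning behind the choices that were genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Response-surface analysis

### Model and basis

The full second-order surface in k factors is fitted by ordinary least
squares on the 1 + 2k + k(k−1)/2 term basis {1, xᵢ, xᵢ², xᵢxⱼ}. Two
regressor bases are available:

- **natural units** (default): pressure in bar, temperature in °C,
  particle size in Tyler mesh, exactly as tabulated;
- **coded units**: each declared level mapped onto −1/0/+1.

For evenly spaced levels the two bases span the same model space. They
do **not** when a factor's levels are uneven — here the particle-size
classes 42/60/150 mesh — because the level map is then a nonlinear
reparameterization and products like T·G_coded involve T·G² terms absent
from the natural basis. The embedded study tabulates its quadratic in
uncoded variables and its ANOVA is reproduced only on the natural basis,
so that is the default throughout.

### ANOVA

The decomposition follows the Minitab table shape: sequential (Type I)
sums of squares in a stated entry order (default for the embedded
Box–Behnken table: T, P, G, then squares, then pairwise interactions in
the induced order), adjusted (Type III) sums of squares per term and per
group (Linear / Square / Interaction), F = adjusted MS over residual MS
with upper-tail F p-values, and the residual split into lack-of-fit and
pure error using replicate runs (pure-error df = Σ(nᵢ−1) over replicate
groups). Without replicates the lack-of-fit rows are omitted with a
warning. Sums of squares are computed on the w/w **fraction** scale by
default — the scale on which the study's printed SS magnitudes (e.g. a
pure-error SS of ~7·10⁻⁶) arise — while fitted surfaces are reported on
the percent scale; F ratios, p-values and R² are invariant to that
choice, and rescaling multiplies every coefficient by exactly 100.
Rows whose adjusted MS is zero report no F rather than infinity.
Responses missing for a run drop that run with a warning; there is no
imputation.

### Constrained maximization

The maximum of a quadratic over a box is found exactly: every face of
the box (3ᵏ sign patterns of {at-lower, at-upper, free}) restricts the
quadratic to a lower-dimensional one whose stationary point is a linear
solve; all in-box stationary candidates plus the vertices are compared.
Faces with singular Hessian restrictions are skipped — their maxima lie
on sub-faces that are enumerated anyway. Ties within 10⁻⁹ (relative) are
all reported, ordered so the lowest value of the first factor (pressure,
for the embedded study) comes first, matching the practical preference
for lower operating pressure. Infinite bounds are rejected.

### Two-level factorial

The 2² factorial model fits {1, A, B, AB} on coded corners; an optional
center-point indicator keeps the intercept at the corner mean and
estimates curvature as mean(center) − mean(corners). Classical effects
are twice the coded coefficients.

### Published equations

The printed regression equations of the source study are shipped in
`sfekin._reference` for display only. They are not reproducible from the
printed (2-decimal) responses — and the uncoded quadratic's T·G
coefficient has the opposite sign from the refit while its value at the
reported optimum does not match the reported prediction — so every
computation in this package uses the refit of the embedded tables. The
consequence is visible and accepted: F ratios agree with the printed
ANOVA to ~1 % rather than to the last printed digit, because the
original analysis ran on unrounded data.

## Kinetic models

All kinetics are strict SI internally; constructors accept bar, °C,
mesh, mm, g and minutes. The mesh→mm map defaults to the sieve classes
used in the study (42→0.423, 60→0.303, 150→0.125 mm) and is
configurable.

### Crank (sphere diffusion)

M_t/M_∞ = 1 − (6/π²) Σ_{n≥1} n⁻² exp(−Dn²π²t/r²). The series is summed
adaptively — terms are added until the next term falls below 10⁻¹²,
capped at 10⁵ terms. No short-time approximation is substituted; for
Fourier numbers below 10⁻⁴ a warning notes the slow convergence. The
single parameter is the internal diffusivity D (m²·s⁻¹) at a given
particle radius.

### Sovová (broken and intact cells)

Milling breaks part of the cell structure: a fraction x₀−x_k of the
solute loading is directly accessible (extraction limited by the fluid
film, fast-period parameter Z), the rest (x_k) sits in intact cells
(limited by solid diffusion, slow-period parameter W). In the specific
solvent consumption q the yield has three periods separated at
q_m = (x₀−x_k)/(y_r Z) and
q_n = q_m + W⁻¹ ln[(x_k + (x₀−x_k)e^{Wx₀/y_r})/x₀], with the
moving-boundary coordinate z_w entering the middle period. The curve is
continuous at both transitions (asserted to 10⁻⁹·x₀ over 10³ random
parameter draws) and saturates at x₀. Note that x_k → 0 does *not*
collapse q_n onto q_m: it leaves a depletion period of length x₀/y_r
during which the accessible solute empties from bed inlet to outlet,
with complete exhaustion (e = x₀) exactly at q_n. The evaluator is
written in log-stable form (shifted exponentials, `logaddexp`) so the
extreme parameter regions an optimizer visits return finite values; the
z_w logarithm raises an error where its argument is non-positive
(outside the model's validity) rather than clamping. Boundary
membership is left-closed. Fitted (Z, W) convert to phase coefficients
via k_f = Z·q̇(1−ε)ρ_s/(a₀ρ) and k_s = W·q̇(1−ε)/a₀ when the bed is
specified.

### Reverchon (plug flow + linear equilibrium)

With negligible axial dispersion and constant solvent density/flow, the
bed obeys (1/τ)∂c/∂h + ∂c/∂t + φ∂q/∂t = 0 and
∂q/∂t = −(q − Kc)/t_i on the nondimensional axial coordinate h ∈ [0,1],
where τ = εV/V̇ is the interstitial residence time and
φ = (1−ε)ρ_s/ε the solid mass per fluid volume. This grouping means only
(τ, t_i, K, q₀, φ) enter the solver, which removes the dimensional
bookkeeping ambiguities of the original formulation without changing
the model. Clean solvent enters (c(0,t)=0); the bed starts uniformly
loaded. The cumulative yield is the integral of the outlet flux,
tracked as an auxiliary ODE state so it inherits the integrator's
accuracy, and the system — linear and time-invariant — is solved by the
method of lines: first-order upwind on N = 50 cells (LSODA, rtol 10⁻⁸,
atol 10⁻¹², analytic constant Jacobian). Solute mass closes to 10⁻⁶
relative by construction of the upwind stencil.

Grid resolution: the semi-discretization converges under cell doubling
(50→100) to ≤10⁻⁴ relative in the **kinetics-limited regime** τ ≪ t_i —
the regime in which the model's characteristic limits are defined and in
which the convergence test runs (τ = t_i/1000). When the residence time
is comparable to t_i (as for the documented pilot-bed defaults, τ ≈
1800 s), the advective breakthrough transient dominates early samples
and first-order upwind resolves the curve to ~0.5 % there; users who
need tighter early-time accuracy in that regime should raise `n_cells`.

Derived coefficients: D_i = μl²/t_i with μ = 3/5 and l = r/3 for
spheres, and k_TM = (1−ε)V/(A_p·t_i).

### Default bed configuration

`BedProperties.default()` describes the 500 mL pilot extractor of the
study: 80 g of milled flowers (≈78 g insoluble), 800 g·h⁻¹ CO₂, CO₂
density ≈900 kg·m⁻³ at the optimized condition, plant-matter density
1400 kg·m⁻³ (hence porosity 0.886 from the 160 kg·m⁻³ bulk density), and
a specific interfacial area taken as the sphere surface-to-volume ratio
6/d of the 0.423 mm particles. With these defaults the fitted slow- and
fast-period parameters of the study map to phase coefficients of order
10⁻⁹ m·s⁻¹, the magnitude its authors report. These are documented
estimates, not measurements; every conversion takes an explicit
`BedProperties` for beds that differ.

## Parameter estimation

Unweighted least squares by default (the study states no weights); an
optional relative-error weighting flag exists for curves whose early
samples matter most. Minimization is Nelder–Mead with the
classical coefficients (reflection 1, expansion 2, contraction 0.5,
shrink 0.5). Positivity is enforced by searching log-parameters; the
Sovová constraint x_k ≤ x₀ by a logit of x_k/x₀. Convergence: simplex
spread below 10⁻¹⁰ (log-space, hence ~relative) and SSE spread below
10⁻¹⁴, capped at 10⁴ iterations; the Reverchon fit relaxes these to
10⁻⁶/10⁻¹²/10³ since each evaluation is a PDE solve and the remaining
error is far below fit uncertainty. Non-finite model evaluations score
+∞ and the search continues.

Initial guesses are data-driven: Crank's D from the 63.2 % crossing time
(D ≈ r²/(π²t₆₃)); Sovová's y_r·Z product from the initial slope and the
departure-from-linearity point, split by a 1-D root solve, with
x_k = x₀/2; Reverchon's t_i from t₆₃ with K = 10⁻³. A deterministic
multi-start (default 8; 3 for Reverchon) jitters the log-parameters with
a seeded Gaussian; the best start is reported and the same seed
reproduces the result bit-identically. x₀ is fixed at the curve's
asymptote estimate (median of the last three samples) unless supplied; a
curve still rising more than 5 % per step at its end flags the result as
weakly identified.

Identifiability: in the small-Z regime of the embedded example
(Z ≈ 0.05) the first-period slope constrains only the product
y_r(1−e^{−Z}) ≈ y_r·Z, so y_r and Z are individually ill-determined
under noise — errors along this ridge are large even though the fitted
curve, the product, and x_k/W remain stable, and they shrink as the
noise does. This is a property of the model in that regime, not of the
optimizer.

## Synthetic data

The generator emulates what the estimation stage must survive in a real
SFE campaign: monotone saturating curves over a 6-hour horizon sampled
24 times from 10 minutes onward with power-law early bias, ~2 %
multiplicative replicate-level noise (the study ran triplicates but
prints no scatter; 2 % is a typical gravimetric repeatability), values
clipped to the physical range but never monotonized, and design
responses equal to a known quadratic plus independent run-level noise
(replicated centers draw independently). Everything is seeded and
bit-reproducible, and ground truth travels with every simulated object.

What passing the recovery tests shows — and does not. The generators
share the forward models with the fitters, so recovery tests validate
the estimation machinery (objective, transforms, multi-start, seeding),
not the models' adequacy for real flowers; real curves carry
time-correlated sampling error, flow fluctuations and co-extraction of
non-target solutes that the noise model does not emulate. The embedded
design tables, by contrast, are real measurements and anchor the
response-surface half end to end.

## Known limitations

- No confidence intervals on kinetic parameters (a bootstrap hook exists
  in the report schema, unimplemented); no model-selection criteria; no
  simultaneous multi-curve fitting.
- Design handling covers 2-level factorials with centers and the
  3-factor Box–Behnken; no general design generation, desirability
  functions or mixture designs.
- The Reverchon solver assumes isothermal beds, constant solvent density
  and no axial dispersion, as the model prescribes.
- S/F (solvent-to-feed) bookkeeping is out of scope; the study's own
  figures for it are mutually inconsistent.
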