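# Methods

## Baseline model

The package is organised around a two-species Lotka-Volterra competition
model of a pathogen $P(t)$ and a commensal $C(t)$ under antibiotic
perturbation:

$$\dot P = r_p P (1 - (P + \alpha_{pc} C)/k_p) - x A P, \qquad
  \dot C = r_c C (1 - (C + \alpha_{cp} P)/k_c) - x f A C.$$

Assumptions worth making explicit:

* **Density-independent antibiotic loss.** Inhibition (bactericidal or
  bacteriostatic alike) enters as an extra linear loss term, the standard
  pharmacodynamic abstraction. Because the loss is linear, the perturbed
  system is again a classic Lotka-Volterra model with effective growth rates
  $r_p - xA$, $r_c - xfA$ and proportionally shrunken carrying capacities.
* **Weak interference, $|\alpha_{ij}| < 1$.** This excludes the bistable
  regime of strong interference competition, so for any valid parameter set
  the interior attractor reachable from interior initial conditions is
  unique. Parameter validation enforces the bound; `classify_outcome` keeps
  a defensive multistability branch anyway.
* **Rescaled densities.** Carrying capacities are expressed relative to a
  unit-density default pathogen; values outside $(0, 2]$ are accepted with a
  warning rather than rejected, since the dimensionless gradient conditions
  do not depend on the scale.

### Parameters

| name | meaning | units | default |
|---|---|---|---|
| `r_p`, `r_c` | maximal growth rates | 1/time | 0.5 |
| `k_p`, `k_c` | carrying capacities | rescaled density | 1.0 |
| `alpha_pc` | effect of commensal on pathogen (+ inhibits) | — | 0.8 |
| `alpha_cp` | effect of pathogen on commensal | — | 0.8 |
| `x` | maximal pathogen clearance rate | 1/time | 0.1 |
| `f` | commensal susceptibility relative to pathogen | — | 1.0 |
| `A` | antibiotic exposure | — (0–1) | 0.0 |

The default demographic set (r = 0.5, k = 1, x = 0.1) is the competition
scenario used throughout the figure presets; `x/r = 0.2` encodes a partially
resistant pathogen whose density maximal exposure reduces by 20%.

## Equilibria and stability

Four fixed-point classes exist: joint extinction $(0,0)$, pathogen dominance
$(k_p(1 - xA/r_p), 0)$, commensal dominance $(0, k_c(1 - xfA/r_c))$, and the
interior coexistence point given by the closed form in the README. Stability
is classified numerically from the real parts of the $2\times2$ Jacobian
eigenvalues (computed in closed form from trace and determinant) with
tolerance $10^{-9}$, rather than from transcribed analytic inequality
tables; the analytic conditions are recovered behaviourally and are
cross-checked in the test suite by long-horizon ODE integration (200 random
parameter sets agree with the classification to $10^{-5}$).

Numerical conventions:

* **Feasibility snap.** Closed-form densities in $[-10^{-9}, 0)$ are snapped
  to 0; more negative values mean the branch is infeasible.
* **Marginal states.** A leading eigenvalue within $10^{-9}$ of zero is
  reported as `marginal`, never silently stable — parameter values exactly
  on bifurcation lines (e.g. $f = 0$, $A = 1$ in the default ecology) are
  routinely evaluated when drawing thresholds.
* **Effective-growth extinction.** If antibiotic loss exceeds the maximal
  growth rate, the corresponding single-species density is 0, not negative.
* **Tie-breaking in `classify_outcome`.** Duplicated fixed points (the
  interior branch collapsing onto a boundary at a transcritical point) are
  de-duplicated at $10^{-8}$ in state space; among marginal candidates the
  most strongly contracting one is returned.

## Gradients, thresholds and sweeps

`dPstar_dA` and `dPstar_df` evaluate the closed-form interior gradients; both
raise `NotApplicableError` outside the coexistence regime, because the
statements they encode are interior-equilibrium statements — no analytic
continuation across bifurcation boundaries is attempted. Sweeps
(`scan_Af`, `scan_alpha`) therefore mask gradients as NaN in cells whose
attractor is a boundary state and colour those cells by outcome class
instead. Sweep defaults are 201×201 over $(A, f) \in [0,1]\times[0,2]$; the
interaction sweep uses a 0.01-step grid over $\pm 0.96$ so the four canonical
scenarios $(\pm 0.8, \pm 0.8)$ lie exactly on grid nodes. Contour increments
(0.03, or 0.06 for the mutualism panel) are carried as plot metadata only.

## Temporal dynamics

`integrate` wraps scipy's adaptive LSODA with rtol $10^{-8}$ / atol
$10^{-11}$; convergence is declared when the terminal right-hand side falls
below $10^{-8}$ in max norm, and tiny negative solver excursions are clipped
to zero with a warning. Two-species runs default to starting at the
no-antibiotic coexistence equilibrium — the modelled communities (chronic
polymicrobial infections, bystander microbiomes) are assumed settled before
exposure begins — with a default horizon of 200 time units and a 6-rung
exposure ladder over $[0, 1]$.

A caveat the tests encode explicitly: "terminal pathogen density increases
with exposure" (competitive release) holds **while the commensal persists**.
On the top rungs of a susceptible-commensal ladder the commensal is
eliminated and the pathogen falls back to its alone-equilibrium, so
monotonicity is asserted over rungs where the commensal's terminal density
exceeds 10% of its no-antibiotic value — that 10% rule is the package's
operational definition of persistence on a ladder.

## Resource-explicit variant

To show the conclusions are not an artifact of the Lotka-Volterra
abstraction, `comres.resource` implements a one-nutrient chemostat with
Monod uptake:

$$\dot P = P(v_p R/(K_p + R) - d - xA), \quad
  \dot C = C(v_c R/(K_c + R) - d - xfA), \quad
  \dot R = s - dR - \textstyle\sum_i u_i N_i / y_i.$$

Both consumers draw on the same pool, the analogue of mutual inhibition
($\alpha_{pc}, \alpha_{cp} > 0$). Defaults (chosen once): demographically
identical consumers ($v = 1$, $K = 0.5$, $y = 1$, $s = 1$, $d = 0.2$) — the
two-strains-of-one-species reading, which coexist neutrally at $A = 0$ so
that antibiotic exposure alone breaks the tie — and a pathogen kill
coefficient $x = 0.1$ small against the growth margin, mirroring the
partially resistant pathogen of the baseline scenarios.

Because a single shared nutrient means complete niche overlap, long-run
competition always excludes one consumer for any $A > 0$; competitive
release is a transient-phase signature here, and the `fig5DEF` preset uses a
horizon of 60 time units, inside that window. The `lv_analogue` helper maps
a chemostat set onto a near-complete-overlap Lotka-Volterra set
(interaction coefficients truncated below 1) for which-species-persists
comparisons only; it makes no quantitative claim.

## Spatial variant

`comres.spatial` extends the baseline model to a 2-D reaction-diffusion
system with Fickian diffusion and a spatially varying exposure field,
discretised with a 5-point Laplacian on a uniform grid (method of lines,
adaptive RK45, rtol $10^{-6}$). Choices where the design was open:

* **Boundaries:** no-flux by default (a closed host compartment); periodic
  available.
* **Exposure field:** a linear ramp from `A_min` to `A_max` along one axis.
* **Diffusion:** $D_p = D_c = 10^{-3}$ on a unit domain by default, putting
  domain-crossing diffusion within an order of magnitude of the demographic
  timescale $1/r$ so spatial structure neither freezes nor mixes away.
* **Grid:** 64×64 default for production runs; the test suite and
  acceptance checks use 8×8–16×16 grids, which the degeneracy properties
  show to be sufficient for the qualitative contracts.

Reported pathogen densities are averaged over space. The module's contracts
are degeneracy ($D=0$, uniform $A$ reproduces the non-spatial ODE), mass
conservation under pure diffusion with no-flux boundaries, and the
small-diffusion limit (the spatial mean approaches the mean of the local
closed-form equilibria $P^*(A(x,y))$ as $D \to 0$).

## Risk optimization

Total infection risk at the attractor is
$w_p P^*(f) + w_c C^*(f) + w_{h\beta} P^*(f) C^*(f)$: a pathogen term, a
commensal opportunistic-infection term, and a static HGT term proportional
to the product of the two densities (maximal when both are abundant, zero
when either is extinct). Weights are static per-capita constants; an
optional `weight_fn` hook accepts $f$-dependent weights (e.g.
resistance-strength-dependent virulence) but none is defaulted. The $f$
grid defaults to 301 points over $[0, 3]$; grid argmin ties are broken
toward larger $f$ (the least resistance achieving minimal risk) with the
full tie set reported, and an interior maximum is reported only when the
largest interior value exceeds both endpoints beyond a $10^{-9}$-scale
prominence tolerance (which absorbs float noise at bifurcation kinks).

In the default competition ecology at $A = 1$, $P^* = 0.444 f$, so the
pathogen-exclusion region degenerates to the full-resistance boundary
$f = 0$; the no-HGT minimum sits there, and adding HGT
($w_{h\beta} = 5$) creates an interior risk peak near $f \approx 1.06$
without moving the minimum.

## What the tests do and do not show

All quantitative anchors are properties of the deterministic model at the
figure-preset parameter values; the randomized property tests sample
parameter space away from bifurcations (attractor leading eigenvalue below
$-0.01$) so that finite-horizon integration can meet the $10^{-5}$
agreement tolerance. Nothing here is fitted to data: passing tests show the
implementation agrees with the mathematics and that the qualitative claims
are robust across the three model frames at the stated parameterizations,
not that any particular microbial community obeys the model. Known
limitations: two species only (indirect effects in richer communities can
attenuate or reverse pairwise conclusions), no time-varying dosing or
pharmacokinetics, no demographic stochasticity, HGT as a static risk term
rather than a transfer dynamic, and the chemostat/spatial variants are
structural reimplementations whose published parameterizations were not
available, so only their qualitative ordering is asserted.
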