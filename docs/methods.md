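# Methods

`t2dsim` simulates the decades-long progression of type 2 diabetes in a
single virtual subject by coupling two time scales. A *slow* system (months)
carries the pancreatic compensation state; a *fast* system (minutes) carries
one complete day of glucose homeostasis. The two are advanced by alternating
steps: at every slow step the fast model simulates a full day from the
current compensation state, and the day's aggregates drive the slow
derivatives for the next month. No quasi-steady-state reduction is used, so
fasting and post-prandial glycemia are distinct quantities and the daily
glycemic profile can feed back on the slow dynamics.

## Slow system

State: beta-cell population `B` [Mc], replication reserve `eta` [/mo],
fasting glycemia `G_f` [mM], glycated haemoglobin `A` [%].

    dB/dt   = k_BB(eta, G_B) B (1 - B/B_max) - mu(t) B
    k_BB    = kBB_min + eta G_B^2 / (G_B50^2 + G_B^2)
    deta/dt = -k_XetaG G_eta eta + k_eta(t)
    dG_f/dt = k_GG (G_f24 - G_f)
    dA/dt   = k_AG G_B - k_XA A

`G_B` is the day's mean glycemia, `G_eta` the day's mean glucotoxicity and
`G_f24` the glycemia exactly 24 h after the day's start — all supplied by
the fast model. Replication is logistic with carrying capacity `B_max =
4000 Mc`; the net rate is negative below roughly 5.3 mM mean glycemia and is
bounded above by the reserve `eta`, which glucotoxicity erodes and a slowly
declining recovery rate `k_eta(t)` replenishes. The excess-mortality sigmoid
`mu(t)` is structurally present (it lets the same equations express the
rapid beta-cell loss of autoimmune diabetes) but defaults to zero; no
calibrated parameter values exist for that scenario, so only the
all-zero type 2 case is exercised by the tests.

The HbA1c balance is not given in closed form by the source material; the
implemented form (linear production from mean glycemia, first-order decay)
is the only one dimensionally consistent with `k_AG` [%/mo/mM] and `k_XA`
[/mo], and its steady state `A* = 0.9875 G_B` maps 5.5 mM to 5.4% — a
clinically sensible anchoring.

Glucotoxicity is an increasing Hill function of instantaneous glycemia
calibrated through two anchors — toxicity 1 at 5.5 mM, 3.5 at 30 mM — with
asymptote 4. Exponent and half-constant follow in closed form
(`h = 1.7946`, `K = 10.14 mM`); both anchors are reproduced to 1e-9.

Natural (untreated) aging of the control variables: peripheral insulin
sensitivity `k_XGImax`, hepatic insulin sensitivity `lam_GI` and secretory
ability `k_IBmax` decline along shared Hill-in-time curves beginning at
month 216 (age 18); insulin elimination `k_XI` and the recovery rate
`k_eta` drift linearly over the lifespan; gastric emptying `k_JS` is
constant. The first 18 years therefore run on constant young-adult
parameters, and the slow state settles to a healthy quasi-equilibrium
before the programmed insulin-resistance progression begins.

## Fast system (one day, minutes)

State: stomach and gut glucose `S`, `J` [mmol], plasma glucose `G` [mM],
insulin `I` [pM], glucagon `L` [pM], plus the renal tubule profile.

    dS/dtau = -k_JS S  (+ meal impulses)
    dJ/dtau = k_JS S - k_GJ J,      ra = f_GJ k_GJ J
    dG/dtau = -k_XGImax I/(I+I_KXGI50) G - k_XG G
              + [HGO + glucagon-driven production - brain - ur + ra] / (V_G W)
    dI/dtau = -k_XI I + psi(B, G (1 + f_IJ J/(J_G50+J))) / (V_I W)
    dL/dtau = -k_XL L + k_LG_max (f_LG_min + (1-f_LG_min) e^{-lam_LG G})

with `psi(B, G) = k_IBmax B G^3/(G_I50^3 + G^3)` the glucose-driven
secretion, amplified saturably by intestinal glucose content (incretin
effect), `HGO = k_GI_max exp(-lam_GI I[uIU/ml] G)` the insulin- and
glucose-suppressible hepatic output, and brain oxidation saturating at
`W k_Xgbrox_max`. The day runs 06:00 to 06:00 (simulation window
tau = 360..1800 min) with meals of 417/280/280 mmol at 07:00, 12:00 and
18:00 applied as instantaneous stomach loads (integrator stop/restart).
Each day starts from the fasted fast-equilibrium: insulin at its
secretion/elimination balance, glucagon at its glycemia-conditional steady
state, tubule at its steady profile — avoiding a spurious transient every
simulated day.

### Two resolved inconsistencies in the published parameterization

The printed constants contain two mutually inconsistent statements that the
package resolves in favour of dynamical self-consistency; both choices are
plain parameters and can be overridden.

1. **Peripheral-uptake pair.** The tabulated values `kXGI0max = 0.08 /min`,
   `I_KXGI50 = 333 pM`, `kXGI00 = 1.5e-4 /min/pM` violate the defining
   identity `kXGI0max = I_KXGI50 * kXGI00` (333 x 1.5e-4 = 0.05). The
   package uses the coherent triple `(0.05 /min, 500 pM, 1e-4 /min/pM)`
   worked through in the source's own text.
2. **Hepatic-suppression unit.** With the exponent read as
   `lam_GI * I[pM] * G` the baseline fast model has no equilibrium near the
   stated baseline fasting glycemia of 4.2 mM (the fasted fluxes leave a
   0.38 mmol/min deficit and the day settles near 3.4 mM). Read with
   insulinemia in uIU/ml (pM/6) the fasting fluxes at 4.2 mM balance to
   0.3%, so `lam_GI` is stored in /(uIU/ml)/mM and the conversion is the
   parameter `insulin_pM_per_uIU` (set it to 1 to recover the literal pM
   reading).

Under these two readings every stated baseline anchor holds simultaneously
in simulation: the net replication rate is ~0 at the baseline state, the
reserve is stationary at `eta0 = 0.04`, mean daily toxicity is 1.01, the
beta-cell mass plateaus near 1000-1100 Mc through early adulthood, and the
subject presents pre-diabetic (fasting glycemia ~5.6 mM, HbA1c ~6.6%) at
month 600. The tabulated fasting insulin `I_f0 = 19.8 pM` is ~9% above the
secretion/elimination equilibrium at (1000 Mc, 4.2 mM); initialization uses
the equilibrium value (18.2 pM) and keeps the tabulated number as data.

## Renal tubule

A single idealized tubule on normalized length `z in [0, 1]` receives
ultrafiltrate at the glomerular filtration rate and discharges urine;
water reabsorption gives the flow profile
`phi(z) = (Cl_inulin - F_urine) e^{-8z} + F_urine` (per kg). Filtered
glucose is advected with the flow and removed by a saturable transporter
with capacity density `k_GU_max * 7 e^{-7z}` and half-constant 19 mM:

    dq/dtau = D_U d2C/dz2 - d(phi C)/dz - k_GU_max 7 e^{-7z} C/(19 + C)

with `C = q/v`, boundary `C(tau, 0) = G(tau)` and whole-body loss
`ur = W C(tau, 1) F_urine`. The advection is implemented in conservative
flux form, so filtered load = reabsorption + tubular outflow holds exactly
at steady state on the grid (the reported urinary rate differs from the
discrete outflow only by the factor `F_urine/phi(1) = 0.97`, an artifact of
the exponential flow profile not quite reaching `F_urine` at `z = 1`).
This form produces the physiological titration curve — losses negligible at
low glycemia, rising toward slope `W Cl_inulin` once transport saturates —
as an emergent property; a hard threshold is nowhere encoded. The transit
time `T` (not specified by the source, default 5 min) scales only the
transient: the steady profile provably contains no `T`, and the test suite
verifies 2-vs-10-min agreement to 0.1%.

Numerics: first-order upwind in `z` on 101 uniform nodes (`D_U = 0`
defaults make the equation hyperbolic; the diffusion stencil is implemented
for `D_U > 0`). Steady profiles are computed exactly by marching the
discrete balance node by node — each node is a scalar quadratic with a
unique non-negative root. The grid-convergence test measures first-order
convergence of the outlet loss under refinement.

## Coupled integration

The daily ODEs, the tubule method-of-lines system and five cumulative flux
integrals (absorption, uptake, brain, endogenous production, urinary loss)
are advanced as one monolithic stiff system with SciPy's BDF and an
explicit Jacobian sparsity pattern (the tubule couples lower-bidiagonally,
plus one column from plasma glucose). This is unconditionally stable — no
splitting error, no CFL sub-stepping — and costs 0.2-0.4 s per simulated
day; the carried quadrature states let the daily glucose bookkeeping close
to solver tolerance (relative residual < 1e-4) instead of trapezoid
accuracy. Tolerances: rtol 1e-6, atol 1e-8 (state units); reporting on a
1-minute grid. The slow system uses explicit Euler with a 1-month step
(configurable; a step-halving test verifies first-order consistency), with
`eta` floored at 0 and `B` clipped to `[0, B_max]` after each step.

## Therapy engine

A treatment is, per control channel, a difference-of-exponentials
proportional effect `E(t) = Ampl (e^{-beta t} - e^{-alpha t})/peak(alpha,
beta)` starting at `t_thx` (default month 600, the mean enrollment age of
the study cohort), normalized so its maximum is exactly `Ampl` at
`t_peak = log(alpha/beta)/(alpha-beta)`. The default application strategy is
multiplicative, `actual = natural (1 + E)` with `E` clipped below at -0.99;
a saturating alternative (`E/(1+|E|)`) is provided because the source never
states the combination rule and its tabulated amplitudes are not consistent
with its quoted percent-of-normal peak improvements under any simple
convention. `calibrate_amplitude` inverts the achieved peak increment to a
target percent-of-baseline for users who prefer the quoted percentages over
the tabulated amplitudes. The built-in arms (none / placebo / lifestyle /
metformin) carry the tabulated triples for peripheral sensitivity, hepatic
sensitivity and gastric emptying; no arm touches secretory ability or the
reserve channel, though both channels are wired.

## Virtual experiments and indices

*OGTT*: a separate protocol run — fasted fast-equilibrium start at the
current `G_f`, one 417-mmol (75 g at 180.16 mg/mmol) stomach load at time
zero, 180-min horizon, samples at 0/30/60/120 min.

*Euglycemic hyperinsulinemic clamp*: insulin forced to square-wave plateaus
(100 pM for 120 min, then 420 pM for 120 min) while glycemia is pinned at
5.0 mM; the glucose infusion rate is obtained algebraically as the rate
that zeroes the glucose balance (including the urinary loss at the clamped
glycemia), floored at 0 with a flag; `M1`/`M2` are the mean infusion over
the final 30 min of each step, converted to mg/kgBW/min. Glucagon and the
tubule evolve dynamically from the fasted state. At the baseline state this
yields M1 = 2.0, M2 = 5.0 mg/kg/min; the low-dose step retains sensitivity
to hepatic insulin sensitivity (partial HGO suppression at 100 pM), the
high-dose step is dominated by peripheral uptake — reproducing the
clinical interpretation of the two-step protocol.

*Indices*: standard clinical definitions with 6.0 pM per uIU/ml —
HOMA-IR = I[uIU/ml] G/22.5; HOMA-B = 20 I[uIU/ml]/(G-3.5), flagged
undefined at G <= 3.5 mM; insulinogenic index = dI(0-30)/dG(0-30).

## Synthetic observed-data fixture

`generate_fixture` emulates the averaged clinical endpoint series the model
is meant to be overlaid on: the five endpoints (fasting glycemia and
insulin, 30-min glycemia and insulin, 2-h glycemia) at protocol visits,
plus i.i.d. Gaussian noise per endpoint (seeded). It reproduces the *file
format and sampling structure* of averaged trial data, not its
between-subject variability structure (no correlated errors, no cohort
drift, no dropout); passing comparison tests therefore demonstrates the
harness plumbing, not fidelity to any real cohort.

## Problem sizes and known limitations

The shipped configuration — 101 tubule nodes, 1-month slow steps, 55-year
horizons — was chosen as the point where further refinement changes the
reported quantities by less than 0.1% (grid and step-halving studies in the
test suite); a full life course simulates in under two minutes.

Limitations worth knowing:

* The source's printed calibration does not reproduce its own stated 5-year
  beta-cell decline (>10% from enrollment): this package computes 7.6-7.9%
  across the defensible structural readings. The acceptance suite asserts
  the stated figure and the assertion fails; the number the package
  actually computes is reported by `scripts/acceptance.py`.
* With the conservative tubule and the printed half-constant (19 mM),
  urinary loss at normal glycemia is ~130 mmol/day — higher than
  physiological (real normoglycemic glycosuria is near zero). The smeared
  titration is inherent to the printed transporter parameters.
* Body weight is constant; no lipid/fat-mass channel; glucagon dynamics do
  not age; gastric emptying is mono-exponential (no pulsatility, no meal
  composition); a single scalar beta-cell pool.
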