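# Methods

## The model

The presomitic mesoderm (PSM) is a 1-D array of `N = 41` cells at fixed
spacing `dx = 10 um` on `0 <= x <= L = 400 um`, in the *tailbud reference
frame*: `x = L` is the posterior tip, and axis elongation appears as
anterior advection of cells at constant speed `u`.  A cell reaching `x = 0`
leaves the domain; a new posterior cell is added at `x = L` as a copy of its
anterior neighbour, keeping `N` constant.  The *lab frame* (embryo-static,
`x_lab = x + u t`) is where somite boundaries are stationary.

Eight variables per cell, all dimensionless: nascent and mature *her* mRNA
(`m_h`, `M_h`), nascent and mature *ripply* mRNA (`m_r`, `M_r`), Her,
Ripply and Tbx6 proteins (`p_h`, `p_r`, `p_t`), and dpErk (`p_e`,
prescribed, not integrated).  mRNA concentrations are scaled by the maximal
*her* transcription rate over its mRNA decay rate; proteins by the Tbx6
positive-feedback production rate over its basal decay rate.  Delay
differential equations (one set per cell, no cell-cell coupling —
Delta-Notch signalling is deliberately omitted):

* **her**: transcription `1/(1 + (p_h(t-tau_h)/K1)^n1) * f(p_t(t-tau_h))`,
  where the Tbx6 gate `f` is a Hill activation for `x <= x_h` and constant 1
  posteriorly (posterior *her* expression is carried by other T-box
  factors); splicing `mu_sh`; mature decay `mu1`.  Her protein is translated
  from `M_h(t - tau_H(x))` with a *linear delay gradient*
  `tau_H(x) = tau_H0 + (tau_HL - tau_H0) x/L`, and decays at `mu3 mu4`.
* **ripply**: transcription `nu1 * rep(p_h; K3) * rep(p_e; K4) *
  act(p_t; K5)` delayed by `tau_r` — a coincidence detector that fires in
  the trough between Her waves, anterior of the dpErk border, inside the
  Tbx6 domain; splicing `mu_sr`, mature decay `mu1 mu2`; translation delayed
  by `tau_R`, protein decay `mu3 mu5`.
* **Tbx6**: `dp_t/dt = mu3 [ act(p_t; K6, n6) + gamma * rep(F; K_FR, nR) *
  act(F; K_FA, nA) - (1 + eta p_r) p_t ]`.  The first term is the positive
  feedback loop (PFL, the bistable memory); the second is an incoherent
  feedforward read-out (IFFL) of the Fgf gradient
  `F(x) = F0 exp(-(L-x)/x_f)` that drives Tbx6 on only at intermediate `F`
  (requires `K_FA < K_FR`); Ripply multiplies the degradation rate by
  `1 + eta p_r`.
* **dpErk**: `p_e = 0` anterior of the border `x_e(t)`, rising as
  `nu_e (1 - exp(-q (x - x_e)))` posteriorly.  In `fixed` mode
  `x_e = x_E` (the gradient rides with the tailbud); in `stepwise` mode the
  border is lab-fixed between resets — it recedes at `u` in the tailbud
  frame and snaps back to `x_E` after travelling `delta`.

Steady states of the switch solve `P = D` with `P` the production curve and
`D = (1 + eta p_r) p_t`; raising the factor `d = 1 + eta p_r` annihilates
the upper stable state through a saddle-node (SN) bifurcation.  For
`n6 = 2` with no IFFL input the SN factor is exactly `d* = 1/(2 K6)`
(from the discriminant of `d p^2 - p + d K6^2 = 0`), which anchors the
numerical bisection as an oracle.

## Calibration of the defaults

The published parameter table was not available to this implementation, so
the defaults are a calibration, fixed once and recorded in
`somitesim.params`:

| group | values | rationale |
| --- | --- | --- |
| geometry / integration | `L=400`, `dx=10`, `N=41`, `dt=0.01 min`, warm-up 460 min | printed in the source description |
| clock rates | `mu1=0.4/min`, `mu_sh=mu_sr=5`, `mu3=0.3/min`, `mu4=1.5`, `nu2=10`, `K1=1`, `n1=2`, `tau_h=8 min` | minutes-scale half-lives; the single-cell posterior circuit oscillates with period 30.0 min (measured by scan, scratch-calibrated before tests were frozen) |
| delays | `tau_HL=2`, `tau_H0=12 min` (ratio 6), `tau_r=5`, `tau_R=3 min` | ratio 6 as printed; `tau_H = 7.45 min` then falls at `x = 182 um`, inside the boundary-forming zone, consistent with the single-cell scan convention |
| advection | `u = 6 dx / 30 = 2 um/min` | one clock cycle advects exactly one 6-cell somite; `dx/u = 5 min` is an exact multiple of `dt` |
| Tbx6 switch | `K6=0.4`, `n6=2`, `gamma=0.4`, `K_FA=0.12`, `K_FR=0.3`, `nA=4`, `nR=6`, `F0=1`, `x_f=70 um` | bistable anteriorly (`d* = 1.25`); the IFFL drive exceeds the low-state annihilation threshold only for `x ~ 210-340 um`, so cells ignite mid-PSM, the tailbud keeps its low branch (new cells enter low), and anterior removal is permanent |
| ripply arm | `nu1=1`, `K3=1`, `K4=0.2`, `K5=0.4`, `n3..n5=2`, `nu3=5`, `mu2=1`, `mu5=2`, `eta=2` | Ripply pulses reach a peak degradation factor `1 + eta p_r ~ 4.4`, comfortably above `d*`; Ripply protein is short-lived (half-life ~1.2 min), so persistence of Tbx6 repression must come from bistability, not from Ripply itself |
| dpErk | `nu_e=1`, `q=0.1 /um`, `x_E=200`, `delta=60`, `x_e0=180 um` | border anchored mid-domain; stepwise constants as printed |
| her/Tbx6 gate | `x_h = 250 um`, `K2=0.4`, `n2=2` | inside the Tbx6-high region; not printed in the source, exposed in config |

All Hill exponents default to 2 except the IFFL pair (`nA=4`, `nR=6`),
which the calibration needs to keep the tailbud input below the ignition
threshold while the mid-PSM input is far above it; `n6 = 2` keeps the SN
closed form exact.

Emergent behaviour under these defaults, produced by the analysis scripts
and asserted by the test suite: Her waves travel anteriorly and slow down
(per-cell period 35 -> 39.5 min across the recorded window, ratio ~1.13;
uniform at 30 min when the delay ratio is set to 1); a Ripply pulse fires
once per cycle at the anterior skirt of the dpErk gradient; Tbx6 is cut and
the new anterior border persists; consecutive lab-frame borders are spaced
6.0 cells apart; *her* transcription shuts off where Tbx6 is removed.

## Numerical choices

* **Integrator**: explicit Euler at `dt = 0.01 min`, the model's reference
  scheme; the suite verifies first-order convergence (error halves per `dt`
  halving).  Delays are rounded to the nearest multiple of `dt` at
  configuration time (max error `dt/2`), making every history lookup an
  exact ring-buffer read.
* **Initial history**: for all `t` in `[-max delay, 0]`: `m_h = M_h = 1`,
  `m_r = M_r = p_r = 0`, `p_h = nu2/mu4`, `p_t = 1` for `x <= x_h` else 0,
  `p_e` from the dpErk profile.
* **Advection** is an exact one-index shift every `dx/u` minutes
  (`validate_parameters` enforces divisibility by `dt`), with the new
  posterior cell copying its neighbour's full delay history — the only
  choice that keeps delayed terms well-defined.  Lab-frame bookkeeping uses
  the integer shift count, so a material cell owns one lab grid column
  exactly and somite boundaries are grid-exact.
* **Negative excursions**: values in `[-1e-9, 0)` are clamped to zero and
  counted (Hill terms are undefined below zero); anything lower aborts.
  With the defaults the clamp counter stays at zero.
* **Root finding**: vectorised sign scan (1e4 points, doubled for a
  consistency check) with Brent refinement; stability from the sign of
  `d(P-D)/dp_t`; tangencies labelled `sn`.  The SN factor is bisected to
  1e-6 on a single 2e4-point scan (the coarse/fine agreement check would
  trip by construction near the tangency).
* **Boundary detection**: threshold = midpoint of the low/high stable
  states at the anterior signal level (parameter-aware); a new boundary is
  a posterior border jump >= 2 cells; *persistence* is the time until the
  border returns anteriorly past the formation position (Tbx6
  re-ignition).  Persistence is deliberately insensitive to posterior
  motion: a fresh border trails 1-2 cells of late erosion before settling,
  and the next cycle's cut moves the anteriormost border posteriorly
  without destroying the existing boundary.
* **Wave arrest**: anteriormost position whose amplitude over a trailing
  half-period window exceeds 20% of the maximum.  Because Tbx6 removal
  propagates to Her protein only after `tau_h + tau_H` (~17 min), protein
  amplitude trails the border by up to one somite right after a cut; the
  acceptance check therefore evaluates the nascent-transcript (`m_h`)
  kymograph late in the cycle, where arrest and border coincide to the
  cell.
* **Phase diagram**: each `(K6, nu3)` point runs the full pipeline
  (warm-up + two cycles); "formed" requires a boundary persisting >= one
  clock period.  The reported y-coordinate is the *achieved* peak factor
  `1 + eta max p_r` near the dpErk border; the overlaid SN curve is
  evaluated at the anterior signal level, where a formed boundary has to
  survive.

## What the synthetic fixtures do and do not show

`somitesim.fixtures` generates step/boxcar/sigmoid profiles, traveling
waves `A(x)(1 + sin(2 pi (t/T(x) - x/lambda)))/2` with linearly graded
period, and programmed border-jump schedules, each carrying its exact
ground truth, optionally with clipped additive Gaussian noise.  They
exercise the detectors (edges, periods, arrest, jump events) independently
of the simulator, so a detector bug cannot hide behind model behaviour and
vice versa.  They do not emulate advection bookkeeping, delay-induced
waveform asymmetry, or the covariation of variables — those are covered
only by the closure tests on real simulator output.

## Design choices on genuinely open points

* The spatial bifurcation structure cannot make the posterior tip
  monostable-low: production is bounded below by the PFL curve, so wherever
  the switch is bistable anteriorly the high state also exists at the
  tailbud.  What keeps the tailbud dark is occupancy, not topology: the
  IFFL input there is far below the low-state annihilation threshold, and
  newly added cells copy a still-low neighbour.  Tests assert this
  occupancy picture.
* `x_h` (the her/Tbx6-gate switch) is treated as fixed in the tailbud
  frame, like the gradients it stands in for.
* The her knock-out zeroes only the transcription term (splicing and decay
  continue); the no-PFL variant zeroes only the autoregulation term.
* Problem sizes in the scripts and tests (160-min recordings, 4x4 phase
  grids, 100-draw oracle sweeps) were chosen as the smallest sizes that
  show each effect clearly.

## Known limitations

* No Delta-Notch coupling: cells are autonomous, so noise-induced
  desynchronisation and its rescue cannot be studied.
* One *her* and one *ripply* gene stand in for the paralogue pairs.
* dpErk is prescribed, not a signalling model; MEK inhibition is a
  ten-fold plateau reduction, not receptor-level kinetics.
* Explicit Euler is first-order; all reported quantities are grid-level
  (cell, frame) statements, well inside that accuracy, but trajectories
  are not reference-quality beyond O(dt).
* The calibration reproduces qualitative wild-type and mutant behaviour
  and the printed geometric/delay constants; individual rate constants are
  not claims about zebrafish biochemistry.
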