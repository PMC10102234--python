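"""Parameter set for the PSM gene-network model, with validation and mutant presets.

The model couples four players on a moving 1-D array of presomitic-mesoderm
(PSM) cells:

* a delayed Her negative-feedback oscillator (the segmentation clock),
* Ripply, whose transcription is gated by Her (repression), dpErk
  (repression) and Tbx6 (activation),
* Tbx6, a bistable switch built from a positive feedback loop (PFL) and an
  incoherent feedforward loop (IFFL) reading the posterior Fgf gradient,
  degraded at a rate boosted proportionally to Ripply,
* dpErk, a prescribed posterior-high profile with a sharp anterior border.

All concentrations are dimensionless: mRNAs are scaled by the maximal
*her* transcription rate over its mRNA decay rate, proteins by the PFL
production rate of Tbx6 over its basal decay rate.  ``mu1`` (mature *her*
mRNA decay, 1/min) and ``mu3`` (basal Tbx6 decay, 1/min) set the reference
timescales of the mRNA and protein equations; the remaining ``mu*`` are
relative to them.

Calibration of the defaults (:func:`default_parameters`) is executable
policy, not a table of magic numbers:

* the single-cell her circuit at the posterior translation delay
  ``tau_HL`` oscillates with period ``CLOCK_PERIOD`` = 30 min
  (zebrafish-like), pinned by the choice of ``mu1, mu3, mu4, tau_h``;
* the advection speed is derived as ``u = SOMITE_CELLS * dx /
  CLOCK_PERIOD`` so one clock cycle advects exactly one somite
  (6 cells) through the domain;
* the Tbx6 input constants (``gamma, K_FA, K_FR, nA, nR, F0, x_f``) place
  the IFFL drive above the saddle-node ignition threshold only in the
  mid-PSM, so cells enter the tailbud on the low branch, ignite to the
  high branch in the mid-PSM, and are bistable (hysteretic) anteriorly;
* ``eta, nu3`` give Ripply pulses a peak degradation factor 1 + eta*p_r
  comfortably above the saddle-node threshold 1/(2*K6).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any

__all__ = [
    "ModelParameters",
    "default_parameters",
    "validate_parameters",
    "apply_perturbation",
    "SCENARIOS",
    "CLOCK_PERIOD",
    "SOMITE_CELLS",
    "write_config",
]

#: Calibrated posterior clock period, min.  The her delays and decay rates in
#: :func:`default_parameters` were chosen so that the single-cell oscillator
#: at tau_H = tau_HL realises this period (see docs/methods.md).
CLOCK_PERIOD = 30.0

#: Somite size in cells; one clock cycle advects one somite.
SOMITE_CELLS = 6

SCENARIOS = (
    "wild_type",
    "her_ko",
    "ripply_ko",
    "mek_inhibition",
    "no_pfl",
    "erk_stepwise",
)


@dataclass(frozen=True)
class ModelParameters:
    """Every rate constant, Hill constant, delay and geometric constant.

    Units: lengths in micrometres, times/delays in minutes, ``mu1``/``mu3``
    in 1/min, ``q`` in 1/micrometre.  All other rates, Hill constants and
    concentrations are dimensionless (see module docstring).
    """

    # -- geometry / integration -------------------------------------------
    L: float = 400.0          # domain length, um
    dx: float = 10.0          # cell spacing (cell size), um
    N: int = 41               # cell count == round(L/dx) + 1
    u: float = 2.0            # advection speed, um/min (= 6*dx/CLOCK_PERIOD)
    dt: float = 0.01          # Euler step, min
    t_warmup: float = 460.0   # warm-up duration, min

    # -- mRNA kinetics (reference rate mu1, 1/min) ------------------------
    mu1: float = 0.4          # mature her mRNA decay, 1/min (reference)
    mu_sh: float = 5.0        # her splicing rate, relative to mu1
    mu_sr: float = 5.0        # ripply splicing rate, relative to mu1
    mu2: float = 1.0          # mature ripply mRNA decay, relative to mu1

    # -- protein kinetics (reference rate mu3, 1/min) ---------------------
    mu3: float = 0.3          # basal Tbx6 decay, 1/min (reference)
    mu4: float = 1.5          # Her protein decay, relative to mu3
    mu5: float = 2.0          # Ripply protein decay, relative to mu3

    # -- production rates --------------------------------------------------
    nu1: float = 1.0          # max ripply transcription (0 in ripply KO)
    nu2: float = 10.0         # Her translation rate
    nu3: float = 5.0          # Ripply translation rate
    nu_e: float = 1.0         # dpErk plateau level

    # -- Hill constants and exponents -------------------------------------
    K1: float = 1.0           # Her self-repression
    K2: float = 0.4           # Tbx6 activation of her (anterior regime)
    K3: float = 1.0           # Her repression of ripply
    K4: float = 0.2           # dpErk repression of ripply
    K5: float = 0.4           # Tbx6 activation of ripply
    K6: float = 0.4           # Tbx6 PFL (its own promoter)
    K_FA: float = 0.12        # Fgf activation arm of the IFFL
    K_FR: float = 0.3         # Fgf repression arm of the IFFL (> K_FA)
    n1: float = 2.0
    n2: float = 2.0
    n3: float = 2.0
    n4: float = 2.0
    n5: float = 2.0
    n6: float = 2.0
    nA: float = 4.0
    nR: float = 6.0

    # -- delays, min -------------------------------------------------------
    tau_h: float = 8.0        # her transcription delay
    tau_r: float = 5.0        # ripply transcription delay
    tau_H0: float = 12.0      # Her translation delay at x = 0 (anterior)
    tau_HL: float = 2.0       # Her translation delay at x = L (tailbud)
    tau_R: float = 3.0        # Ripply translation delay

    # -- spatial inputs ----------------------------------------------------
    x_h: float = 250.0        # her Tbx6-dependence switch position, um
    gamma: float = 0.4        # IFFL production weight
    eta: float = 2.0          # Ripply-boosted Tbx6 degradation coupling
    F0: float = 1.0           # Fgf amplitude at the tailbud tip
    x_f: float = 70.0         # Fgf gradient length scale, um
    q: float = 0.1            # dpErk rise length-scale inverse, 1/um

    # -- dpErk border ------------------------------------------------------
    x_E: float = 200.0        # dpErk border anchor (tailbud frame), um
    delta: float = 60.0       # stepwise-shift travel distance, um
    x_e0: float = 180.0       # initial dpErk border in stepwise mode, um
    erk_mode: str = "fixed"   # "fixed" | "stepwise"

    # -- scenario multipliers ---------------------------------------------
    her_tx_scale: float = 1.0  # multiplies the her transcription term (0 = her KO)
    pfl_scale: float = 1.0     # multiplies the Tbx6 PFL term (0 = no PFL)

    def max_delay(self) -> float:
        """History horizon: the largest delay appearing in any equation."""
        return max(self.tau_h, self.tau_r, self.tau_H0, self.tau_HL, self.tau_R)

    def advection_interval(self) -> float:
        """Time between advection index shifts, min (= dx / u)."""
        return self.dx / self.u

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{**dataclasses.asdict(cls()), **d})


def default_parameters() -> ModelParameters:
    """Calibrated wild-type parameter set.

    Geometry, integration and the dpErk border constants are the printed
    ones (L = 400 um, dx = 10 um, N = 41, dt = 0.01 min, warm-up 460 min,
    tau_H0/tau_HL = 6, x_E = 200 um, delta = 60 um, x_e0 = 180 um); the
    kinetic constants come from the calibration policy in the module
    docstring.  The advection speed is derived here rather than stored, so
    that the one-cycle-per-somite relation is explicit.
    """
    u = SOMITE_CELLS * 10.0 / CLOCK_PERIOD   # 6 cells x 10 um per 30 min clock
    return ModelParameters(u=u, N=int(round(400.0 / 10.0)) + 1)


def validate_parameters(p: ModelParameters) -> list[str]:
    """Check every structural invariant; return a violation list (empty = valid).

    Violations are data, not exceptions: each entry names the offending
    field(s) and the rule.  ``nu1``, ``nu_e`` and the scenario multipliers
    may be zero (knock-out presets); everything else must be strictly
    positive.
    """
    v: list[str] = []

    strictly_positive = [
        "L", "dx", "u", "dt", "t_warmup",
        "mu1", "mu_sh", "mu_sr", "mu2", "mu3", "mu4", "mu5",
        "nu2", "nu3", "q",
        "K1", "K2", "K3", "K4", "K5", "K6", "K_FA", "K_FR",
        "tau_h", "tau_r", "tau_H0", "tau_HL", "tau_R",
        "gamma", "eta", "F0", "x_f",
    ]
    for name in strictly_positive:
        if getattr(p, name) <= 0:
            v.append(f"{name} must be strictly positive, got {getattr(p, name)}")
    for name in ("nu1", "nu_e", "her_tx_scale", "pfl_scale", "delta"):
        if getattr(p, name) < 0:
            v.append(f"{name} must be non-negative, got {getattr(p, name)}")
    for name in ("n1", "n2", "n3", "n4", "n5", "n6", "nA", "nR"):
        if getattr(p, name) < 1:
            v.append(f"{name}: Hill exponents must be >= 1, got {getattr(p, name)}")

    if not p.K_FA < p.K_FR:
        v.append(f"K_FA < K_FR required (IFFL band), got K_FA={p.K_FA}, K_FR={p.K_FR}")
    if p.tau_HL > 0:
        ratio = p.tau_H0 / p.tau_HL
        if not 1.0 <= ratio <= 7.0:
            v.append(
                f"tau_H0/tau_HL must lie in [1, 7], got {ratio:g} "
                f"(tau_H0={p.tau_H0}, tau_HL={p.tau_HL})"
            )
    if p.dx > 0 and p.N != int(round(p.L / p.dx)) + 1:
        v.append(f"N must equal round(L/dx) + 1 = {int(round(p.L / p.dx)) + 1}, got {p.N}")
    if not 0 < p.x_h < p.L:
        v.append(f"x_h must lie strictly inside (0, L), got {p.x_h}")
    if not 0 <= p.delta < p.x_E <= p.L:
        v.append(f"require 0 <= delta < x_E <= L, got delta={p.delta}, x_E={p.x_E}, L={p.L}")
    if p.erk_mode not in ("fixed", "stepwise"):
        v.append(f"erk_mode must be 'fixed' or 'stepwise', got {p.erk_mode!r}")
    if p.u > 0 and p.dt > 0:
        k = p.dx / p.u / p.dt
        if abs(k - round(k)) > 1e-9 * max(1.0, k):
            v.append(
                f"dt must divide dx/u exactly (grid advection), "
                f"got dx/u = {p.dx / p.u:g}, dt = {p.dt:g}"
            )
    return v


def apply_perturbation(p: ModelParameters, scenario: str) -> ModelParameters:
    """Return a new parameter set for a named scenario; never mutates ``p``.

    * ``wild_type``       -- identity.
    * ``her_ko``          -- her transcription term multiplied by zero.
    * ``ripply_ko``       -- nu1 = 0 (no ripply transcription).
    * ``mek_inhibition``  -- nu_e reduced ten-fold (MEK inhibitor).
    * ``no_pfl``          -- Tbx6 autoregulation term multiplied by zero.
    * ``erk_stepwise``    -- dpErk border steps posteriorly: stepwise mode
      with x_E = 200 um, delta = 60 um, x_e0 = 180 um.
    """
    if scenario == "wild_type":
        return replace(p)
    if scenario == "her_ko":
        return replace(p, her_tx_scale=0.0)
    if scenario == "ripply_ko":
        return replace(p, nu1=0.0)
    if scenario == "mek_inhibition":
        return replace(p, nu_e=p.nu_e / 10.0)
    if scenario == "no_pfl":
        return replace(p, pfl_scale=0.0)
    if scenario == "erk_stepwise":
        return replace(p, erk_mode="stepwise", x_E=200.0, delta=60.0, x_e0=180.0)
    raise ValueError(f"unknown scenario {scenario!r}; valid scenarios: {SCENARIOS}")


# ---------------------------------------------------------------------------
# configuration files


def write_config(p: ModelParameters, path: str | Path) -> None:
    """Write a flat JSON config, one key per parameter field."""
    Path(path).write_text(json.dumps(p.to_dict(), indent=1) + "\n")


def _read_toml_or_json(path: Path) -> dict[str, Any]:
    if path.suffix == ".toml":
        import tomllib

        return tomllib.loads(path.read_text())
    return json.loads(path.read_text())


def read_config(path: str | Path) -> ModelParameters:
    """Read a flat JSON/TOML config; missing keys fall back to defaults.

    Unknown keys raise ``KeyError``; a parameter set violating any invariant
    raises ``ValueError`` listing all violations at once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    overrides = _read_toml_or_json(path)
    base = default_parameters().to_dict()
    known = set(base)
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(f"unknown parameter keys in {path.name}: {sorted(unknown)}")
    base.update(overrides)
    if "N" not in overrides and {"L", "dx"} & set(overrides):
        base["N"] = int(round(base["L"] / base["dx"])) + 1
    p = ModelParameters(**base)
    violations = validate_parameters(p)
    if violations:
        raise ValueError(
            f"invalid configuration {path.name}:\n  " + "\n  ".join(violations)
        )
    return p
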