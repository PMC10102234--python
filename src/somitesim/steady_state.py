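"""Equilibria and bifurcations of the Tbx6 switch; her-oscillation scan.

The Tbx6 equation at fixed Ripply level p_r and signal level F is a 1-D
flow dp_t/dt = mu3 (P(p_t) - D(p_t)) with

    P = PFL Hill term + IFFL input  (S-shaped, bounded by 1 + gamma),
    D = (1 + eta p_r) p_t           (linear).

Intersections P = D are the steady states; generically one or three, with
stabilities alternating stable/unstable/stable.  Raising the degradation
factor d = 1 + eta p_r tilts D until the upper stable state collides with
the unstable one and vanishes -- a saddle-node (SN) bifurcation.  For
n6 = 2 with the IFFL input absent the SN factor has the closed form
d* = 1/(2 K6), which the numerical routines are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .kinetics import hill_activation, tbx6_production
from .params import CLOCK_PERIOD, ModelParameters
from .tissue import fgf_gradient

__all__ = [
    "SteadyStateSet",
    "PhaseDiagram",
    "production_degradation_curves",
    "find_steady_states",
    "sn_degradation_threshold",
    "bifurcation_along_axis",
    "phase_diagram",
    "her_oscillation_scan",
]


@dataclass
class SteadyStateSet:
    """Tbx6 fixed points at one (F, p_r) condition, sorted ascending."""

    F: float
    p_r: float
    states: list[tuple[float, str]]  # (p_t, "stable" | "unstable" | "sn")

    @property
    def roots(self) -> list[float]:
        return [r for r, _ in self.states]

    @property
    def stable_roots(self) -> list[float]:
        return [r for r, s in self.states if s == "stable"]

    @property
    def bistable(self) -> bool:
        return len(self.stable_roots) >= 2


@dataclass
class PhaseDiagram:
    """Boundary-formation outcomes over (K6, Ripply translation rate).

    ``outcome[i, j]`` is True where the simulation formed a persistent
    anterior Tbx6 boundary for K6 = k6_values[i], nu3 = v3_values[j];
    ``achieved_factor`` is the realised max 1 + eta p_r near the dpErk
    border; ``sn_factor[i]`` is the SN threshold at that K6.
    """

    k6_values: np.ndarray
    v3_values: np.ndarray
    outcome: np.ndarray
    achieved_factor: np.ndarray
    sn_factor: np.ndarray
    errors: list[tuple[int, int, str]] = field(default_factory=list)


def _degradation_factor(p: ModelParameters, p_r: float) -> float:
    return 1.0 + p.eta * p_r


def production_degradation_curves(
    p_t_grid: np.ndarray, F: float, p_r: float, p: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """The P (production) and D (degradation) curves on a Tbx6 grid."""
    grid = np.asarray(p_t_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty p_t grid")
    if np.any(np.diff(grid) < 0) or np.any(grid < 0):
        raise ValueError("p_t grid must be sorted ascending and non-negative")
    P = np.asarray(tbx6_production(grid, F, p), dtype=float)
    D = _degradation_factor(p, p_r) * grid
    return P, D


def _p_max(p: ModelParameters) -> float:
    # production is bounded by 1 + gamma, so every root lies below this
    return 10.0 * (1.0 + p.gamma)


def _scan_roots(g, p_max: float, n: int) -> list[float]:
    """Vectorised sign-change scan on [0, p_max] with Brent refinement."""
    grid = np.linspace(0.0, p_max, n)
    vals = g(grid)
    roots: list[float] = []
    # an exact zero at the origin (no input: production starts at 0);
    # a merely tiny positive value there is a genuine crossing just above 0
    # and is found by the sign scan instead
    if vals[0] == 0.0:
        roots.append(0.0)
    idx = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
    scalar_g = lambda x: float(g(x))
    for i in idx:
        roots.append(brentq(scalar_g, grid[i], grid[i + 1], xtol=1e-12))
    exact = np.nonzero(vals[1:-1] == 0.0)[0] + 1
    roots.extend(float(grid[i]) for i in exact)
    return sorted(roots)


def find_steady_states(
    F: float,
    p_r: float,
    p: ModelParameters,
    n_scan: int = 10_000,
    _factor: float | None = None,
) -> SteadyStateSet:
    """All roots of P = D by sign-scan bracketing + Brent refinement.

    Stability follows the sign of d(P - D)/dp_t at the root (negative =
    stable); a tangency (derivative ~ 0) is labelled ``"sn"``.  The scan is
    re-run at double resolution and must agree on the root count,
    otherwise the resolution was too coarse and an error is raised.
    """
    d = _degradation_factor(p, p_r) if _factor is None else _factor

    def g(pt):
        return np.asarray(tbx6_production(pt, F, p), dtype=float) - d * np.asarray(
            pt, dtype=float
        )

    def roots_at(n: int) -> list[float]:
        return _scan_roots(g, _p_max(p), n)

    roots = roots_at(n_scan)
    check = roots_at(2 * n_scan)
    if len(roots) != len(check):
        raise RuntimeError(
            f"steady-state scan resolution too coarse: {len(roots)} roots at "
            f"{n_scan} points but {len(check)} at {2 * n_scan}"
        )

    states: list[tuple[float, str]] = []
    eps = 1e-7
    for r in sorted(roots):
        slope = (g(r + eps) - g(max(r - eps, 0.0))) / (eps + min(eps, r))
        if abs(slope) < 1e-4:
            label = "sn"
        else:
            label = "stable" if slope < 0 else "unstable"
        states.append((r, label))
    return SteadyStateSet(F=F, p_r=p_r, states=states)


def sn_degradation_threshold(
    F: float,
    p: ModelParameters,
    tol: float = 1e-6,
    allow_monostable: bool = False,
) -> float:
    """Smallest degradation factor d* at which the switch loses its high state.

    Found by bisection on the factor d in D = d p_t, between the bistable
    regime (three roots) and the collapsed one (one root).  If the system
    is not bistable at d = 1 the threshold is returned as 1.0 when
    ``allow_monostable`` is set, otherwise this is an error.
    """
    def n_roots(d: float) -> int:
        def g(pt):
            return np.asarray(tbx6_production(pt, F, p), dtype=float) - d * np.asarray(
                pt, dtype=float
            )

        # single high-resolution scan: near the tangency the coarse/fine
        # agreement check of find_steady_states would trip by construction
        return len(_scan_roots(g, _p_max(p), 20_000))

    if n_roots(1.0) < 3:
        if allow_monostable:
            return 1.0
        raise ValueError("system is not bistable at degradation factor 1")
    lo, hi = 1.0, 2.0
    while n_roots(hi) >= 3:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no saddle-node found below factor 1e6")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_roots(mid) >= 3:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bifurcation_along_axis(
    p: ModelParameters, p_r_profile: np.ndarray
) -> list[SteadyStateSet]:
    """Steady states at every grid position given a Ripply level profile.

    Reproduces the spatial bifurcation structure: where the Ripply level
    exceeds the local SN threshold the high state is gone and cells must
    fall to the low branch.
    """
    profile = np.asarray(p_r_profile, dtype=float)
    if profile.shape != (p.N,):
        raise ValueError(f"p_r profile must have length N={p.N}")
    x = np.arange(p.N) * p.dx
    return [
        find_steady_states(float(fgf_gradient(xi, p)), float(pr), p)
        for xi, pr in zip(x, profile)
    ]


def phase_diagram(
    p: ModelParameters,
    k6_values: np.ndarray,
    v3_values: np.ndarray,
    t_end: float | None = None,
) -> PhaseDiagram:
    """Boundary-formation outcome over a (K6, nu3) grid of wild-type runs.

    For each point the wild-type simulation runs one full warm-up plus two
    clock cycles; the outcome is success if a new anterior Tbx6 boundary
    forms and persists for at least one clock period (the analysis-module
    boundary detector supplies both).  The y-coordinate reported per point
    is the *achieved* peak degradation factor 1 + eta max(p_r) measured
    near the dpErk border, where Ripply pulses peak; the overlaid SN curve
    is evaluated at the anterior signal level, where a formed boundary has
    to survive.
    """
    from .analysis import detect_tbx6_boundaries  # local import: avoid cycle
    from .simulator import run

    k6_values = np.asarray(k6_values, dtype=float)
    v3_values = np.asarray(v3_values, dtype=float)
    if t_end is None:
        t_end = 2.0 * CLOCK_PERIOD + 10.0
    outcome = np.zeros((len(k6_values), len(v3_values)), dtype=bool)
    achieved = np.full_like(outcome, np.nan, dtype=float)
    errors: list[tuple[int, int, str]] = []

    # SN curve at the anterior signal level (where boundaries must persist;
    # the IFFL input is negligible there, so for n6 = 2 this tracks 1/(2 K6))
    sn = np.array(
        [
            sn_degradation_threshold(
                float(fgf_gradient(0.0, replace(p, K6=k6))),
                replace(p, K6=k6),
                allow_monostable=True,
            )
            for k6 in k6_values
        ]
    )

    near_border = None
    for i, k6 in enumerate(k6_values):
        for j, v3 in enumerate(v3_values):
            pij = replace(p, K6=k6, nu3=v3)
            try:
                out = run(pij, "wild_type", t_end=t_end, record_every=1.0)
            except FloatingPointError as e:  # recorded, not fatal
                errors.append((i, j, str(e)))
                continue
            if near_border is None:
                near_border = np.abs(out.positions - p.x_E) <= 3 * p.dx
            pr_max = float(out.data["p_r"][:, near_border].max())
            achieved[i, j] = 1.0 + pij.eta * pr_max
            events = detect_tbx6_boundaries(out)
            outcome[i, j] = any(
                ev.persistence >= CLOCK_PERIOD for ev in events
            )
    return PhaseDiagram(
        k6_values=k6_values,
        v3_values=v3_values,
        outcome=outcome,
        achieved_factor=achieved,
        sn_factor=sn,
        errors=errors,
    )


def her_oscillation_scan(
    p_t_values: np.ndarray,
    p: ModelParameters,
    tau_H: float = 7.45,
    t_max: float = 500.0,
    discard: float = 250.0,
) -> list[dict]:
    """Single-cell her oscillation amplitude and period versus fixed Tbx6.

    The anterior regime applies (her transcription gated by Tbx6), with a
    constant translation delay tau_H = 7.45 min, the value near the
    anterior border of the Tbx6 domain.  Amplitude is max - min of p_h on
    the retained window; amplitude below 1% of the Her protein scale
    (nu2/mu4) marks oscillation arrest (period reported as nan).
    """
    from scipy.signal import find_peaks

    from .simulator import integrate_her_cell

    results = []
    arrest_level = 0.01 * p.nu2 / p.mu4
    for pt in np.asarray(p_t_values, dtype=float):
        t, trace = integrate_her_cell(p, float(pt), tau_H, t_max=t_max)
        keep = t >= discard
        sig = trace[keep]
        amp = float(sig.max() - sig.min())
        if amp < arrest_level:
            results.append({"p_t": float(pt), "amplitude": 0.0, "period": float("nan")})
            continue
        peaks, _ = find_peaks(sig, prominence=0.2 * amp)
        if len(peaks) < 3:
            raise RuntimeError(
                f"transient not converged at p_t={pt}: fewer than 3 peaks; "
                "increase t_max"
            )
        period = float(np.mean(np.diff(peaks)) * p.dt)
        results.append({"p_t": float(pt), "amplitude": amp, "period": period})
    return results
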