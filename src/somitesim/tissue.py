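"""Moving 1-D PSM geometry: advection, Fgf gradient, dpErk profile, frames.

Coordinates are tailbud-frame by default: x = L is the posterior tip of
the tailbud, x = 0 the anterior end of the modelled tissue; cells advect
anteriorly (toward x = 0) at constant speed u as the body axis extends.
Because every cell shares the same speed, advection on the regular grid is
realised as an exact one-index shift every dx/u minutes (dt is constrained
to divide dx/u), avoiding any resampling: the cell reaching x = 0 is
removed and a new posterior cell is added at x = L as a copy -- state and
delay history -- of its nearest anterior neighbour.

The lab frame is embryo-static: x_lab = x_tailbud + u * t, so somite
boundaries are stationary in it while the tailbud tip recedes posteriorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import DelayHistory
from .params import ModelParameters

__all__ = [
    "TissueState",
    "fgf_gradient",
    "dperk_profile",
    "erk_border",
    "advance_cells",
    "to_lab_frame",
    "from_lab_frame",
]

#: integrated concentration variables, in the order stored in TissueState
STATE_VARS = ("m_h", "M_h", "m_r", "M_r", "p_h", "p_r", "p_t")
#: variables whose past values are needed by some delayed term
DELAYED_VARS = ("M_h", "M_r", "p_h", "p_t", "p_e")
#: everything recorded by the simulator
ALL_VARS = STATE_VARS + ("p_e",)


def _check_domain(x, p: ModelParameters) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > p.L):
        raise ValueError(f"position outside domain [0, {p.L}]")
    return x


def fgf_gradient(x, p: ModelParameters):
    """Posterior signalling gradient F(x) = F0 exp(-(L - x)/x_f).

    Maximal (F0) at the tailbud tip, decaying anteriorly with length scale
    x_f; the shape is fixed in the tailbud reference frame.
    """
    x = _check_domain(x, p)
    return p.F0 * np.exp(-(p.L - x) / p.x_f)


def erk_border(t: float, p: ModelParameters) -> float:
    """Anterior border x_e(t) of the dpErk domain, tailbud frame.

    Fixed mode: x_e = x_E (the dpErk pattern moves with the tailbud).
    Stepwise mode: the border is fixed in the lab frame between resets, so
    in the tailbud frame it recedes anteriorly at speed u from its anchor
    and snaps back to x_E after travelling delta; x_e(0) = x_e0.
    """
    if p.erk_mode == "fixed":
        return p.x_E
    # position along the sawtooth, measured posteriorly from x_E
    phase = (p.x_E - p.x_e0 + p.u * t) % p.delta
    return p.x_E - phase


def dperk_profile(x, t: float, p: ModelParameters):
    """Prescribed dpErk level p_e(x, t).

    Zero anterior to the border x_e(t); rises as
    nu_e * (1 - exp(-q (x - x_e))) toward its plateau posteriorly.
    """
    x = _check_domain(x, p)
    xe = erk_border(t, p)
    return np.where(x < xe, 0.0, p.nu_e * (1.0 - np.exp(-p.q * (x - xe))))


@dataclass
class TissueState:
    """State of the moving cell array plus per-cell delay histories.

    ``data`` maps each variable name to an (N,) array ordered anterior ->
    posterior on the grid {0, dx, ..., L}.  ``t`` is simulation time (min,
    warm-up included; the recording clock is handled by the simulator),
    ``step`` the Euler step count, ``shifts`` the number of advection
    events so far, and ``clamped`` counts negative Euler excursions zeroed.
    """

    params: ModelParameters
    data: dict[str, np.ndarray]
    history: DelayHistory
    t: float = 0.0
    step: int = 0
    shifts: int = 0
    clamped: int = 0
    tau_H_steps: np.ndarray = field(default=None)  # per-cell Her delay, steps

    @property
    def positions(self) -> np.ndarray:
        p = self.params
        return np.arange(p.N) * p.dx

    def copy(self) -> "TissueState":
        import copy

        return copy.deepcopy(self)


def advance_cells(s: TissueState, p: ModelParameters) -> TissueState:
    """One advection event: exact one-index anterior shift of every cell.

    Must be called exactly every dx/u minutes (the simulator schedules it);
    the anteriormost cell leaves the domain, and the new posterior cell at
    x = L copies the full state *and delay history* of its nearest anterior
    neighbour.  Cell count and grid spacing are conserved exactly.
    """
    if abs(s.t - (s.shifts + 1) * p.advection_interval()) > p.dt / 2:
        raise RuntimeError(
            f"advance_cells called off-schedule at t={s.t:g} min "
            f"(shift #{s.shifts + 1} due at {(s.shifts + 1) * p.advection_interval():g} min)"
        )
    for name, arr in s.data.items():
        arr[:-1] = arr[1:]
    s.history.shift_cells()
    s.shifts += 1
    return s


def to_lab_frame(x_tailbud, t: float, p: ModelParameters):
    """Lab-frame position of a tailbud-frame point: x_lab = x + u t."""
    return np.asarray(x_tailbud, dtype=float) + p.u * t


def from_lab_frame(x_lab, t: float, p: ModelParameters):
    """Inverse of :func:`to_lab_frame`."""
    return np.asarray(x_lab, dtype=float) - p.u * t
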