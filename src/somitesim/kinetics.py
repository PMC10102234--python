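"""Per-cell reaction terms of the delayed gene network, and delay machinery.

Every function here is a pure evaluation of one right-hand-side term; the
simulator composes them.  Arguments may be scalars or numpy arrays (one
entry per cell).  Hill terms at argument 0 return exactly 0 (activation)
or 1 (repression) -- no epsilon regularisation.

Delays are handled by :class:`DelayHistory`, a fixed-resolution ring
buffer.  All delays are rounded to the nearest multiple of the Euler step
at configuration time (max rounding error dt/2), which makes every lookup
an exact stored sample.  Histories are attached to cell identity
(Lagrangian): when cells advect, their history columns move with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "hill_activation",
    "hill_repression",
    "her_transcription",
    "ripply_transcription",
    "mature_mrna_rhs",
    "protein_rhs",
    "her_translation_delay",
    "tbx6_production",
    "tbx6_rhs",
    "CellState",
    "DelayHistory",
]


def _check_nonneg(**kwargs) -> None:
    for name, val in kwargs.items():
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"{name} must be non-negative")


def hill_activation(y, K: float, n: float):
    """(y/K)^n / (1 + (y/K)^n): increasing, 0 at y=0, saturating at 1."""
    r = (np.asarray(y, dtype=float) / K) ** n
    return r / (1.0 + r)


def hill_repression(y, K: float, n: float):
    """1 / (1 + (y/K)^n): decreasing, 1 at y=0."""
    return 1.0 / (1.0 + (np.asarray(y, dtype=float) / K) ** n)


def her_transcription(p_h_del, p_t_del, x, p: ModelParameters):
    """her transcription rate, in [0, 1].

    Her protein (delayed by tau_h) represses; Tbx6 activates, but only in
    the anterior PSM (x <= x_h) -- posteriorly other T-box factors stand in
    and the Tbx6 gate is held at 1.  The scenario multiplier
    ``her_tx_scale`` (0 in the her knock-out) scales the whole term.
    """
    _check_nonneg(p_h_del=p_h_del, p_t_del=p_t_del)
    gate = np.where(
        np.asarray(x, dtype=float) <= p.x_h,
        hill_activation(p_t_del, p.K2, p.n2),
        1.0,
    )
    rep = hill_repression(p_h_del, p.K1, p.n1)
    return p.her_tx_scale * rep * gate


def ripply_transcription(p_h_del, p_e_del, p_t_del, p: ModelParameters):
    """ripply transcription rate, in [0, nu1].

    Her and dpErk (both delayed by tau_r) repress; Tbx6 activates.  This is
    the coincidence detector that fires in the gap between Her waves, at
    the anterior skirt of the dpErk gradient, inside the Tbx6 domain.
    """
    _check_nonneg(p_h_del=p_h_del, p_e_del=p_e_del, p_t_del=p_t_del)
    return (
        p.nu1
        * hill_repression(p_h_del, p.K3, p.n3)
        * hill_repression(p_e_del, p.K4, p.n4)
        * hill_activation(p_t_del, p.K5, p.n5)
    )


def mature_mrna_rhs(m, M, splice_rate: float, decay_rate: float):
    """d(mature mRNA)/d(reference time): splicing in, first-order decay out.

    The caller scales by mu1.  her uses decay_rate = 1 (mu1 is its decay);
    ripply uses decay_rate = mu2.
    """
    _check_nonneg(m=m, M=M)
    return splice_rate * np.asarray(m, float) - decay_rate * np.asarray(M, float)


def protein_rhs(M_del, pp, translation_rate: float, decay_rate: float):
    """d(protein)/d(reference time): delayed translation minus decay.

    The caller scales by mu3.  Her uses (nu2, mu4) with the position-graded
    delay tau_H(x); Ripply uses (nu3, mu5) with tau_R.
    """
    _check_nonneg(M_del=M_del, pp=pp)
    return translation_rate * np.asarray(M_del, float) - decay_rate * np.asarray(pp, float)


def her_translation_delay(x, p: ModelParameters):
    """Linear delay gradient tau_H(x) = tau_H0 + (tau_HL - tau_H0) x / L, min.

    The anterior delay exceeds the posterior one (ratio tau_H0/tau_HL up to
    7), which lengthens Her peak-to-peak intervals anteriorly and produces
    the anteriorly slowing expression waves.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > p.L):
        raise ValueError(f"position outside [0, L={p.L}]")
    return p.tau_H0 + (p.tau_HL - p.tau_H0) * x / p.L


def tbx6_production(p_t, F, p: ModelParameters):
    """Tbx6 production speed P: PFL + IFFL, the S-shaped curve of the switch.

    First term: Hill activation of Tbx6 by itself (positive feedback,
    strength set by K6; scaled by ``pfl_scale``, 0 in the no-PFL scenario).
    Second term: the incoherent feedforward read-out of the Fgf signal F --
    activation above K_FA and repression above K_FR (> K_FA) confine the
    drive to intermediate F, i.e. to the mid-PSM.
    """
    _check_nonneg(p_t=p_t, F=F)
    pfl = p.pfl_scale * hill_activation(p_t, p.K6, p.n6)
    iffl = p.gamma * hill_repression(F, p.K_FR, p.nR) * hill_activation(F, p.K_FA, p.nA)
    return pfl + iffl


def tbx6_rhs(p_t, p_r, F, p: ModelParameters):
    """d(Tbx6)/d(reference time): production minus Ripply-boosted decay.

    Degradation rate is (1 + eta * p_r): Ripply raises it proportionally,
    which is what pushes the switch through its saddle-node bifurcation.
    The caller scales by mu3.
    """
    _check_nonneg(p_t=p_t, p_r=p_r, F=F)
    return tbx6_production(p_t, F, p) - (1.0 + p.eta * np.asarray(p_r, float)) * np.asarray(
        p_t, float
    )


# ---------------------------------------------------------------------------
# delay histories


@dataclass
class CellState:
    """Instantaneous state of one cell (all concentrations dimensionless).

    ``p_e`` is prescribed by the dpErk profile, not integrated.
    """

    m_h: float = 0.0
    M_h: float = 0.0
    m_r: float = 0.0
    M_r: float = 0.0
    p_h: float = 0.0
    p_r: float = 0.0
    p_t: float = 0.0
    p_e: float = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_h", "M_h", "m_r", "M_r", "p_h", "p_r", "p_t", "p_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"CellState.{name} must be non-negative")


class DelayHistory:
    """Ring buffer of past samples for a set of variables over all cells.

    Stores ``horizon/dt + 1`` samples per variable at resolution ``dt``.
    ``lookup(name, tau)`` returns the exact sample ``tau`` minutes ago,
    provided ``tau`` is a multiple of ``dt`` within the horizon.  The
    buffer is initialised by pre-filling every slot, which realises the
    prescribed constant initial history of the model.
    """

    def __init__(self, names: tuple[str, ...], n_cells: int, horizon: float, dt: float):
        self.dt = dt
        self.horizon_steps = int(round(horizon / dt))
        self.slots = self.horizon_steps + 1
        self.n_cells = n_cells
        self._buf = {name: np.zeros((self.slots, n_cells)) for name in names}
        self._head = 0  # slot holding the current sample

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._buf)

    def fill(self, name: str, values) -> None:
        """Set the entire history of ``name`` (initial-history prescription)."""
        self._buf[name][:] = np.broadcast_to(values, (self.slots, self.n_cells))

    def push(self, name: str, values) -> None:
        """Record the current sample of ``name`` (call advance() once per step)."""
        self._buf[name][self._head] = values

    def advance(self) -> None:
        self._head = (self._head + 1) % self.slots

    def _steps(self, tau: float) -> int:
        steps = int(round(tau / self.dt))
        if abs(steps * self.dt - tau) > 1e-9:
            raise ValueError(f"delay {tau} is not a multiple of dt={self.dt}")
        if steps < 0 or steps > self.horizon_steps:
            raise ValueError(
                f"delay {tau} outside history horizon {self.horizon_steps * self.dt} min"
            )
        return steps

    def lookup(self, name: str, tau: float) -> np.ndarray:
        """Values of ``name`` exactly ``tau`` minutes before the current sample."""
        return self._buf[name][(self._head - self._steps(tau)) % self.slots]

    def lookup_percell(self, name: str, taus: np.ndarray) -> np.ndarray:
        """Per-cell delays (used for the graded Her translation delay)."""
        steps = np.rint(np.asarray(taus) / self.dt).astype(int)
        if np.any(steps < 0) or np.any(steps > self.horizon_steps):
            raise ValueError("per-cell delay outside history horizon")
        rows = (self._head - steps) % self.slots
        return self._buf[name][rows, np.arange(self.n_cells)]

    def shift_cells(self) -> None:
        """Advect: drop the anteriormost column, duplicate the posteriormost.

        The new posterior cell inherits its anterior neighbour's *entire*
        history, keeping every delayed term well-defined.
        """
        for arr in self._buf.values():
            arr[:, :-1] = arr[:, 1:]
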