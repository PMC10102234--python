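"""Quantification of simulated (or synthetic) spatio-temporal patterns.

Positions are reported in the lab (embryo-static) frame by default, where
somite boundaries are stationary.  The discrete advection scheme realises
the frame shift u*t as whole-cell index shifts, so lab-frame bookkeeping
uses the recorded advection counts and is exact on the grid: a material
cell occupies one fixed lab grid index for the entire recording.

The Tbx6 boundary threshold is parameter-aware: the midpoint of the low
and high stable steady states of the switch at the anterior signal level,
rather than a hard-coded constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .params import CLOCK_PERIOD, ModelParameters
from .simulator import SimulationOutput
from .tissue import fgf_gradient

__all__ = [
    "Kymograph",
    "BoundaryRecord",
    "PeriodProfile",
    "boundary_threshold",
    "tbx6_border_trace",
    "detect_tbx6_boundaries",
    "somite_spacing",
    "build_kymograph",
    "kymograph_to_tailbud",
    "measure_period_profile",
    "wave_arrest_position",
    "domain_extent",
]


@dataclass
class Kymograph:
    """Space-by-time matrix of one variable with explicit axes.

    In the lab frame columns are material cells (fixed lab positions);
    entries are NaN while a cell is outside the modelled domain.
    """

    variable: str
    matrix: np.ndarray          # (n_times, n_positions)
    positions: np.ndarray       # um, monotone increasing
    times: np.ndarray           # min, monotone increasing
    frame: str = "tailbud"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.positions) <= 0):
            raise ValueError("kymograph axes must be strictly increasing")
        finite = self.matrix[np.isfinite(self.matrix)]
        if finite.size and finite.min() < 0:
            raise ValueError("kymograph values must be non-negative")


@dataclass
class BoundaryRecord:
    """One somite-boundary formation event (lab frame)."""

    time: float            # formation time, min
    position: float        # lab-frame position, um
    spacing_cells: float   # distance to the previous boundary, cells (nan for first)
    persistence: float     # how long the border then stayed put, min


def _params_of(out: SimulationOutput) -> ModelParameters:
    return ModelParameters.from_dict(out.params) if out.params else ModelParameters()


def boundary_threshold(p: ModelParameters) -> float:
    """Midpoint of the low/high stable Tbx6 states at the anterior end."""
    from .steady_state import find_steady_states

    sset = find_steady_states(float(fgf_gradient(0.0, p)), 0.0, p)
    stable = sset.stable_roots
    if len(stable) >= 2:
        return 0.5 * (stable[0] + stable[-1])
    # not bistable (e.g. no-PFL variants): half of the largest steady state
    return 0.5 * max(sset.roots) if sset.roots else 0.5


def _border_index(profile: np.ndarray, thr: float) -> int | None:
    """Anteriormost upward crossing of ``thr`` (index of the first high cell)."""
    above = profile >= thr
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    if idx.size:
        return int(idx[0] + 1)
    if above[0]:  # high from the very first cell: border at the domain edge
        return 0
    return None


def tbx6_border_trace(
    out: SimulationOutput, threshold: float | None = None
) -> np.ndarray:
    """Lab-frame anterior Tbx6 border position per snapshot (NaN if none)."""
    if "p_t" not in out.data:
        raise KeyError("output does not contain the Tbx6 field 'p_t'")
    p = _params_of(out)
    thr = boundary_threshold(p) if threshold is None else threshold
    if out.frame == "lab":
        return np.array(
            [
                np.nan if (i := _border_index(row, thr)) is None else out.positions[i]
                for row in out.data["p_t"]
            ]
        )
    idx = np.array(
        [
            np.nan if (i := _border_index(row, thr)) is None else i
            for row in out.data["p_t"]
        ]
    )
    return (idx + out.shift_counts) * p.dx


def detect_tbx6_boundaries(
    out: SimulationOutput,
    min_jump_cells: int = 2,
    threshold: float | None = None,
) -> list[BoundaryRecord]:
    """Somite-boundary events from the Tbx6 field.

    Per snapshot the anterior border is the anteriormost upward crossing of
    the Tbx6 level through the low/high midpoint.  A new boundary is
    recorded when the border jumps posteriorly by at least
    ``min_jump_cells`` between snapshots (lab frame).  Its persistence is
    the time until the border returns anteriorly past the formation
    position -- Tbx6 re-ignition, the failure mode of a switch without
    positive feedback; the 1-2 cells of trailing erosion right after a cut
    and the next cycle's cut (both posterior motions) leave a real somite
    boundary intact and do not count against it.
    """
    p = _params_of(out)
    lab_border = tbx6_border_trace(out, threshold=threshold)
    events: list[BoundaryRecord] = []
    jump = min_jump_cells * p.dx
    for k in range(1, len(lab_border)):
        prev, cur = lab_border[k - 1], lab_border[k]
        if not (np.isfinite(prev) and np.isfinite(cur)):
            continue
        if cur - prev >= jump:
            # persistence: time until the border returns anteriorly past the
            # new position (Tbx6 re-ignition = boundary lost).  Posterior
            # motion -- the trailing edge of erosion, or the next somite
            # forming behind -- does not count against the boundary.
            stay = lab_border[k:]
            lost = stay < cur - 1.5 * p.dx
            n_stay = int(np.argmax(lost)) if lost.any() else len(stay)
            persistence = float(out.times[k + n_stay - 1] - out.times[k])
            spacing = (cur - events[-1].position) / p.dx if events else float("nan")
            events.append(
                BoundaryRecord(
                    time=float(out.times[k]),
                    position=float(cur),
                    spacing_cells=float(spacing),
                    persistence=persistence,
                )
            )
    return events


def somite_spacing(boundaries: list[BoundaryRecord]) -> tuple[float, np.ndarray]:
    """Mean and per-interval spacing between consecutive boundaries, cells."""
    if len(boundaries) < 2:
        raise ValueError("need at least two boundaries to measure spacing")
    spacings = np.array([b.spacing_cells for b in boundaries[1:]])
    return float(spacings.mean()), spacings


def build_kymograph(
    out: SimulationOutput, variable: str, frame: str | None = None
) -> Kymograph:
    """Kymograph of one recorded variable, optionally converted to lab frame.

    Lab-frame conversion reindexes columns to material cells using the
    recorded advection counts (no smoothing, no interpolation); cells
    outside the domain at a given time are NaN.
    """
    if variable not in out.data:
        raise KeyError(
            f"variable {variable!r} not recorded; have {sorted(out.data)}"
        )
    frame = frame or out.frame
    mat = out.data[variable]
    if frame == out.frame:
        return Kymograph(
            variable=variable,
            matrix=mat.copy(),
            positions=out.positions.copy(),
            times=out.times.copy(),
            frame=out.frame,
        )
    if out.frame == "tailbud" and frame == "lab":
        p = _params_of(out)
        nt, N = mat.shape
        n_lab = N + int(out.shift_counts[-1])
        lab = np.full((nt, n_lab), np.nan)
        for k in range(nt):
            s = int(out.shift_counts[k])
            lab[k, s : s + N] = mat[k]
        return Kymograph(
            variable=variable,
            matrix=lab,
            positions=np.arange(n_lab) * p.dx,
            times=out.times.copy(),
            frame="lab",
        )
    raise ValueError(f"cannot convert frame {out.frame!r} -> {frame!r}")


def kymograph_to_tailbud(k: Kymograph, shift_counts: np.ndarray, N: int) -> Kymograph:
    """Undo the lab-frame reindexing (lossless inverse of the conversion)."""
    if k.frame != "lab":
        raise ValueError("expected a lab-frame kymograph")
    nt = len(k.times)
    mat = np.empty((nt, N))
    for row in range(nt):
        s = int(shift_counts[row])
        mat[row] = k.matrix[row, s : s + N]
    return Kymograph(
        variable=k.variable,
        matrix=mat,
        positions=k.positions[:N].copy(),
        times=k.times.copy(),
        frame="tailbud",
    )


@dataclass
class PeriodProfile:
    """Per-position mean peak-to-peak interval with validity flags."""

    positions: np.ndarray
    period: np.ndarray        # min; nan where flagged
    n_peaks: np.ndarray
    flagged: np.ndarray       # True where < min_peaks peaks were found

    def valid(self) -> np.ndarray:
        return ~self.flagged


def measure_period_profile(
    k: Kymograph,
    prominence_frac: float = 0.2,
    min_peaks: int = 3,
    discard: float = 0.0,
) -> PeriodProfile:
    """Mean interval between successive local maxima, per position.

    Peak prominence is ``prominence_frac`` of the largest oscillation
    amplitude in the kymograph (the posterior amplitude for clock fields).
    Positions with fewer than ``min_peaks`` peaks -- including constant
    (non-oscillatory) traces -- are flagged, not dropped.
    """
    keep = k.times >= k.times[0] + discard
    times = k.times[keep]
    mat = k.matrix[keep]
    amp_global = np.nanmax(mat) - np.nanmin(mat)
    if amp_global <= 0:
        return PeriodProfile(
            positions=k.positions.copy(),
            period=np.full(len(k.positions), np.nan),
            n_peaks=np.zeros(len(k.positions), dtype=int),
            flagged=np.ones(len(k.positions), dtype=bool),
        )
    periods = np.full(len(k.positions), np.nan)
    n_peaks = np.zeros(len(k.positions), dtype=int)
    flagged = np.ones(len(k.positions), dtype=bool)
    for j in range(len(k.positions)):
        col = mat[:, j]
        ok = np.isfinite(col)
        if ok.sum() < min_peaks:
            continue
        sig = col[ok]
        tt = times[ok]
        peaks, _ = find_peaks(sig, prominence=prominence_frac * amp_global)
        n_peaks[j] = len(peaks)
        if len(peaks) >= min_peaks:
            periods[j] = float(np.mean(np.diff(tt[peaks])))
            flagged[j] = False
    return PeriodProfile(
        positions=k.positions.copy(), period=periods, n_peaks=n_peaks, flagged=flagged
    )


def wave_arrest_position(
    k: Kymograph,
    window: float | None = None,
    amplitude_frac: float = 0.2,
) -> float:
    """Anteriormost position still oscillating at the end of the recording.

    Oscillation amplitude is max - min over a trailing window (default:
    half a clock period, so recently arrested cells score low); a position
    counts as oscillating if its amplitude exceeds ``amplitude_frac`` of
    the largest amplitude in the window.  Raises if nothing oscillates.
    """
    if window is None:
        window = 0.5 * CLOCK_PERIOD
    sel = k.times >= k.times[-1] - window
    if sel.sum() < 3:
        raise ValueError("window too short for the recorded sampling")
    tail = k.matrix[sel]
    amp = np.zeros(tail.shape[1])
    has_data = np.isfinite(tail).any(axis=0)
    if has_data.any():
        sub = tail[:, has_data]
        amp[has_data] = np.nanmax(sub, axis=0) - np.nanmin(sub, axis=0)
    ref = amp.max()
    if ref <= 0:
        raise ValueError("no oscillation anywhere in the trailing window")
    osc = amp >= amplitude_frac * ref
    return float(k.positions[np.nonzero(osc)[0][0]])


def domain_extent(
    snapshot: np.ndarray,
    positions: np.ndarray,
    threshold_frac: float = 0.2,
) -> tuple[float, float] | None:
    """(anterior edge, posterior edge) where the level exceeds a fraction of max.

    Returns None (empty domain) for an all-zero snapshot.
    """
    snap = np.asarray(snapshot, dtype=float)
    if np.any(snap < 0):
        raise ValueError("snapshot must be non-negative")
    peak = snap.max()
    if peak <= 0:
        return None
    above = np.nonzero(snap > threshold_frac * peak)[0]
    return float(positions[above[0]]), float(positions[above[-1]])
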