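"""Synthetic spatio-temporal profiles with known ground truth, plus disk IO.

The generators emulate the qualitative features of simulator output --
step-like Tbx6 borders, boxcar expression domains, anteriorly slowing
traveling waves, sawtooth border-jump schedules -- with exactly known
edges, periods and event times, so every pattern detector in
:mod:`somitesim.analysis` can be tested independently of the simulator.
Optional additive Gaussian noise (clipped at zero) probes detector
robustness; the biological model itself is deterministic.

On-disk layout: one TSV per variable (first column time, header row the
positions) plus a JSON manifest carrying the schema version, parameters,
scenario, frame and -- for fixtures -- the ground-truth annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .params import ModelParameters, read_config  # noqa: F401  (re-exported)
from .simulator import SimulationOutput

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "write_output",
    "read_output",
    "read_config",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

KINDS = ("step", "boxcar", "sigmoid", "traveling_wave", "sawtooth_border")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic space-time dataset.

    ``kind``-specific entries go in ``params``:

    * ``step``: ``edge`` (um), ``low``, ``high``.
    * ``boxcar``: ``left``, ``right`` (um), ``level``.
    * ``sigmoid``: ``edge`` (um), ``width`` (um), ``high``.
    * ``traveling_wave``: ``period_anterior``/``period_posterior`` (min,
      linear profile T(x)), ``wavelength`` (um), ``amplitude`` or
      amplitude profile endpoints ``amp_anterior``/``amp_posterior``,
      optional ``arrest_x`` (um) anterior of which the amplitude is zero.
    * ``sawtooth_border``: ``start`` (um), ``jump`` (um), ``every`` (min)
      -- the border sits still and jumps posteriorly by ``jump`` every
      ``every`` minutes; ``high`` level posterior of the border.
    """

    kind: str
    N: int = 41
    dx: float = 10.0
    t_end: float = 120.0
    record_every: float = 1.0
    params: dict[str, Any] = field(default_factory=dict)
    noise: float = 0.0
    seed: int = 0
    variable: str = "p_t"


def generate_fixture(spec: FixtureSpec) -> tuple[SimulationOutput, dict[str, Any]]:
    """Deterministic synthetic dataset plus its ground-truth annotations.

    Output is lab-frame (no advection; ``shift_counts`` all zero), shaped
    exactly like simulator output so the analysis operations consume it
    unchanged.
    """
    if spec.kind not in KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; valid: {KINDS}")
    x = np.arange(spec.N) * spec.dx
    times = np.arange(0.0, spec.t_end + 1e-9, spec.record_every)
    P = spec.params
    truth: dict[str, Any] = {"kind": spec.kind}

    if spec.kind == "step":
        edge = float(P.get("edge", x[-1] / 2))
        low, high = float(P.get("low", 0.0)), float(P.get("high", 1.0))
        mat = np.where(x >= edge, high, low)[None, :].repeat(len(times), 0).astype(float)
        truth["edge"] = edge
    elif spec.kind == "boxcar":
        left = float(P.get("left", x[-1] / 4))
        right = float(P.get("right", 3 * x[-1] / 4))
        level = float(P.get("level", 1.0))
        mat = np.where((x >= left) & (x <= right), level, 0.0)
        mat = mat[None, :].repeat(len(times), 0)
        truth["left"], truth["right"] = left, right
    elif spec.kind == "sigmoid":
        edge = float(P.get("edge", x[-1] / 2))
        width = float(P.get("width", spec.dx))
        high = float(P.get("high", 1.0))
        prof = high / (1.0 + np.exp(-(x - edge) / width))
        mat = prof[None, :].repeat(len(times), 0)
        truth["edge"] = edge
    elif spec.kind == "traveling_wave":
        Ta = float(P.get("period_anterior", 60.0))
        Tp = float(P.get("period_posterior", 30.0))
        lam = float(P.get("wavelength", 150.0))
        A0 = float(P.get("amplitude", 1.0))
        Aa = float(P.get("amp_anterior", A0))
        Ap = float(P.get("amp_posterior", A0))
        arrest = P.get("arrest_x")
        Tx = Ta + (Tp - Ta) * x / x[-1]
        Ax = Aa + (Ap - Aa) * x / x[-1]
        if arrest is not None:
            Ax = np.where(x < float(arrest), 0.0, Ax)
        phase = 2 * np.pi * (times[:, None] / Tx[None, :] - x[None, :] / lam)
        mat = Ax[None, :] * (1.0 + np.sin(phase)) / 2.0
        truth["period_profile"] = Tx.tolist()
        if arrest is not None:
            truth["arrest_x"] = float(arrest)
    else:  # sawtooth_border
        start = float(P.get("start", 100.0))
        jump = float(P.get("jump", 60.0))
        every = float(P.get("every", 30.0))
        high = float(P.get("high", 1.0))
        n_jumps = np.floor(times / every)
        border = start + jump * n_jumps
        mat = np.where(x[None, :] >= border[:, None], high, 0.0)
        truth["jump_times"] = [float(k * every) for k in range(1, int(times[-1] // every) + 1)]
        truth["border_positions"] = [
            float(start + jump * k) for k in range(1, int(times[-1] // every) + 1)
        ]

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        mat = np.clip(mat + rng.normal(0.0, spec.noise, mat.shape), 0.0, None)

    out = SimulationOutput(
        times=times,
        positions=x,
        data={spec.variable: mat},
        shift_counts=np.zeros(len(times), dtype=int),
        frame="lab",
        scenario=f"fixture:{spec.kind}",
        params={},
    )
    return out, truth


# ---------------------------------------------------------------------------
# disk round trip


def write_output(out: SimulationOutput, directory: str | Path,
                 truth: dict[str, Any] | None = None) -> None:
    """Write one TSV per variable plus a JSON manifest (lossless round trip)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, mat in out.data.items():
        df = pd.DataFrame(mat, columns=[f"{p:g}" for p in out.positions])
        df.insert(0, "time", out.times)
        df.to_csv(d / f"{name}.tsv", sep="\t", index=False, float_format="%.17g")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "variables": sorted(out.data),
        "frame": out.frame,
        "scenario": out.scenario,
        "params": out.params,
        "shift_counts": out.shift_counts.tolist(),
        "clamped": out.clamped,
    }
    if truth is not None:
        manifest["ground_truth"] = truth
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def read_output(directory: str | Path) -> SimulationOutput:
    """Read a directory written by :func:`write_output`.

    A schema-version mismatch or a missing variable table is a loud error.
    """
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"schema version mismatch: file has {version}, reader expects {SCHEMA_VERSION}"
        )
    data = {}
    times = positions = None
    for name in manifest["variables"]:
        path = d / f"{name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing variable table {name}.tsv in {d}")
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        times = df["time"].to_numpy()
        positions = np.array([float(c) for c in df.columns[1:]])
        data[name] = df.iloc[:, 1:].to_numpy()
    return SimulationOutput(
        times=times,
        positions=positions,
        data=data,
        shift_counts=np.asarray(manifest["shift_counts"], dtype=int),
        frame=manifest["frame"],
        scenario=manifest["scenario"],
        params=manifest["params"],
        clamped=manifest.get("clamped", 0),
    )
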