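"""Excitability maps: feature-detection and latency sweeps over (mu0, c).

These operations characterise how the microlaser neuron responds to bit
patterns as a function of the base pump ``mu0`` and the pulse amplitude
``c`` (at fixed bit/pulse times): the minimum run of consecutive "1"s
needed to elicit a spike, the region where the asymmetric pattern
"10111" is distinguishable from its mirror "11101", the spike-latency
difference between 3-run and 4-run inputs, and the pump value at which
the laser starts self-pulsing with no input at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coding import PumpProgram, constant_pump, encode_bits
from .model import (
    DEFAULT_MIN_SEPARATION,
    DEFAULT_PADDING,
    DEFAULT_SPIKE_THRESHOLD,
    LaserParams,
    LatencyResult,
    SpikeTrain,
    detect_spikes,
    integrate,
    latency,
    steady_state,
)

__all__ = [
    "ParameterMap",
    "simulate_bits",
    "first_spike_latency",
    "min_run_to_spike",
    "pattern_discriminates",
    "latency_difference",
    "self_pulsing_onset",
    "sweep",
    "run_pattern",
    "clear_cache",
]

#: Frame width used when embedding run-length inputs; matches the 5-pixel
#: receptive fields of the digit task.
DEFAULT_FRAME = 5


def run_pattern(k: int, frame: int = DEFAULT_FRAME, alignment: str = "left") -> str:
    """A run of ``k`` ones embedded in a ``frame``-bit sequence.

    ``alignment`` places the run at the start ("left") or centre
    ("center") of the frame.
    """
    if not 0 <= k <= frame:
        raise ValueError(f"run length {k} does not fit a {frame}-bit frame")
    if alignment == "left":
        return "1" * k + "0" * (frame - k)
    if alignment == "center":
        lead = (frame - k) // 2
        return "0" * lead + "1" * k + "0" * (frame - k - lead)
    raise ValueError("alignment must be 'left' or 'center'")


@lru_cache(maxsize=4096)
def _simulate_cached(
    bits: str,
    mu0: float,
    c: float,
    tau_b: float,
    tau_p: float,
    tau_d: float,
    t_pad: float,
    params: LaserParams,
    threshold: float,
    min_separation: float,
) -> SpikeTrain:
    pump = PumpProgram(bits, mu0, c, tau_b, tau_p, tau_d, t_pad)
    traj = integrate(params, pump)
    return detect_spikes(
        traj, threshold=threshold, min_separation=min_separation,
        reference_time=pump.onset,
    )


def simulate_bits(
    bits,
    mu0: float,
    c: float,
    tau_b: float = 50.0,
    tau_p: float = 30.0,
    tau_d: float = 0.0,
    t_pad: float = DEFAULT_PADDING,
    params: LaserParams = LaserParams(),
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> SpikeTrain:
    """Integrate a bit-sequence pump program and detect spikes.

    Results are memoised on the full argument tuple: sweeps and the digit
    classifiers repeatedly probe identical (pattern, tuning) pairs, and
    the ODE solution is deterministic, so each distinct stimulus is
    integrated once per process.
    """
    bits_str = "".join(str(int(b)) for b in bits) if not isinstance(bits, str) else bits
    return _simulate_cached(
        bits_str, float(mu0), float(c), float(tau_b), float(tau_p),
        float(tau_d), float(t_pad), params, float(threshold),
        float(min_separation),
    )


def clear_cache() -> None:
    """Drop memoised simulations (mainly for tests)."""
    _simulate_cached.cache_clear()


def first_spike_latency(bits, mu0, c, tau_b=50.0, tau_p=30.0, **kw) -> float:
    """Latency of the first spike after stimulus onset; +inf if none."""
    spikes = simulate_bits(bits, mu0, c, tau_b, tau_p, **kw)
    return latency(spikes).tau_l


def min_run_to_spike(
    params: LaserParams,
    mu0: float,
    c: float,
    tau_b: float = 50.0,
    tau_p: float = 30.0,
    max_run: int = DEFAULT_FRAME,
    frame: int = DEFAULT_FRAME,
    alignment: str = "left",
    t_pad: float = DEFAULT_PADDING,
) -> int | None:
    """Smallest number of consecutive "1" bits that elicits a spike.

    Returns 0 when the unperturbed laser spikes by itself (self-pulsing),
    ``k`` when runs shorter than ``k`` are silent but a ``k``-run fires,
    and ``None`` when even ``max_run`` consecutive pulses stay silent.
    Runs are embedded left-aligned in a ``frame``-bit sequence.
    """
    for k in range(0, max_run + 1):
        spikes = simulate_bits(
            run_pattern(k, frame, alignment), mu0, c, tau_b, tau_p,
            t_pad=t_pad, params=params,
        )
        if spikes.n_spikes > 0:
            return k
    return None


def pattern_discriminates(
    params: LaserParams,
    mu0: float,
    c: float,
    fire_pattern: str = "10111",
    reject_pattern: str = "11101",
    tau_b: float = 50.0,
    tau_p: float = 30.0,
    t_pad: float = DEFAULT_PADDING,
) -> bool:
    """True iff ``fire_pattern`` elicits >= 1 spike and ``reject_pattern`` none."""
    if len(fire_pattern) != len(reject_pattern):
        raise ValueError("patterns must have equal length")
    fire = simulate_bits(fire_pattern, mu0, c, tau_b, tau_p, t_pad=t_pad, params=params)
    if fire.n_spikes == 0:
        return False
    reject = simulate_bits(
        reject_pattern, mu0, c, tau_b, tau_p, t_pad=t_pad, params=params
    )
    return reject.n_spikes == 0


def latency_difference(
    params: LaserParams,
    mu0: float,
    c: float,
    tau_b: float = 50.0,
    tau_p: float = 30.0,
    frame: int = DEFAULT_FRAME,
    t_pad: float = DEFAULT_PADDING,
) -> LatencyResult:
    """Latency gap between a 3-run and a 4-run input, both left-aligned.

    ``delta_tau_l = tau(3) - tau(4)`` is positive whenever both fire (the
    stronger summed stimulus crosses the excitable threshold earlier) and
    diverges as the 3-run input approaches the excitable threshold;
    infinities propagate when either input stays silent.
    """
    tau3 = first_spike_latency(
        run_pattern(3, frame), mu0, c, tau_b, tau_p, t_pad=t_pad, params=params
    )
    tau4 = first_spike_latency(
        run_pattern(4, frame), mu0, c, tau_b, tau_p, t_pad=t_pad, params=params
    )
    return LatencyResult(tau_l=tau3, tau3=tau3, tau4=tau4)


def self_pulsing_onset(
    params: LaserParams,
    mu0_lo: float = 2.0,
    mu0_hi: float = 3.2,
    resolution: float = 0.01,
    horizon: float = 5000.0,
) -> float:
    """Pump value at which the laser starts spiking with zero input.

    Bisects the predicate ">= 1 spike within ``horizon`` at constant pump"
    between a quiet ``mu0_lo`` and a self-pulsing ``mu0_hi``.  Every
    candidate is integrated from the quiet steady state of the bracket's
    low end, so the bracket endpoints define a single reference initial
    condition for the whole search.
    """
    if not mu0_lo < mu0_hi:
        raise ValueError("require mu0_lo < mu0_hi")
    init = steady_state(params, mu0_lo)

    def spiking(mu0: float) -> bool:
        traj = integrate(params, constant_pump(mu0, horizon), init=init)
        return detect_spikes(traj).n_spikes > 0

    lo, hi = mu0_lo, mu0_hi
    if spiking(lo):
        raise ValueError(f"mu0_lo={lo} already self-pulsing; invalid bracket")
    if not spiking(hi):
        raise ValueError(f"mu0_hi={hi} not self-pulsing; invalid bracket")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spiking(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class ParameterMap:
    """Result of a two-parameter sweep: one scalar per (mu0, c) cell.

    ``values[i, j]`` corresponds to ``mu0_grid[i]``, ``c_grid[j]``.
    Non-finite entries encode "no spike"/undefined cells; ``kind`` names
    the swept quantity and ``fixed`` records the frozen timing parameters.
    """

    kind: str
    mu0_grid: np.ndarray
    c_grid: np.ndarray
    values: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu0_grid = np.asarray(self.mu0_grid, dtype=float)
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mu0_grid), len(self.c_grid)):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({len(self.mu0_grid)}, {len(self.c_grid)})"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (mu0, c, value)."""
        mu, cc = np.meshgrid(self.mu0_grid, self.c_grid, indexing="ij")
        return pd.DataFrame(
            {"mu0": mu.ravel(), "c": cc.ravel(), "value": self.values.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def log10_values(self, sentinel: float = np.nan) -> np.ndarray:
        """log10 of strictly positive finite values; others -> sentinel."""
        out = np.full_like(self.values, sentinel)
        ok = np.isfinite(self.values) & (self.values > 0)
        out[ok] = np.log10(self.values[ok])
        return out


_MAP_KINDS = ("minrun", "discriminate", "latency")


def sweep(
    map_kind: str,
    mu0_grid: Sequence[float],
    c_grid: Sequence[float],
    fixed: dict | None = None,
    params: LaserParams = LaserParams(),
) -> ParameterMap:
    """Evaluate a per-point operation over a (mu0, c) grid.

    ``map_kind`` selects the cell operation: "minrun"
    (:func:`min_run_to_spike`; None encoded as NaN), "discriminate"
    (:func:`pattern_discriminates`; 0/1), or "latency"
    (:func:`latency_difference`; delta, +inf propagated).  ``fixed``
    overrides timing parameters (tau_b, tau_p, and per-kind extras such
    as fire/reject patterns).  Cells are evaluated in deterministic
    row-major order.
    """
    if map_kind not in _MAP_KINDS:
        raise ValueError(f"map_kind must be one of {_MAP_KINDS}")
    fixed = dict(fixed or {})
    tau_b = float(fixed.pop("tau_b", 50.0))
    tau_p = float(fixed.pop("tau_p", 30.0))
    fire = fixed.pop("fire_pattern", "10111")
    reject = fixed.pop("reject_pattern", "11101")
    max_run = int(fixed.pop("max_run", DEFAULT_FRAME))
    if fixed:
        raise ValueError(f"unknown fixed parameters: {sorted(fixed)}")

    mu0_grid = np.asarray(mu0_grid, dtype=float)
    c_grid = np.asarray(c_grid, dtype=float)
    values = np.empty((len(mu0_grid), len(c_grid)))
    for i, mu0 in enumerate(mu0_grid):
        for j, c in enumerate(c_grid):
            if map_kind == "minrun":
                k = min_run_to_spike(params, mu0, c, tau_b, tau_p, max_run=max_run)
                values[i, j] = np.nan if k is None else k
            elif map_kind == "discriminate":
                values[i, j] = float(
                    pattern_discriminates(params, mu0, c, fire, reject, tau_b, tau_p)
                )
            else:
                values[i, j] = latency_difference(
                    params, mu0, c, tau_b, tau_p
                ).delta_tau_l
    return ParameterMap(
        kind=map_kind,
        mu0_grid=mu0_grid,
        c_grid=c_grid,
        values=values,
        fixed={"tau_b": tau_b, "tau_p": tau_p},
    )
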