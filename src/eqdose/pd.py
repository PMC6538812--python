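"""Cell-population response: logistic growth with time-dependent death rates.

The cell count ``N(t)`` follows a logistic law whose net rate is reduced by
a treatment-induced death rate after drug application at ``t = 0``::

    dN/dt = (k_p - k_d(t)) * N * (1 - N / theta)

Two empirical death kernels represent distinct death modes and are combined
with a convex weight ``lam``:

* an immediate, stable rate ``k_d_a`` (apoptosis-like), and
* a transient kernel ``k_d_b * r * t * exp(1 - r*t)`` (mitotic-catastrophe-
  like) that ramps to its maximum ``k_d_b`` at ``t = 1/r`` and decays,
  allowing the population to recover.

Before treatment (``t < 0``) the death rate is zero.  Because (1-lam)*k_d_a
and lam*k_d_b enter only as products, the weight is not identifiable from
count data and is carried as a fixed configuration value (see docs).

The equation linearises under ``u = theta/N - 1`` (``du/dt = -g(t) u``), so
the solution is closed form given the integral of the net rate, which both
kernels admit analytically.  ``simulate_counts`` is therefore exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["PDParams", "CellCountSeries", "death_rate", "simulate_counts"]


@dataclass(frozen=True)
class PDParams:
    """Logistic-growth / death-rate parameters.

    k_p : proliferation rate, 1/h.
    theta : carrying capacity of the experimental system, cells.
    k_d_a : stable post-treatment death rate, 1/h.
    k_d_b : peak transient death rate, 1/h.
    r : induction/decay rate of the transient kernel, 1/h.
    lam : convex weight in [0, 1] mixing the stable (lam=0) and transient
        (lam=1) kernels.
    """

    k_p: float
    theta: float
    k_d_a: float = 0.0
    k_d_b: float = 0.0
    r: float = 0.1
    lam: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_p", "k_d_a", "k_d_b", "r"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite nonnegative rate, got {v!r}")
            object.__setattr__(self, name, v)
        theta = float(self.theta)
        if not np.isfinite(theta) or theta <= 0:
            raise ValueError(f"theta must be positive, got {theta!r}")
        object.__setattr__(self, "theta", theta)
        lam = float(self.lam)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {lam!r}")
        object.__setattr__(self, "lam", lam)

    def replace(self, **changes: float) -> "PDParams":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "k_p": self.k_p,
            "theta": self.theta,
            "k_d_a": self.k_d_a,
            "k_d_b": self.k_d_b,
            "r": self.r,
            "lam": self.lam,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "PDParams":
        unknown = set(data) - {"k_p", "theta", "k_d_a", "k_d_b", "r", "lam"}
        if unknown:
            raise ValueError(f"unknown PDParams fields: {sorted(unknown)}")
        return cls(**dict(data))

    @property
    def response_vector(self) -> np.ndarray:
        """The death-response parameters [k_d_a, k_d_b, r] used in matching."""
        return np.array([self.k_d_a, self.k_d_b, self.r])


def death_rate(t, p: PDParams) -> np.ndarray:
    """Treatment-induced death rate k_d(t), 1/h; zero before treatment."""
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    transient = p.r * tp * np.exp(1.0 - p.r * tp)
    rate = (1.0 - p.lam) * p.k_d_a + p.lam * p.k_d_b * transient
    return np.where(t < 0.0, 0.0, rate)


def _death_rate_integral(t, p: PDParams) -> np.ndarray:
    """Integral of k_d from 0 to max(t, 0), closed form."""
    tp = np.maximum(np.asarray(t, dtype=float), 0.0)
    stable = (1.0 - p.lam) * p.k_d_a * tp
    if p.r > 0.0 and p.lam > 0.0 and p.k_d_b > 0.0:
        rt = p.r * tp
        transient = p.lam * p.k_d_b * np.e * (1.0 - np.exp(-rt) * (1.0 + rt)) / p.r
    else:
        transient = 0.0
    return stable + transient


def simulate_counts(p: PDParams, N0: float, times) -> np.ndarray:
    """Noise-free cell counts at the sample times (treatment at t = 0).

    ``N0`` is the count at ``times[0]``; negative (pre-treatment) times are
    allowed and grow at the untreated logistic rate.  Exact closed-form
    solution of the time-varying logistic equation.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    N0 = float(N0)
    if not np.isfinite(N0) or N0 < 0:
        raise ValueError(f"N0 must be a finite nonnegative count, got {N0!r}")
    if N0 == 0.0:
        return np.zeros_like(times)
    t0 = times[0]
    # cumulative net growth exponent relative to the anchor time
    G = p.k_p * (times - t0) - (_death_rate_integral(times, p) - _death_rate_integral(t0, p))
    u0 = p.theta / N0 - 1.0
    if u0 == 0.0:
        return np.full_like(times, p.theta)
    if u0 > 0.0:
        # overflow-safe: N = theta / (1 + exp(log(u0) - G))
        return p.theta * np.exp(-np.logaddexp(0.0, np.log(u0) - G))
    with np.errstate(over="ignore"):
        denom = 1.0 + u0 * np.exp(-G)
    if np.any(denom <= 0):
        raise ValueError("trajectory diverges: started above theta with net death")
    return p.theta / denom


@dataclass(frozen=True)
class CellCountSeries:
    """Replicate cell-count timecourses on a shared time grid.

    counts has shape (n_replicates, n_times); treatment is at t = 0 and
    pre-treatment (negative) times are allowed.
    """

    times: np.ndarray
    counts: np.ndarray
    replicates: tuple = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if counts.shape[1] != times.size:
            raise ValueError("counts must have one column per time point")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        reps = tuple(self.replicates) if self.replicates else tuple(range(counts.shape[0]))
        if len(reps) != counts.shape[0]:
            raise ValueError("one replicate id per row required")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "replicates", reps)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for rep, row in zip(self.replicates, self.counts):
            frames.append(pd.DataFrame({"time_h": self.times, "replicate": rep, "count": row}))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CellCountSeries":
        required = {"time_h", "replicate", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        wide = df.pivot_table(index="replicate", columns="time_h", values="count")
        return cls(
            times=wide.columns.to_numpy(dtype=float),
            counts=wide.to_numpy(dtype=float),
            replicates=tuple(wide.index),
        )
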