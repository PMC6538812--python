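"""Nonlinear least-squares estimation of PK, PD and Hill parameters.

Three model classes follow the familiar fit-object pattern: construct a
model from data, call :meth:`fit`, and receive a results object carrying
estimates, 95% confidence intervals, residual diagnostics and a
``summary()`` table.

* :class:`UptakeModel` — fits the three-compartment rates to intracellular
  drug timecourses.  The observable is the whole-cell concentration
  ``C_F + C_B`` (fluorescence does not distinguish free from bound drug);
  ``v_ratio`` is fixed from configuration because only ``k_EF * v_ratio``
  is identifiable from intracellular data.
* :class:`ResponseModel` — fits the logistic/death-rate model to replicate
  cell counts, with pre-treatment points anchoring the proliferation rate.
* :class:`HillModel` — fits the sigmoidal survival curve
  ``S(D) = E_inf + (1 - E_inf) / (1 + (D / EC50)^h)`` against either the
  extracellular dose or the equivalent dose.

All fitters pool squared residuals across replicates, use a deterministic
Latin-hypercube multistart over box bounds (log-scaled where parameters
span decades) and report curvature-based (Jacobian) asymptotic confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .pd import PDParams, simulate_counts
from .pk import PKParams, TreatmentCourse, simulate_pk

__all__ = [
    "UptakeModel",
    "UptakeResults",
    "ResponseModel",
    "ResponseResults",
    "HillModel",
    "HillResults",
]


# ---------------------------------------------------------------------------
# shared multistart least-squares machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Param:
    """One free parameter: natural-scale bounds plus internal transform."""

    name: str
    lo: float
    hi: float
    scale: str = "log"  # "log" -> optimise log10(x); "linear" -> optimise x

    def to_internal(self, x: float) -> float:
        return np.log10(x) if self.scale == "log" else x

    def from_internal(self, u: float) -> float:
        return 10.0**u if self.scale == "log" else u

    @property
    def internal_bounds(self) -> tuple:
        return (self.to_internal(self.lo), self.to_internal(self.hi))


def _starts(specs: Sequence[_Param], n_starts: int, seed: int) -> np.ndarray:
    lo = np.array([s.internal_bounds[0] for s in specs])
    hi = np.array([s.internal_bounds[1] for s in specs])
    mid = 0.5 * (lo + hi)
    pts = [mid]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(specs), seed=seed)
        unit = sampler.random(n_starts - 1)
        pts.extend(lo + unit * (hi - lo))
    return np.array(pts)


def _multistart(residual, specs, n_starts, seed, extra_starts=()):
    """Run least_squares from LHS starts; return (best result, all costs)."""
    lo = np.array([s.internal_bounds[0] for s in specs])
    hi = np.array([s.internal_bounds[1] for s in specs])
    starts = list(_starts(specs, n_starts, seed)) + [np.clip(x, lo, hi) for x in extra_starts]
    best = None
    costs = []
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        costs.append(res.cost)
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimizer starts failed")
    return best, np.array(costs)


def _natural(specs: Sequence[_Param], u: np.ndarray) -> dict:
    return {s.name: s.from_internal(v) for s, v in zip(specs, u)}


def _confidence(res, specs, n_obs):
    """95% CIs from the local curvature of the pooled objective.

    Returns (conf_int, half_widths, at_bound) keyed by parameter name.
    conf_int is on the natural scale (asymmetric for log-scaled params).
    """
    dof = max(n_obs - len(specs), 1)
    s2 = 2.0 * res.cost / dof
    jac = res.jac
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(len(specs), np.nan)
    tq = stats.t.ppf(0.975, dof)
    conf_int, half_widths, at_bound = {}, {}, set()
    for i, spec in enumerate(specs):
        u = res.x[i]
        lo_i, hi_i = spec.internal_bounds
        span = hi_i - lo_i
        if span > 0 and (u - lo_i < 1e-6 * span or hi_i - u < 1e-6 * span):
            at_bound.add(spec.name)
        lo_nat = spec.from_internal(u - tq * se[i])
        hi_nat = spec.from_internal(u + tq * se[i])
        conf_int[spec.name] = (min(lo_nat, hi_nat), max(lo_nat, hi_nat))
        half_widths[spec.name] = 0.5 * (conf_int[spec.name][1] - conf_int[spec.name][0])
    return conf_int, half_widths, at_bound


class _ResultsBase:
    """Common surface of all fit results."""

    def __init__(self, model, specs, res, costs, n_obs, residuals):
        self.model = model
        self._specs = specs
        self._x_internal = res.x.copy()
        self.estimates = _natural(specs, res.x)
        self.conf_int, self.half_widths, self.at_bound = _confidence(res, specs, n_obs)
        self.converged = bool(res.success)
        self.cost = float(res.cost)
        self.start_costs = costs
        self.n_obs = int(n_obs)
        self.residuals = residuals
        self.mae = float(np.mean(np.abs(residuals)))
        self.degenerate = bool(self.at_bound)

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            f"  observations: {self.n_obs}   converged: {self.converged}",
            f"  mean |residual|: {self.mae:.6g}",
            f"  {'parameter':<10} {'estimate':>12} {'95% CI':>28}",
        ]
        for name, value in self.estimates.items():
            lo, hi = self.conf_int[name]
            flag = "  (at bound)" if name in self.at_bound else ""
            lines.append(f"  {name:<10} {value:>12.5g} [{lo:>12.5g}, {hi:>12.5g}]{flag}")
        return "\n".join(lines)

    def bootstrap_conf_int(self, n_boot: int = 500, seed: int = 0) -> dict:
        """Residual-bootstrap 95% intervals (percentile method).

        Resamples the fitted residuals with replacement, refits from the
        point estimate, and returns per-parameter (lo, hi) bounds.  Slower
        but more honest than the curvature intervals near bounds or on
        weakly identified ridges.
        """
        if not hasattr(self, "_x_internal"):
            raise ValueError("no converged fit to bootstrap")
        residual = self.model._residual
        u_hat = self._x_internal
        r_hat = residual(u_hat)
        lo = np.array([s.internal_bounds[0] for s in self._specs])
        hi = np.array([s.internal_bounds[1] for s in self._specs])
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, len(self._specs)))
        for b in range(n_boot):
            e_star = rng.choice(r_hat, size=r_hat.size, replace=True)
            res = least_squares(
                lambda u: residual(u) - r_hat + e_star, u_hat,
                bounds=(lo, hi), method="trf",
            )
            draws[b] = [s.from_internal(v) for s, v in zip(self._specs, res.x)]
        return {
            s.name: (float(np.percentile(draws[:, i], 2.5)),
                     float(np.percentile(draws[:, i], 97.5)))
            for i, s in enumerate(self._specs)
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.summary()


# ---------------------------------------------------------------------------
# PK uptake fitting
# ---------------------------------------------------------------------------

_PK_DEFAULT_BOUNDS = {"k_EF": (1e-9, 1e-2), "k_FE": (1e-4, 10.0), "k_FB": (1e-4, 10.0)}


class UptakeModel:
    """Fit the three-compartment uptake rates to intracellular timecourses.

    Parameters
    ----------
    times : array, hours
        Shared sample grid within the course horizon.
    observed : array (n_replicates, n_times) or (n_times,)
        Whole-cell drug concentration ``C_F + C_B`` in nM.
    course : TreatmentCourse
        The drug schedule applied to every replicate.
    v_ratio : float
        Fixed extracellular/intracellular volume ratio.
    bounds : mapping, optional
        Per-rate (lo, hi) box bounds overriding the nM/hour-scale defaults.
    """

    param_names = ("k_EF", "k_FE", "k_FB")

    def __init__(self, times, observed, course: TreatmentCourse, v_ratio: float = 1.0e4,
                 bounds: Mapping | None = None):
        self.times = np.asarray(times, dtype=float)
        obs = np.atleast_2d(np.asarray(observed, dtype=float))
        if obs.shape[1] != self.times.size:
            raise ValueError("observed must have one column per time point")
        if not np.all(np.isfinite(obs)):
            raise ValueError("observations must be finite")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > course.horizon + 1e-9):
            raise ValueError("observation times must lie within the course horizon")
        if course.max_concentration == 0.0 and np.any(obs != 0.0):
            warnings.warn(
                "nonzero observations under an all-zero drug schedule; fit proceeds",
                UserWarning,
                stacklevel=2,
            )
        self.observed = obs
        self.course = course
        self.v_ratio = float(v_ratio)
        merged = dict(_PK_DEFAULT_BOUNDS)
        if bounds:
            merged.update({k: tuple(v) for k, v in bounds.items()})
        self._specs = [_Param(n, *merged[n], scale="log") for n in self.param_names]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, course: TreatmentCourse, v_ratio: float = 1.0e4,
                       value_col: str = "value", **kwargs) -> "UptakeModel":
        """Build from a long table with columns time_h, replicate, value."""
        wide = df.pivot_table(index="replicate", columns="time_h", values=value_col)
        return cls(wide.columns.to_numpy(dtype=float), wide.to_numpy(dtype=float), course,
                   v_ratio=v_ratio, **kwargs)

    def predict(self, params: PKParams, times=None) -> np.ndarray:
        traj = simulate_pk(params, self.course, self.times if times is None else times)
        return traj.intracellular

    def _residual(self, u: np.ndarray) -> np.ndarray:
        vals = _natural(self._specs, u)
        pred = self.predict(PKParams(v_ratio=self.v_ratio, **vals))
        return (self.observed - pred[None, :]).ravel()

    def fit(self, n_starts: int = 16, seed: int = 0) -> "UptakeResults":
        best, costs = _multistart(self._residual, self._specs, n_starts, seed)
        return UptakeResults(self, self._specs, best, costs, self.observed.size)


class UptakeResults(_ResultsBase):
    def __init__(self, model, specs, res, costs, n_obs):
        super().__init__(model, specs, res, costs, n_obs, res.fun)

    @property
    def params(self) -> PKParams:
        return PKParams(v_ratio=self.model.v_ratio, **self.estimates)

    def fitted_values(self) -> np.ndarray:
        return self.model.predict(self.params)

    def plot_fit(self, ax=None):
        """Overlay the best-fit timecourse on the replicate data."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for row in self.model.observed:
            ax.plot(self.model.times, row, ".", color="0.6", ms=3)
        ax.plot(self.model.times, self.fitted_values(), "-", color="C3", lw=2)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("intracellular drug (nM)")
        return ax


# ---------------------------------------------------------------------------
# PD response fitting
# ---------------------------------------------------------------------------


class ResponseModel:
    """Fit the logistic/death-rate model to replicate cell counts.

    Free parameters: ``N0`` (anchor count at the first sample time),
    ``k_p``, ``theta``, ``k_d_a``, ``k_d_b`` and ``r``.  The kernel weight
    ``lam`` is fixed configuration (see module docs).  ``theta`` is bounded
    below by the maximum observed count.  ``fixed`` pins any subset of the
    parameters — typically the proliferation rate, a cell-line property
    best measured once from an untreated control.  The loss acts on raw
    counts by default; ``loss="log"`` fits log(count + 1) for
    heteroscedastic data.
    """

    param_names = ("N0", "k_p", "theta", "k_d_a", "k_d_b", "r")

    def __init__(self, times, counts, lam: float = 0.5, loss: str = "counts",
                 bounds: Mapping | None = None, fixed: Mapping | None = None):
        self.times = np.asarray(times, dtype=float)
        cts = np.atleast_2d(np.asarray(counts, dtype=float))
        if cts.shape[1] != self.times.size:
            raise ValueError("counts must have one column per time point")
        if not np.all(np.isfinite(cts)):
            raise ValueError("counts must be finite")
        if np.all(cts == 0.0):
            raise ValueError("all-zero counts cannot constrain the model")
        if cts.size < len(self.param_names):
            raise ValueError("fewer observations than free parameters")
        if loss not in ("counts", "log"):
            raise ValueError(f"unknown loss {loss!r}")
        self.counts = cts
        self.lam = float(lam)
        self.loss = loss
        cmax = float(cts.max())
        first = max(float(np.mean(cts[:, 0])), 1.0)
        defaults = {
            "N0": (max(0.05 * first, 1e-2), max(20.0 * first, 1.0)),
            "k_p": (0.0, 0.3),
            "theta": (1.02 * cmax, 1e3 * cmax),
            "k_d_a": (0.0, 0.3),
            # transient-kernel bounds reflect what daily sampling resolves:
            # induction faster than ~3 h (r > 0.3/h) is sub-sample-interval
            "k_d_b": (0.0, 0.3),
            "r": (2e-3, 0.3),
        }
        if bounds:
            defaults.update({k: tuple(v) for k, v in bounds.items()})
        self.fixed = dict(fixed) if fixed else {}
        unknown = set(self.fixed) - set(self.param_names)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        scales = {"N0": "log", "k_p": "linear", "theta": "log",
                  "k_d_a": "linear", "k_d_b": "linear", "r": "log"}
        self._specs = [_Param(n, *defaults[n], scale=scales[n])
                       for n in self.param_names if n not in self.fixed]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ResponseModel":
        """Build from a long table with columns time_h, replicate, count."""
        wide = df.pivot_table(index="replicate", columns="time_h", values="count")
        return cls(wide.columns.to_numpy(dtype=float), wide.to_numpy(dtype=float), **kwargs)

    def predict(self, p: PDParams, N0: float, times=None) -> np.ndarray:
        return simulate_counts(p, N0, self.times if times is None else times)

    def _residual(self, u: np.ndarray) -> np.ndarray:
        vals = {**self.fixed, **_natural(self._specs, u)}
        p = PDParams(k_p=vals["k_p"], theta=vals["theta"], k_d_a=vals["k_d_a"],
                     k_d_b=vals["k_d_b"], r=vals["r"], lam=self.lam)
        pred = self.predict(p, vals["N0"])
        if self.loss == "log":
            return (np.log1p(self.counts) - np.log1p(pred)[None, :]).ravel()
        return (self.counts - pred[None, :]).ravel()

    def fit(self, n_starts: int = 16, seed: int = 0) -> "ResponseResults":
        best, costs = _multistart(self._residual, self._specs, n_starts, seed)
        return ResponseResults(self, self._specs, best, costs, self.counts.size)


class ResponseResults(_ResultsBase):
    def __init__(self, model, specs, res, costs, n_obs):
        super().__init__(model, specs, res, costs, n_obs, res.fun)

    @property
    def params(self) -> PDParams:
        e = {**self.model.fixed, **self.estimates}
        return PDParams(k_p=e["k_p"], theta=e["theta"], k_d_a=e["k_d_a"],
                        k_d_b=e["k_d_b"], r=e["r"], lam=self.model.lam)

    @property
    def N0(self) -> float:
        return self.model.fixed.get("N0", self.estimates.get("N0"))

    def fitted_values(self) -> np.ndarray:
        return self.model.predict(self.params, self.N0)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for row in self.model.counts:
            ax.plot(self.model.times, row, ".", color="0.6", ms=3)
        ax.plot(self.model.times, self.fitted_values(), "-", color="C0", lw=2)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cell count")
        return ax


# ---------------------------------------------------------------------------
# Hill dose-survival fitting
# ---------------------------------------------------------------------------


class HillModel:
    """Fit a Hill dose-survival curve with floor effect.

    ``S(D) = E_inf + (1 - E_inf) / (1 + (D / EC50)^h)``.  The dose axis may
    be the extracellular concentration or the equivalent dose; survival is
    the count relative to untreated control at a fixed endpoint.  A flat
    survival profile is flagged non-identifiable and no EC50 is returned.
    """

    param_names = ("EC50", "hill", "E_inf")

    def __init__(self, dose, survival, flat_tol: float = 0.05):
        dose = np.asarray(dose, dtype=float)
        survival = np.asarray(survival, dtype=float)
        if dose.shape != survival.shape or dose.ndim != 1:
            raise ValueError("dose and survival must be matching 1-D arrays")
        if np.unique(dose).size < 4:
            raise ValueError("at least 4 distinct doses are required")
        if np.any(dose <= 0):
            raise ValueError("doses must be positive")
        if np.any(survival < -0.1) or np.any(survival > 1.3):
            raise ValueError("survival values outside the plausible [0, ~1.2] range")
        self.dose = dose
        self.survival = survival
        self.flat = float(survival.max() - survival.min()) < flat_tol
        self._specs = [
            _Param("EC50", dose.min() / 30.0, dose.max() * 30.0, scale="log"),
            _Param("hill", 0.2, 10.0, scale="log"),
            _Param("E_inf", 0.0, 1.0, scale="linear"),
        ]

    @staticmethod
    def curve(dose, EC50: float, hill: float, E_inf: float) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return E_inf + (1.0 - E_inf) / (1.0 + (dose / EC50) ** hill)

    def _residual(self, u: np.ndarray) -> np.ndarray:
        vals = _natural(self._specs, u)
        return self.curve(self.dose, vals["EC50"], vals["hill"], vals["E_inf"]) - self.survival

    def fit(self, n_starts: int = 16, seed: int = 0) -> "HillResults":
        if self.flat:
            return HillResults.flat(self)
        best, costs = _multistart(self._residual, self._specs, n_starts, seed)
        return HillResults(self, self._specs, best, costs, self.dose.size)


class HillResults(_ResultsBase):
    identifiable = True

    def __init__(self, model, specs, res, costs, n_obs):
        super().__init__(model, specs, res, costs, n_obs, res.fun)

    @classmethod
    def flat(cls, model) -> "HillResults":
        """Degenerate result for survival flat across doses."""
        obj = cls.__new__(cls)
        obj.model = model
        obj.identifiable = False
        obj.estimates = {"EC50": None, "hill": None, "E_inf": None}
        obj.conf_int = {}
        obj.half_widths = {}
        obj.at_bound = set()
        obj.converged = False
        obj.degenerate = True
        obj.cost = float("nan")
        obj.start_costs = np.array([])
        obj.n_obs = model.dose.size
        obj.residuals = np.array([])
        obj.mae = float("nan")
        return obj

    @property
    def EC50(self):
        return self.estimates["EC50"]

    def summary(self) -> str:
        if not self.identifiable:
            return "HillResults\n  non-identifiable: survival flat across doses (no EC50)"
        return super().summary()
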