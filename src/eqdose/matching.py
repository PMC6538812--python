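"""Equivalent-dose matching and constrained sensitizer-rate estimation.

Monotherapy response fits define a non-parametric *response surface*: the
death-response vector ``p = [k_d_a, k_d_b, r]`` as a piecewise-linear
function of equivalent dose.  A co-treatment condition's fitted ``p`` is
then assigned the equivalent dose ``D_est`` whose interpolated parameters
are nearest in the (range-normalised) L2 sense.  Finally, the per-level
sensitizer effect on a single PK rate ``k_x`` is recovered by minimising

    G(k_x) = sum_i (D_est,i - D_i(k_x))^2

over the sensitizer levels, subject to the hard constraint that the
optimised variable is monotone across levels (the reciprocal ``1/k_x`` is
optimised for rates the sensitizer decreases, so the constraint is always
non-decreasing increments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar

from .pd import PDParams
from .pk import PKParams, TreatmentCourse, equivalent_dose

__all__ = [
    "ResponseSurface",
    "MatchResult",
    "SensitizerEffect",
    "build_response_surface",
    "estimate_equivalent_dose",
    "estimate_kx",
]

RESPONSE_PARAMS = ("k_d_a", "k_d_b", "r")


@dataclass(frozen=True)
class ResponseSurface:
    """Piecewise-linear map D_eq -> [k_d_a, k_d_b, r] through the nodes.

    Queries are restricted to the node range (no extrapolation).  Each
    parameter dimension stores its range over the nodes; matching distances
    are computed on range-normalised coordinates so that rates differing by
    orders of magnitude contribute comparably.  When per-node confidence
    half-widths are attached (``node_ci``), matching can weight each
    dimension locally by its uncertainty instead (see
    :func:`estimate_equivalent_dose`).
    """

    d_nodes: np.ndarray
    p_nodes: np.ndarray
    param_names: tuple = RESPONSE_PARAMS
    node_ci: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.d_nodes, dtype=float)
        p = np.asarray(self.p_nodes, dtype=float)
        if d.ndim != 1 or p.ndim != 2 or p.shape[0] != d.size:
            raise ValueError("d_nodes must be 1-D with one parameter row per node")
        if d.size < 3:
            raise ValueError("at least 3 monotherapy nodes are required")
        order = np.argsort(d)
        d, p = d[order], p[order]
        if np.any(np.diff(d) == 0):
            raise ValueError("duplicate equivalent-dose nodes")
        if not np.all(np.isfinite(p)):
            raise ValueError("parameter vectors must be finite")
        ci = self.node_ci
        if ci is not None:
            ci = np.asarray(ci, dtype=float)[order]
            if ci.shape != p.shape:
                raise ValueError("node_ci must match p_nodes in shape")
            ci = np.nan_to_num(ci, nan=np.inf)
        object.__setattr__(self, "d_nodes", d)
        object.__setattr__(self, "p_nodes", p)
        object.__setattr__(self, "node_ci", ci)
        object.__setattr__(self, "param_names", tuple(self.param_names))

    @property
    def d_range(self) -> tuple:
        return (float(self.d_nodes[0]), float(self.d_nodes[-1]))

    @property
    def scale_(self) -> np.ndarray:
        """Per-dimension normalisation: parameter range over the nodes."""
        return self.p_nodes.max(axis=0) - self.p_nodes.min(axis=0)

    @property
    def identifiable(self) -> bool:
        return bool(np.any(self.scale_ > 0))

    def __call__(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        lo, hi = self.d_range
        if np.any(d < lo - 1e-9 * max(1.0, abs(lo))) or np.any(d > hi * (1 + 1e-9)):
            raise ValueError(f"query outside surface range [{lo}, {hi}]; no extrapolation")
        cols = [np.interp(d, self.d_nodes, self.p_nodes[:, j])
                for j in range(self.p_nodes.shape[1])]
        return np.stack(cols, axis=-1)

    def normalise(self, p) -> np.ndarray:
        scale = np.where(self.scale_ > 0, self.scale_, 1.0)
        return (np.asarray(p, dtype=float) - self.p_nodes.min(axis=0)) / scale

    def ci_at(self, d) -> np.ndarray:
        """Interpolated per-dimension confidence half-widths at dose d."""
        if self.node_ci is None:
            raise ValueError("surface carries no node uncertainties")
        ci = np.minimum(self.node_ci, 1e12)
        cols = [np.interp(d, self.d_nodes, ci[:, j]) for j in range(ci.shape[1])]
        return np.stack(cols, axis=-1)


def build_response_surface(
    fits: Sequence, doses: Sequence[float], node_ci: Sequence | None = None
) -> ResponseSurface:
    """Assemble the monotherapy surface from per-dose PD parameters.

    ``fits`` may be :class:`PDParams` instances or raw [k_d_a, k_d_b, r]
    vectors; ``doses`` are the corresponding monotherapy equivalent doses.
    ``node_ci`` optionally attaches per-node confidence half-widths for
    uncertainty-weighted matching.
    """
    if len(fits) != len(doses):
        raise ValueError("one parameter vector per equivalent dose required")
    rows = [f.response_vector if isinstance(f, PDParams) else np.asarray(f, dtype=float)
            for f in fits]
    ci = None if node_ci is None else np.vstack([np.asarray(c, dtype=float) for c in node_ci])
    return ResponseSurface(
        d_nodes=np.asarray(doses, dtype=float), p_nodes=np.vstack(rows), node_ci=ci
    )


@dataclass(frozen=True)
class MatchResult:
    """Equivalent dose assigned to one co-treatment condition."""

    d_est: float | None
    residual: float
    at_boundary: bool = False
    ambiguous: bool = False
    identifiable: bool = True


def estimate_equivalent_dose(
    p_fit,
    surface: ResponseSurface,
    grid_size: int = 512,
    q_ci: Sequence[float] | None = None,
    ci_floor: float = 0.02,
) -> MatchResult:
    """Match a fitted response vector onto the monotherapy surface.

    Minimises the L2 distance between the query vector and the
    interpolated surface over a dense dose grid, then refines the best
    bracket with bounded scalar minimisation (the piecewise-linear surface
    makes gradient methods unreliable).  Secondary local minima of
    comparable depth raise the ``ambiguous`` flag.

    Two scalings are available.  By default each dimension is normalised
    by its range over the surface nodes.  When the surface carries node
    uncertainties (and optionally ``q_ci``, the query fit's confidence
    half-widths), a local Mahalanobis distance is used instead: each
    dimension is scaled by the combined surface/query uncertainty at that
    dose, plus ``ci_floor`` times the range, so that dimensions the fits
    cannot resolve (the transient-kernel ridge at weak effects) carry no
    spurious weight.
    """
    if not surface.identifiable:
        return MatchResult(d_est=None, residual=float("nan"), identifiable=False)
    p = p_fit.response_vector if isinstance(p_fit, PDParams) else np.asarray(p_fit, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("query parameter vector must be finite")
    lo, hi = surface.d_range
    rng = np.where(surface.scale_ > 0, surface.scale_, 1.0)
    weighted = surface.node_ci is not None
    ciq = np.zeros(p.size) if q_ci is None else np.minimum(np.asarray(q_ci, dtype=float), 1e12)

    def distance(d):
        diff = surface(d) - p
        if weighted:
            sig = np.sqrt(surface.ci_at(d) ** 2 + ciq**2) + ci_floor * rng
        else:
            sig = rng
        return np.linalg.norm(np.atleast_2d(diff / sig), axis=1)

    grid = np.linspace(lo, hi, grid_size)
    dist = distance(grid)
    i_best = int(np.argmin(dist))

    # refine within the bracketing cell
    a = grid[max(i_best - 1, 0)]
    b = grid[min(i_best + 1, grid_size - 1)]
    if b > a:
        res = minimize_scalar(
            lambda d: float(distance(d)[0]),
            bounds=(a, b), method="bounded", options={"xatol": 1e-10 * (hi - lo)},
        )
        d_est, best = float(res.x), float(res.fun)
    else:  # pragma: no cover - degenerate single-point bracket
        d_est, best = float(grid[i_best]), float(dist[i_best])

    # ambiguity: another local minimum nearly as deep but far away in dose
    interior = np.arange(1, grid_size - 1)
    local = interior[(dist[interior] <= dist[interior - 1]) & (dist[interior] <= dist[interior + 1])]
    tol = best + 0.02 * max(1.0, float(dist.max()))
    far = np.abs(grid[local] - d_est) > 3.0 * (hi - lo) / grid_size
    ambiguous = bool(np.any(dist[local[far]] <= tol)) if local.size else False

    step = (hi - lo) / grid_size
    at_boundary = d_est <= lo + 0.5 * step or d_est >= hi - 0.5 * step
    return MatchResult(d_est=d_est, residual=best, at_boundary=at_boundary, ambiguous=ambiguous)


@dataclass(frozen=True)
class SensitizerEffect:
    """Per-level sensitizer effect on a single PK rate."""

    k_x: np.ndarray
    target: str
    direction: str
    objective: float
    constraint_active: bool = False
    warnings: tuple = ()
    concentrations: tuple = ()

    def __post_init__(self) -> None:
        kx = np.asarray(self.k_x, dtype=float)
        tilde = 1.0 / kx if self.direction == "decreasing" else kx
        if np.any(np.diff(tilde) < -1e-9 * np.abs(tilde[:-1])):
            raise ValueError("k_x sequence violates the monotone constraint")
        object.__setattr__(self, "k_x", kx)


_DEFAULT_DIRECTION = {"k_FE": "decreasing", "k_FB": "increasing"}


def estimate_kx(
    d_est: Sequence[float],
    levels: Sequence[int],
    courses: Sequence[TreatmentCourse],
    params: PKParams,
    target: str,
    direction: str | None = None,
    bounds: tuple = (1e-5, 50.0),
    concentrations: Sequence[float] | None = None,
) -> SensitizerEffect:
    """Estimate the target rate at each sensitizer level from matched doses.

    Parameters
    ----------
    d_est, levels, courses
        Per co-treatment condition: matched equivalent dose (nM), the index
        of its sensitizer level (0-based, ordered by concentration) and its
        drug schedule.  A level may carry several conditions; the objective
        pools them.
    params
        Monotherapy PK rates; every rate except ``target`` stays fixed.
    target, direction
        Which rate the sensitizer modulates ("k_FE" or "k_FB") and whether
        it increases or decreases with sensitizer concentration (defaults:
        efflux decreasing, binding increasing).  For decreasing targets the
        reciprocal is the optimised, monotone-constrained variable.
    """
    d_est = np.asarray(d_est, dtype=float)
    levels = np.asarray(levels, dtype=int)
    courses = list(courses)
    if not (d_est.size == levels.size == len(courses)):
        raise ValueError("d_est, levels and courses must align")
    if target not in ("k_FE", "k_FB"):
        raise ValueError(f"target must be 'k_FE' or 'k_FB', got {target!r}")
    n_levels = int(levels.max()) + 1
    if set(range(n_levels)) - set(levels.tolist()):
        raise ValueError("every sensitizer level needs at least one condition")
    direction = direction or _DEFAULT_DIRECTION[target]
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"direction must be 'increasing' or 'decreasing', got {direction!r}")
    lo_k, hi_k = bounds
    notes = []

    def deq_of(kx: float, course: TreatmentCourse) -> float:
        return equivalent_dose(params.replace(**{target: kx}), course)

    def to_tilde(k):
        return 1.0 / np.asarray(k, dtype=float) if direction == "decreasing" else np.asarray(k, dtype=float)

    def from_tilde(t):
        return 1.0 / np.asarray(t, dtype=float) if direction == "decreasing" else np.asarray(t, dtype=float)

    # warm start: per-condition scalar inversion of the monotone map D(k_x)
    k_start = np.empty(n_levels)
    for q in range(n_levels):
        sel = np.nonzero(levels == q)[0]
        roots = []
        for i in sel:
            course = courses[i]
            f = lambda k, i=i, c=course: deq_of(k, c) - d_est[i]
            f_lo, f_hi = f(lo_k), f(hi_k)
            if f_lo == 0.0:
                roots.append(lo_k)
            elif f_hi == 0.0:
                roots.append(hi_k)
            elif np.sign(f_lo) == np.sign(f_hi):
                # matched dose unreachable for any admissible rate
                roots.append(lo_k if abs(f_lo) < abs(f_hi) else hi_k)
                notes.append(
                    f"condition {i}: D_est={d_est[i]:.4g} nM unreachable within rate bounds"
                )
            else:
                roots.append(brentq(f, lo_k, hi_k, xtol=1e-12, rtol=1e-12))
        k_start[q] = np.exp(np.mean(np.log(roots)))
    tilde_start = np.maximum.accumulate(to_tilde(k_start))

    t_lo, t_hi = sorted((float(to_tilde(lo_k)), float(to_tilde(hi_k))))
    kx_by_level = np.empty(n_levels)

    def residual(z: np.ndarray) -> np.ndarray:
        tilde = z[0] + np.concatenate([[0.0], np.cumsum(z[1:])])
        kx_by_level[:] = from_tilde(np.clip(tilde, t_lo, t_hi))
        return np.array([d_est[i] - deq_of(kx_by_level[levels[i]], courses[i])
                         for i in range(d_est.size)])

    def pack(tilde):
        return np.concatenate([[tilde[0]], np.clip(np.diff(tilde), 0.0, None)])

    z_bounds = (
        np.concatenate([[t_lo], np.zeros(n_levels - 1)]),
        np.concatenate([[t_hi], np.full(n_levels - 1, t_hi - t_lo)]),
    )
    null_tilde = np.full(n_levels, float(np.clip(to_tilde(getattr(params, target)), t_lo, t_hi)))
    best = None
    for z0 in (pack(tilde_start), pack(null_tilde)):
        z0 = np.clip(z0, z_bounds[0], z_bounds[1])
        res = least_squares(residual, z0, bounds=z_bounds, method="trf")
        if best is None or res.cost < best.cost:
            best = res
    tilde = best.x[0] + np.concatenate([[0.0], np.cumsum(best.x[1:])])
    k_x = from_tilde(np.clip(tilde, t_lo, t_hi))
    objective = float(2.0 * best.cost)
    constraint_active = bool(np.any(np.isclose(best.x[1:], 0.0, atol=1e-12))) or bool(notes)
    if notes:
        warnings.warn("; ".join(notes), UserWarning, stacklevel=2)
    return SensitizerEffect(
        k_x=k_x,
        target=target,
        direction=direction,
        objective=objective,
        constraint_active=constraint_active,
        warnings=tuple(notes),
        concentrations=tuple(concentrations) if concentrations is not None else (),
    )
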