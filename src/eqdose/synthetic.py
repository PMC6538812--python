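"""Synthetic study generators with known ground truth.

Every input kind the framework consumes can be generated here with the
statistical structure the analysis assumes, so the full pipeline is
testable end to end without external data:

* drug-uptake timecourses: ODE means (``C_F + C_B``) plus additive
  Gaussian noise, replicate wells;
* treatment-response timecourses: exact PD means plus mean-preserving
  multiplicative lognormal noise, truncated once the mean population
  approaches carrying capacity (emulating the loss of countability at
  confluence);
* complete sensitizer studies: a 2-fold monotherapy dose grid plus
  co-treatment conditions whose PK rates are modulated level by level,
  with the response drawn from a single smooth response map p(D_eq);
* spectral image stacks from the forward model ``I_j = L * sum_f S_f
  T[f, j] + noise``.

Defaults mirror the experimental design the framework targets: doses
5000 -> ~10 nM via 2-fold dilution, 24 h exposure then washout, six
response replicates imaged daily for 15 days (plus pre-treatment days),
three uptake replicates sampled every 25 min for 24 h, 50 nM additive
uptake noise and 5% count CV.  Base PK rates are those measured for an
MDR1-overexpressing breast-cancer line (k_EF = 3.08e-6, k_FE = 0.313,
k_FB = 0.0212 per hour).  Each generator returns a machine-readable truth
bundle and is bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .pd import PDParams, simulate_counts
from .pk import PKParams, TreatmentCourse, equivalent_dose, simulate_pk
from .unmixing import CalibrationLine, FLUOROPHORES, MixingMatrix, SpectralStack

__all__ = [
    "BASE_PK",
    "UPTAKE_PK",
    "StudyDesign",
    "SensitizerStudy",
    "default_pd_map",
    "default_kfe_curve",
    "default_kfb_curve",
    "gen_pk_dataset",
    "gen_pd_dataset",
    "gen_sensitizer_study",
    "gen_spectral_stack",
    "gen_survival_assay",
    "default_scene",
    "default_mixing_matrix",
    "quadratic_illumination",
]

#: Uptake rates measured for an MDR1-overexpressing breast-cancer line
#: under doxorubicin monotherapy; the default "cell line" of all studies.
BASE_PK = PKParams(k_EF=3.08e-6, k_FE=0.313, k_FB=0.0212, v_ratio=1.0e4)

#: Ground truth for uptake *measurement* studies.  Published influx rates
#: of this magnitude carry an unknown volume ratio absorbed into the fit
#: (only k_EF * v_ratio is identifiable), so the generator fixes the
#: product so that a 1 uM application accumulates to ~1.5 uM free
#: intracellular drug — the regime fluorescence uptake assays actually
#: observe, against which a ~50 nM additive measurement error is the
#: few-percent residual such fits report.
UPTAKE_PK = PKParams(k_EF=5.0e-5, k_FE=0.313, k_FB=0.0212, v_ratio=1.0e4)


def _two_fold(top: float, n: int) -> tuple:
    return tuple(top / 2.0**k for k in range(n))


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design shared by the generators.

    Doses and sensitizer levels are 2-fold dilution series (nM); sampling
    intervals, replicate counts and noise scales match the assay layout
    described in the module docstring.
    """

    doses: tuple = _two_fold(5000.0, 10)
    sensitizer_levels: tuple = _two_fold(250.0, 7)
    cotreatment_doses: tuple = (625.0, 312.5, 156.25)
    exposure_h: float = 24.0
    uptake_exposure_h: float = 8.0
    uptake_concentration_nM: float = 1000.0
    uptake_interval_min: float = 25.0
    uptake_duration_h: float = 24.0
    response_days: int = 15
    pre_treatment_days: int = 3
    n_uptake_replicates: int = 3
    n_response_replicates: int = 6
    uptake_sigma_nM: float = 50.0
    count_cv: float = 0.05
    N0: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        if len(set(doses)) != len(doses) or any(d <= 0 for d in doses):
            raise ValueError("doses must be positive and distinct")
        if self.n_uptake_replicates < 1 or self.n_response_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.uptake_sigma_nM < 0 or self.count_cv < 0:
            raise ValueError("noise scales must be nonnegative")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "sensitizer_levels", tuple(float(s) for s in self.sensitizer_levels))
        object.__setattr__(self, "cotreatment_doses", tuple(float(d) for d in self.cotreatment_doses))

    def replace(self, **changes) -> "StudyDesign":
        return _dc_replace(self, **changes)

    @property
    def uptake_times(self) -> np.ndarray:
        step = self.uptake_interval_min / 60.0
        return np.arange(0.0, self.uptake_duration_h + 1e-9, step)

    @property
    def response_times(self) -> np.ndarray:
        days = np.arange(-self.pre_treatment_days, self.response_days + 1)
        return days * 24.0

    def uptake_course(self) -> TreatmentCourse:
        return TreatmentCourse.pulse(
            self.uptake_concentration_nM, self.uptake_exposure_h, self.uptake_duration_h
        )

    def response_course(self, dose_nM: float) -> TreatmentCourse:
        """Drug pulse, washout, then drug-free media refreshes every 3 days.

        The refreshes matter for the equivalent dose: they remove effluxed
        drug from the medium, so the bound pool cannot keep accumulating
        from slow re-entry over the imaging window.
        """
        horizon = (self.response_days) * 24.0
        events = [(0.0, float(dose_nM)), (self.exposure_h, 0.0)]
        t = self.exposure_h + 72.0
        while t < horizon:
            events.append((t, 0.0))
            t += 72.0
        return TreatmentCourse(events=tuple(events), horizon=horizon)


# ---------------------------------------------------------------------------
# ground-truth maps
# ---------------------------------------------------------------------------


def default_pd_map(d_eq: float, k_p: float = 0.0212, theta: float = 18000.0,
                   lam: float = 0.5) -> PDParams:
    """Smooth saturating response map p(D_eq).

    Death rates rise with equivalent dose toward plateaus chosen so that,
    after the convex kernel weight, the top of the dose grid drives the
    population into decline while the bottom barely perturbs growth (the
    qualitative shape of measured dose-response panels); the induction
    rate r falls with dose (high doses act as a slower, protracted death
    mode).  The functional forms are the package's own choice of realistic
    shapes; only smoothness and monotonicity matter downstream.
    """
    d = float(d_eq)
    return PDParams(
        k_p=k_p,
        theta=theta,
        k_d_a=0.050 * d / (d + 25.0),
        k_d_b=0.090 * d / (d + 50.0),
        r=0.06 + 0.14 / (1.0 + d / 50.0),
        lam=lam,
    )


def default_kfe_curve(s_nM: float, k0: float = BASE_PK.k_FE,
                      max_inhibition: float = 0.85, k_half: float = 25.0) -> float:
    """Hill-type efflux inhibition: k_FE falls with sensitizer dose."""
    s = float(s_nM)
    return k0 * (1.0 - max_inhibition * s / (s + k_half))


def default_kfb_curve(s_nM: float, k0: float = BASE_PK.k_FB,
                      fold_increase: float = 3.0, k_half: float = 25.0) -> float:
    """Hill-type activation of the net binding rate with sensitizer dose."""
    s = float(s_nM)
    return k0 * (1.0 + fold_increase * s / (s + k_half))


# ---------------------------------------------------------------------------
# timecourse generators
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_pk_dataset(params: PKParams, course: TreatmentCourse, design: StudyDesign,
                   seed=None) -> tuple:
    """Replicate intracellular uptake timecourses with additive noise.

    Returns ``(df, truth)``: a long table (time_h, replicate, value) and a
    truth bundle with the generating parameters and noise-free means.
    """
    rng = _rng(design.seed if seed is None else seed)
    times = design.uptake_times
    means = simulate_pk(params, course, times).intracellular
    noise = rng.normal(0.0, design.uptake_sigma_nM, size=(design.n_uptake_replicates, times.size))
    values = means[None, :] + noise
    df = pd.DataFrame(
        {
            "time_h": np.tile(times, design.n_uptake_replicates),
            "replicate": np.repeat(np.arange(design.n_uptake_replicates), times.size),
            "value": values.ravel(),
        }
    )
    truth = {"params": params.to_dict(), "course": course.to_dict(),
             "means": means, "sigma_nM": design.uptake_sigma_nM}
    return df, truth


def _lognormal_noise(rng: np.random.Generator, means: np.ndarray, cv: float) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return means.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    factors = np.exp(rng.normal(0.0, sigma, size=means.shape) - 0.5 * sigma**2)
    return means * factors


def gen_pd_dataset(pd_by_dose, design: StudyDesign, seed=None) -> tuple:
    """Replicate count timecourses per dose condition with lognormal noise.

    ``pd_by_dose`` maps dose (nM) to :class:`PDParams` (a mapping or a
    callable).  Samples after the noise-free mean reaches 95% of carrying
    capacity are dropped, emulating the loss of reliable counting at
    confluence.  Returns ``(df, truth)`` with a long table (time_h,
    dose_nM, replicate, count).
    """
    rng = _rng(design.seed if seed is None else seed)
    lookup = pd_by_dose if callable(pd_by_dose) else lambda d: pd_by_dose[d]
    times = design.response_times
    frames, truth_means = [], {}
    for dose in design.doses:
        p = lookup(dose)
        means = simulate_counts(p, design.N0, times)
        keep = means < 0.95 * p.theta
        t_keep, m_keep = times[keep], means[keep]
        noisy = _lognormal_noise(
            rng, np.tile(m_keep, (design.n_response_replicates, 1)), design.count_cv
        )
        frames.append(pd.DataFrame({
            "time_h": np.tile(t_keep, design.n_response_replicates),
            "dose_nM": dose,
            "replicate": np.repeat(np.arange(design.n_response_replicates), t_keep.size),
            "count": noisy.ravel(),
        }))
        truth_means[dose] = {"params": p.to_dict(), "times": t_keep, "means": m_keep}
    df = pd.concat(frames, ignore_index=True)
    return df, {"conditions": truth_means, "N0": design.N0, "cv": design.count_cv}


# ---------------------------------------------------------------------------
# full sensitizer study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitizerStudy:
    """Complete synthetic study bundle with ground truth."""

    target: str
    design: StudyDesign
    base_params: PKParams
    control: pd.DataFrame  # untreated wells: time_h, replicate, count
    monotherapy: pd.DataFrame  # time_h, dose_nM, replicate, count
    cotreatment: pd.DataFrame  # time_h, dose_nM, sensitizer_nM, level, replicate, count
    uptake: pd.DataFrame | None
    truth: dict


def gen_sensitizer_study(
    target: str,
    design: StudyDesign | None = None,
    base_params: PKParams = BASE_PK,
    kx_curve: Callable[[float], float] | None = None,
    pd_map: Callable[[float], PDParams] = default_pd_map,
    include_uptake: bool = False,
    seed=None,
) -> SensitizerStudy:
    """Generate monotherapy + co-treatment response data with known truth.

    The sensitizer modulates only ``target`` (k_FE falling or k_FB rising
    with concentration, by default through Hill-type curves); every
    condition's response parameters come from the shared map p(D_eq)
    evaluated at that condition's true equivalent dose — the core
    assumption the matching procedure then inverts.
    """
    design = design or StudyDesign()
    if target not in ("k_FE", "k_FB"):
        raise ValueError(f"target must be 'k_FE' or 'k_FB', got {target!r}")
    if kx_curve is None:
        kx_curve = default_kfe_curve if target == "k_FE" else default_kfb_curve
    rng = _rng(design.seed if seed is None else seed)

    levels = sorted(design.sensitizer_levels)  # ascending concentration
    kx_true = np.array([kx_curve(s) for s in levels])
    diffs = np.diff(kx_true)
    if not (np.all(diffs <= 0) or np.all(diffs >= 0)):
        raise ValueError("kx curve must be monotone across sensitizer levels")
    expected = "decreasing" if target == "k_FE" else "increasing"
    if expected == "decreasing" and np.any(diffs > 0):
        raise ValueError("k_FE must not increase with sensitizer concentration")
    if expected == "increasing" and np.any(diffs < 0):
        raise ValueError("k_FB must not decrease with sensitizer concentration")

    times = design.response_times
    n_rep = design.n_response_replicates

    def condition_frame(p: PDParams, extra: dict) -> pd.DataFrame:
        means = simulate_counts(p, design.N0, times)
        keep = means < 0.95 * p.theta
        t_keep, m_keep = times[keep], means[keep]
        noisy = _lognormal_noise(rng, np.tile(m_keep, (n_rep, 1)), design.count_cv)
        base = {
            "time_h": np.tile(t_keep, n_rep),
            "replicate": np.repeat(np.arange(n_rep), t_keep.size),
            "count": noisy.ravel(),
        }
        base.update(extra)
        return pd.DataFrame(base)

    control_p = pd_map(0.0)
    control_df = condition_frame(control_p, {})

    mono_frames, mono_truth = [], {}
    for dose in design.doses:
        course = design.response_course(dose)
        d_eq = equivalent_dose(base_params, course)
        p = pd_map(d_eq)
        mono_frames.append(condition_frame(p, {"dose_nM": dose}))
        mono_truth[dose] = {"d_eq": d_eq, "params": p.to_dict()}

    co_frames, co_truth = [], []
    for q, s in enumerate(levels):
        params_q = base_params.replace(**{target: float(kx_true[q])})
        for dose in design.cotreatment_doses:
            course = design.response_course(dose)
            d_eq = equivalent_dose(params_q, course)
            p = pd_map(d_eq)
            co_frames.append(
                condition_frame(p, {"dose_nM": dose, "sensitizer_nM": s, "level": q})
            )
            co_truth.append({"level": q, "sensitizer_nM": s, "dose_nM": dose,
                             "d_eq": d_eq, "params": p.to_dict()})

    uptake_df = None
    if include_uptake:
        frames = []
        for q, s in enumerate(levels):
            params_q = base_params.replace(**{target: float(kx_true[q])})
            df_q, _ = gen_pk_dataset(params_q, design.uptake_course(), design, seed=rng)
            df_q["sensitizer_nM"] = s
            frames.append(df_q)
        uptake_df = pd.concat(frames, ignore_index=True)

    truth = {
        "target": target,
        "sensitizer_nM": list(levels),
        "k_x": kx_true,
        "control": {"params": control_p.to_dict()},
        "monotherapy": mono_truth,
        "cotreatment": co_truth,
    }
    return SensitizerStudy(
        target=target,
        design=design,
        base_params=base_params,
        control=control_df,
        monotherapy=pd.concat(mono_frames, ignore_index=True),
        cotreatment=pd.concat(co_frames, ignore_index=True),
        uptake=uptake_df,
        truth=truth,
    )


def gen_survival_assay(
    pk_by_line: Mapping[str, PKParams],
    design: StudyDesign | None = None,
    pd_map: Callable[[float], PDParams] = default_pd_map,
    endpoint_h: float = 72.0,
    seed=None,
) -> pd.DataFrame:
    """Endpoint survival assay for comparing cell lines.

    For each line and dose the response is simulated from the shared map
    p(D_eq) at the line's own equivalent dose, counts are read at the
    endpoint with replicate lognormal noise, and survival is reported
    relative to the untreated control.  Columns: line, dose_nM, d_eq_nM,
    survival.
    """
    design = design or StudyDesign()
    rng = _rng(design.seed if seed is None else seed)
    times = np.array([design.response_times[0], 0.0, endpoint_h])
    rows = []
    for line, pk in pk_by_line.items():
        control = simulate_counts(pd_map(0.0), design.N0, times)[-1]
        control_obs = _lognormal_noise(
            rng, np.full(design.n_response_replicates, control), design.count_cv
        ).mean()
        for dose in design.doses:
            d_eq = equivalent_dose(pk, design.response_course(dose))
            treated = simulate_counts(pd_map(d_eq), design.N0, times)[-1]
            obs = _lognormal_noise(
                rng, np.full(design.n_response_replicates, treated), design.count_cv
            ).mean()
            rows.append({"line": line, "dose_nM": dose, "d_eq_nM": d_eq,
                         "survival": obs / control_obs})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectral image stacks
# ---------------------------------------------------------------------------

_DEFAULT_T = np.array(
    [
        # channels:  1      2      3      4      5
        [0.05, 0.60, 0.30, 1.00, 0.10],  # H2B (red histone tag)
        [1.00, 0.20, 0.05, 0.40, 0.02],  # MDR (GFP-tagged pump)
        [0.10, 0.80, 1.00, 0.50, 0.30],  # doxorubicin
        [0.30, 0.25, 0.20, 0.25, 1.00],  # media background
    ]
)


def default_mixing_matrix() -> MixingMatrix:
    """A realistic, well-conditioned fluorophore spectrum set."""
    return MixingMatrix(T=_DEFAULT_T.copy())


def quadratic_illumination(shape: tuple, strength: float = 0.35) -> np.ndarray:
    """Smooth centre-bright vignetting field, max 1."""
    ny, nx = shape
    y = np.linspace(-1.0, 1.0, ny)[:, None]
    x = np.linspace(-1.0, 1.0, nx)[None, :]
    L = 1.0 - strength * (0.6 * x**2 + 0.4 * y**2 + 0.1 * x * y)
    return L / L.max()


def default_scene(
    shape: tuple = (96, 96),
    n_cells: int = 12,
    dox_nM: float = 500.0,
    cal: CalibrationLine = CalibrationLine(a=2.0, b=30.0),
    background: float = 40.0,
    seed=0,
) -> dict:
    """Fluorophore signal maps for a sparse field of bright nuclei.

    Doxorubicin signal follows the calibration line inside cells (nuclear
    accumulation) and at 20% concentration outside.  Returns the maps,
    the cell mask and the scene metadata.
    """
    rng = _rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros(shape, dtype=bool)
    radius = max(3, min(ny, nx) // 24)
    centers = []
    attempts = 0
    while len(centers) < n_cells and attempts < 10000:
        attempts += 1
        cy = rng.integers(radius + 1, ny - radius - 1)
        cx = rng.integers(radius + 1, nx - radius - 1)
        if all((cy - y0) ** 2 + (cx - x0) ** 2 > (3 * radius) ** 2 for y0, x0 in centers):
            centers.append((cy, cx))
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    s_maps = np.zeros((len(FLUOROPHORES), ny, nx))
    s_maps[0] = np.where(mask, 500.0, 0.0)  # H2B in nuclei
    s_maps[1] = np.where(mask, 200.0, 0.0)  # MDR on cells
    dox_in = cal.a * dox_nM + cal.b
    dox_out = cal.a * 0.2 * dox_nM + cal.b
    s_maps[2] = np.where(mask, dox_in, dox_out)
    s_maps[3] = background
    return {"s_maps": s_maps, "mask": mask, "cal": cal, "dox_nM": dox_nM,
            "dox_extracellular_nM": 0.2 * dox_nM, "centers": centers}


def gen_spectral_stack(
    s_maps: np.ndarray,
    T: MixingMatrix | np.ndarray,
    L: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_timepoints: int = 1,
    seed=0,
) -> tuple:
    """Forward-model spectral stacks: ``I_j = L * sum_f S_f T[f, j] + eps``.

    Returns ``(stacks, truth)`` where stacks is a list of
    :class:`SpectralStack` (one per timepoint) and truth records the maps,
    spectra and illumination used.
    """
    rng = _rng(seed)
    maps = np.asarray(s_maps, dtype=float)
    M = T.T if isinstance(T, MixingMatrix) else np.asarray(T, dtype=float)
    shape = maps.shape[1:]
    field = np.ones(shape) if L is None else np.asarray(L, dtype=float)
    if field.shape != shape:
        raise ValueError("illumination field shape must match the maps")
    clean = np.einsum("fij,fc->cij", maps, M) * field[None, :, :]
    stacks = []
    for t in range(n_timepoints):
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
        stacks.append(SpectralStack(images=np.clip(noisy, 0.0, None), timepoint=t))
    truth = {"s_maps": maps, "T": M, "L": field, "noise_sd": noise_sd}
    return stacks, truth
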