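"""Synthetic cohort and DIRE-like spectrum generator.

The generator produces, with no external data, a cohort that carries the
statistical structure the downstream analyses are designed to detect:

* marker values drawn log-normal per (marker, sex, BMI class) stratum, with
  a participant-level random intercept linking the two timepoints;
* lipoprotein phospholipid fractions tied to the SPC sub-regions through a
  rank-calibrated Gaussian copula, so realised Pearson correlations
  approach the configured targets at large n;
* demographics and clinical flags (smoking, condition count, blood
  pressure, self-rated health) that drive the healthy-participant filter.

Spectra are emulated, not simulated physically: one Lorentzian line per
marker whose *windowed point-sum on the actual acquisition grid* equals the
requested marker value (the five line amplitudes are obtained from a joint
linear solve, so inter-window tail leakage is compensated exactly), plus a
residual-water line, a smooth baseline and white noise, all multiplied by
the per-sample ERETIC factor so that preprocessing undoes it.
"""

from __future__ import annotations

from typing import Dict, Iterator, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .config import (
    BMI_CLASSES,
    SELF_RATED_LEVELS,
    SEXES,
    AcquisitionConfig,
    GeneratorConfig,
)
from .quantify import CANONICAL_WINDOWS, MARKERS, MarkerPanel
from .spectrum import Spectrum

LIPO_FRACTIONS = ("hdl123_pl", "hdl4_pl", "ldl_pl")
WAVE_GAP_YEARS = 5.0

COHORT_COLUMNS = [
    "sample_id", "participant_id", "cohort", "timepoint", "age", "sex",
    "bmi", "bmi_class", "smoker", "n_conditions", "bp_normal",
    "self_rated_health", "glyca", "glycb", "spc1", "spc2", "spc3",
    "hdl1_pl", "hdl2_pl", "hdl3_pl", "hdl123_pl", "hdl4_pl", "ldl_pl",
]


def _marker_corr_matrix(cfg: GeneratorConfig) -> np.ndarray:
    c = np.eye(len(MARKERS))
    index = {m: i for i, m in enumerate(MARKERS)}
    for (a, b), r in cfg.marker_corr.items():
        i, j = index[a], index[b]
        c[i, j] = c[j, i] = r
    # guard positive definiteness
    w = np.linalg.eigvalsh(c)
    if w.min() <= 1e-10:
        raise ValueError("marker_corr matrix is not positive definite")
    return c


def _normal_scores(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank-based Gaussian scores (ties broken at random, seeded)."""
    from scipy.stats import norm

    n = x.size
    order = np.lexsort((rng.random(n), x))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    return norm.ppf((ranks - 0.5) / n)


def _latent_corr(r: float, s1: float, s2: float) -> float:
    """Latent Gaussian correlation giving Pearson r between two log-normals
    with log-scale SDs s1, s2 (bivariate log-normal closed form)."""
    rho = np.log1p(r * np.sqrt(np.expm1(s1**2) * np.expm1(s2**2))) / (s1 * s2)
    return float(np.clip(rho, -0.999, 0.999))


def _draw_bmi(rng: np.random.Generator, cls: str) -> float:
    if cls == "underweight":
        return float(rng.uniform(17.0, 18.5))
    if cls == "normal":
        return float(rng.uniform(18.5, 25.0))
    if cls == "overweight":
        return float(rng.uniform(25.0, 30.0))
    return float(min(30.0 + rng.gamma(2.0, 1.8), 55.0))


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw the full synthetic cohort table, one row per sample.

    Reproducible: identical configs (including ``seed``) give identical
    tables.  Raises on invalid configuration (weights not summing to one,
    non-positive medians, correlation targets outside (-1, 1), ...).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # -- participants -------------------------------------------------------
    n_pop, n_bas = cfg.n_participants, cfg.n_basque
    n_part = n_pop + n_bas
    t_per = cfg.timepoints_per_participant
    is_basque = np.arange(n_part) >= n_pop

    sex = np.where(rng.random(n_part) < cfg.sex_ratio, "female", "male")
    age_lo, age_hi = cfg.age_range
    span = WAVE_GAP_YEARS * (t_per - 1)
    age0 = np.where(
        is_basque,
        rng.uniform(age_lo, age_hi, n_part),
        rng.uniform(age_lo, max(age_lo, age_hi - span), n_part),
    )
    weights = np.array([cfg.bmi_class_weights.get(c, 0.0) for c in BMI_CLASSES])
    cls_idx = rng.choice(len(BMI_CLASSES), size=n_part, p=weights / weights.sum())
    bmi_class = np.array(BMI_CLASSES)[cls_idx]
    bmi = np.array([_draw_bmi(rng, c) for c in bmi_class])

    if cfg.healthy_mode:
        smoker = np.zeros(n_part, dtype=bool)
        n_cond = np.zeros(n_part, dtype=int)
        bp_normal = np.ones(n_part, dtype=bool)
        srh = rng.choice(["good", "very good", "excellent"], size=n_part, p=[0.45, 0.38, 0.17])
    else:
        smoker = rng.random(n_part) < cfg.smoker_rate
        n_cond = rng.poisson(cfg.conditions_lambda, n_part)
        bp_normal = rng.random(n_part) < cfg.bp_normal_rate
        srh = rng.choice(SELF_RATED_LEVELS, size=n_part, p=np.array(cfg.self_rated_weights))
        # reference-cohort participants are healthy controls by recruitment
        smoker[is_basque] = False
        n_cond[is_basque] = 0
        bp_normal[is_basque] = True
        srh[is_basque] = rng.choice(["good", "very good", "excellent"], size=n_bas)

    # -- sample bookkeeping (missed follow-ups drop the last timepoint) -----
    missing = np.zeros(n_part, dtype=bool)
    if cfg.n_missing_followup > 0 and n_pop > 0 and t_per > 1:
        lost = rng.choice(n_pop, size=min(cfg.n_missing_followup, n_pop), replace=False)
        missing[lost] = True

    part_idx, timepoint = [], []
    for i in range(n_part):
        n_t = 1 if is_basque[i] else (t_per - 1 if missing[i] else t_per)
        for t in range(1, n_t + 1):
            part_idx.append(i)
            timepoint.append(t)
    part_idx = np.asarray(part_idx, dtype=int)
    timepoint = np.asarray(timepoint, dtype=int)
    n_samp = part_idx.size

    # -- marker values: correlated log-normals with participant intercept ---
    chol = np.linalg.cholesky(_marker_corr_matrix(cfg))
    u_part = rng.standard_normal((n_part, len(MARKERS))) @ chol.T
    e_samp = rng.standard_normal((n_samp, len(MARKERS))) @ chol.T
    z = np.sqrt(cfg.icc) * u_part[part_idx] + np.sqrt(1.0 - cfg.icc) * e_samp

    sex_s = sex[part_idx]
    cls_s = bmi_class[part_idx]
    markers: Dict[str, np.ndarray] = {}
    for j, m in enumerate(MARKERS):
        med = np.array([cfg.median_table[m][sx][cl] for sx, cl in zip(sex_s, cls_s)])
        markers[m] = med * np.exp(cfg.log_sd[m] * z[:, j])

    # -- lipoprotein fractions via rank-calibrated Gaussian copula ----------
    involved = sorted({m for (m, _f) in cfg.copula_r}) if n_samp >= 3 else []
    scores = {m: _normal_scores(markers[m], rng) for m in involved}
    log_sd_emp = {m: float(np.std(np.log(markers[m]))) for m in involved}

    lipo: Dict[str, np.ndarray] = {}
    for frac in LIPO_FRACTIONS:
        targets = [(m, r) for (m, f), r in cfg.copula_r.items() if f == frac and m in scores]
        sd_f = cfg.lipo_log_sd[frac]
        if targets:
            ms = [m for m, _ in targets]
            rho = np.array([_latent_corr(r, log_sd_emp[m], sd_f) for m, r in targets])
            s_mat = np.column_stack([scores[m] for m in ms])
            sigma = np.corrcoef(s_mat, rowvar=False)
            sigma = np.atleast_2d(sigma)
            coef = np.linalg.solve(sigma, rho)
            resid_var = 1.0 - float(coef @ sigma @ coef)
            if resid_var < -0.02 and n_samp >= 100:
                raise ValueError(
                    f"copula targets for {frac!r} are jointly infeasible "
                    f"(implied residual variance {resid_var:.3f} < 0)"
                )
            # negatives at small n reflect sampling noise in the empirical
            # score correlations; the copula then degenerates to its bound
            resid_var = max(resid_var, 0.0)
            w = s_mat @ coef + np.sqrt(resid_var) * rng.standard_normal(n_samp)
        else:
            w = rng.standard_normal(n_samp)
        lipo[frac] = cfg.lipo_medians[frac] * np.exp(sd_f * w)

    # split HDL1-3 into its parts; the total is re-summed so the identity
    # hdl123 = hdl1 + hdl2 + hdl3 holds exactly in floating point
    props = rng.dirichlet(np.array(cfg.hdl_split) * cfg.hdl_split_concentration, size=n_samp)
    hdl_parts = props * lipo["hdl123_pl"][:, None]
    hdl123 = hdl_parts.sum(axis=1)

    ids = np.array(
        [
            f"B{part_idx[i] - n_pop:04d}" if is_basque[part_idx[i]] else f"P{part_idx[i]:05d}"
            for i in range(n_samp)
        ]
    )
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n_samp)],
            "participant_id": ids,
            "cohort": np.where(is_basque[part_idx], "basque", "population"),
            "timepoint": timepoint,
            "age": age0[part_idx] + WAVE_GAP_YEARS * (timepoint - 1),
            "sex": sex_s,
            "bmi": bmi[part_idx],
            "bmi_class": cls_s,
            "smoker": smoker[part_idx],
            "n_conditions": n_cond[part_idx],
            "bp_normal": bp_normal[part_idx],
            "self_rated_health": srh[part_idx],
            **{m: markers[m] for m in MARKERS},
            "hdl1_pl": hdl_parts[:, 0],
            "hdl2_pl": hdl_parts[:, 1],
            "hdl3_pl": hdl_parts[:, 2],
            "hdl123_pl": hdl123,
            "hdl4_pl": lipo["hdl4_pl"],
            "ldl_pl": lipo["ldl_pl"],
        },
        columns=COHORT_COLUMNS,
    )
    return df


# ---------------------------------------------------------------------------
# Spectrum synthesis


def _lorentzian(x: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    return halfwidth**2 / ((x - center) ** 2 + halfwidth**2)


def _solve_amplitudes(
    grid: np.ndarray, acq: AcquisitionConfig, targets: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Joint non-negative amplitude solve on the actual grid.

    The windowed point-sums of the summed spectrum are matched to the
    requested marker values; for strictly positive panels the window
    cross-talk matrix is diagonally dominant and the solution equals the
    unconstrained joint solve (round trip exact), while degenerate panels
    (a zero marker next to a large neighbour) keep all lines non-negative
    and leave only Lorentzian tail leakage in the empty windows.
    """
    from scipy.optimize import nnls

    shapes = np.column_stack(
        [_lorentzian(grid, acq.peak_centers[m], acq.peak_halfwidths[m]) for m in MARKERS]
    )
    m_mat = np.array(
        [
            [shapes[CANONICAL_WINDOWS[w].contains(grid), j].sum() for j in range(len(MARKERS))]
            for w in MARKERS
        ]
    )
    amps, _ = nnls(m_mat, targets)
    return amps, shapes


def generate_spectrum(
    panel: Union[MarkerPanel, Mapping[str, float]],
    acq: Optional[AcquisitionConfig] = None,
    seed: Union[int, np.random.Generator, None] = 0,
    eretic_factor: float = 1.0,
) -> Spectrum:
    """Emulate one DIRE-like spectrum carrying the given marker panel.

    The five marker lines are Lorentzians whose amplitudes are solved
    jointly on the actual grid so that each canonical window's point-sum
    equals the requested value; residual water, a smooth random baseline
    and white noise are added, and everything is multiplied by
    ``eretic_factor``.
    """
    acq = acq or AcquisitionConfig()
    acq.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = panel.as_dict() if isinstance(panel, MarkerPanel) else dict(panel)
    targets = np.array([float(values[m]) for m in MARKERS])
    if np.any(targets < 0):
        raise ValueError("panel marker values must be non-negative")
    grid = acq.grid()

    amps, shapes = _solve_amplitudes(grid, acq, targets)
    signal = shapes @ amps
    signal += acq.water_height * _lorentzian(grid, acq.water_ppm, acq.water_halfwidth)

    baseline = np.zeros_like(grid)
    if acq.baseline_amplitude > 0:
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        coefs = rng.uniform(-0.5, 1.0, size=3)
        baseline = coefs[0] + coefs[1] * t + coefs[2] * t**2
        for _ in range(3):
            h = rng.uniform(0.0, 1.0)
            mu = rng.uniform(grid[0], grid[-1])
            sig = rng.uniform(0.6, 2.0)
            baseline = baseline + h * np.exp(-0.5 * ((grid - mu) / sig) ** 2)
        baseline *= acq.baseline_amplitude

    noise = rng.normal(0.0, acq.noise_sd, size=grid.size) if acq.noise_sd > 0 else 0.0

    intensity = (signal + baseline + noise) * eretic_factor
    return Spectrum(grid, intensity, eretic_factor=eretic_factor, water_ppm=acq.water_ppm)


def iter_cohort_spectra(
    cohort: pd.DataFrame, acq: Optional[AcquisitionConfig] = None, seed: int = 0
) -> Iterator[Tuple[str, Spectrum]]:
    """Yield ``(sample_id, raw Spectrum)`` for every cohort row.

    Per-sample randomness (ERETIC factor, baseline shape, noise) is derived
    from independent child seeds of ``seed``, so any subset of spectra is
    reproducible regardless of iteration order.
    """
    acq = acq or AcquisitionConfig()
    acq.validate()
    children = np.random.SeedSequence(seed).spawn(len(cohort))
    lo, hi = acq.eretic_factor_range
    for child, (_, row) in zip(children, cohort.iterrows()):
        rng = np.random.default_rng(child)
        eretic = float(rng.uniform(lo, hi))
        panel = {m: float(row[m]) for m in MARKERS}
        yield str(row["sample_id"]), generate_spectrum(panel, acq, rng, eretic)
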