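"""Configuration objects for the whole study replica.

Every tunable of the pipeline lives here: the cohort generator calibration
(stratum medians in A.U., log-scale dispersions, copula correlation
targets), the synthetic acquisition settings (grid, line positions and
widths, artefact amplitudes), the asymmetric least-squares baseline
parameters and the exclusion regions.  All objects serialise to and from a
single YAML document so a run is fully described by one file plus a seed.

Default calibration
-------------------
The generator defaults encode the population structure the panel is known
to show in large adult cohorts: SPC2 medians fall with BMI class and carry
a large female excess (normal weight: men 5123.65 A.U., women 6837.86 A.U.;
overweight: 4609.95 / 6136.34; obese: 4085.73 / 5502.43), SPC1 is nearly
flat in BMI with a small female excess only in the obese class (3221.94 /
3362.88), SPC3 sits at roughly one fifth of SPC2, and the glycoprotein
signals GlycA/GlycB rise with BMI with GlycB higher in women.  The
healthy-reference preset instead applies a uniform 33.7% female excess to
SPC2 across all ages and draws no obese participants.  Copula targets link
SPC2 to the HDL1-3 phospholipid sum (r = 0.94) and SPC1 to HDL4 (r = 0.53)
and HDL1-3 (r = 0.16).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import yaml

from .quantify import CANONICAL_WINDOWS, MARKERS

BMI_CLASSES = ("underweight", "normal", "overweight", "obese")
SEXES = ("male", "female")

#: Full-population stratum medians, A.U.: marker -> sex -> BMI class.
POPULATION_MEDIANS: Dict[str, Dict[str, Dict[str, float]]] = {
    "spc2": {
        "male": {"underweight": 5350.0, "normal": 5123.65, "overweight": 4609.95, "obese": 4085.73},
        "female": {"underweight": 7150.0, "normal": 6837.86, "overweight": 6136.34, "obese": 5502.43},
    },
    "spc1": {
        "male": {"underweight": 3280.0, "normal": 3300.0, "overweight": 3260.0, "obese": 3221.94},
        "female": {"underweight": 3240.0, "normal": 3280.0, "overweight": 3270.0, "obese": 3362.88},
    },
    "spc3": {
        "male": {"underweight": 1270.0, "normal": 1250.0, "overweight": 1190.0, "obese": 1125.0},
        "female": {"underweight": 1310.0, "normal": 1300.0, "overweight": 1280.0, "obese": 1260.0},
    },
    "glyca": {
        "male": {"underweight": 1750.0, "normal": 1800.0, "overweight": 1900.0, "obese": 2010.0},
        "female": {"underweight": 1745.0, "normal": 1795.0, "overweight": 1895.0, "obese": 2005.0},
    },
    "glycb": {
        "male": {"underweight": 870.0, "normal": 900.0, "overweight": 950.0, "obese": 1000.0},
        "female": {"underweight": 960.0, "normal": 990.0, "overweight": 1045.0, "obese": 1100.0},
    },
}

#: Healthy-reference medians: flat in age and BMI class, SPC2 female excess
#: fixed at 33.7%, SPC2 : SPC1 : SPC3 pooled medians near 2:1 and 5:1.
_HEALTHY_SEX_MEDIANS: Dict[str, Dict[str, float]] = {
    "spc2": {"male": 5124.0, "female": 5124.0 * 1.337},
    "spc1": {"male": 3010.0, "female": 2940.0},
    "spc3": {"male": 1205.0, "female": 1165.0},
    "glyca": {"male": 1810.0, "female": 1760.0},
    "glycb": {"male": 905.0, "female": 900.0},
}

HEALTHY_MEDIANS: Dict[str, Dict[str, Dict[str, float]]] = {
    m: {sex: {cls: v for cls in BMI_CLASSES} for sex, v in by_sex.items()}
    for m, by_sex in _HEALTHY_SEX_MEDIANS.items()
}

#: Log-scale SD of the marker marginals.  The SPC sub-regions are HDL/LDL
#: lipid measures with population IQR/median near 20%; the acute-phase
#: glycoprotein signals are more dispersed.
DEFAULT_LOG_SD: Dict[str, float] = {
    "spc1": 0.15,
    "spc2": 0.15,
    "spc3": 0.15,
    "glyca": 0.25,
    "glycb": 0.22,
}

#: Within-stratum latent correlations between markers (Gaussian scale).
DEFAULT_MARKER_CORR: Dict[Tuple[str, str], float] = {
    ("spc1", "spc2"): 0.17,
    ("spc1", "spc3"): 0.30,
    ("spc2", "spc3"): 0.35,
    ("glyca", "glycb"): 0.50,
}

#: Target Pearson correlations between markers and lipoprotein phospholipid
#: fractions, realised through a rank-calibrated Gaussian copula.
DEFAULT_COPULA_R: Dict[Tuple[str, str], float] = {
    ("spc2", "hdl123_pl"): 0.94,
    ("spc1", "hdl123_pl"): 0.16,
    ("spc1", "hdl4_pl"): 0.53,
    ("spc3", "ldl_pl"): 0.50,
}

#: Median phospholipid concentrations (mg/dL) and log-scale SDs of the
#: lipoprotein fractions drawn by the generator.
DEFAULT_LIPO_MEDIANS: Dict[str, float] = {"hdl123_pl": 42.0, "hdl4_pl": 15.0, "ldl_pl": 55.0}
DEFAULT_LIPO_LOG_SD: Dict[str, float] = {"hdl123_pl": 0.20, "hdl4_pl": 0.20, "ldl_pl": 0.25}

POPULATION_BMI_WEIGHTS = {"underweight": 0.002, "normal": 0.37, "overweight": 0.40, "obese": 0.228}
HEALTHY_BMI_WEIGHTS = {"underweight": 0.01, "normal": 0.60, "overweight": 0.39, "obese": 0.0}

SELF_RATED_LEVELS = ("poor", "fair", "good", "very good", "excellent")


def _pairs_to_str(d: Dict[Tuple[str, str], float]) -> Dict[str, float]:
    return {f"{a}|{b}": v for (a, b), v in d.items()}


def _pairs_from_str(d: Dict[str, float]) -> Dict[Tuple[str, str], float]:
    out = {}
    for k, v in d.items():
        a, _, b = k.partition("|")
        out[(a, b)] = float(v)
    return out


@dataclass
class GeneratorConfig:
    """Calibration of the synthetic cohort generator.

    ``n_participants`` population-cohort participants contribute
    ``timepoints_per_participant`` samples each, minus
    ``n_missing_followup`` missed second visits; ``n_basque`` reference
    participants (single timepoint, all considered healthy) are appended.
    ``healthy_mode`` switches to the healthy-reference calibration: flat
    age/BMI medians, a uniform 33.7% female SPC2 excess, no obese class and
    all clinical flags healthy.
    """

    n_participants: int = 1976
    timepoints_per_participant: int = 2
    n_missing_followup: int = 7
    n_basque: int = 80
    age_range: Tuple[float, float] = (20.0, 70.0)
    sex_ratio: float = 0.5  # fraction female
    bmi_class_weights: Dict[str, float] = field(
        default_factory=lambda: dict(POPULATION_BMI_WEIGHTS)
    )
    median_table: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: json.loads(json.dumps(POPULATION_MEDIANS))
    )
    log_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_SD))
    marker_corr: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_CORR)
    )
    copula_r: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COPULA_R)
    )
    lipo_medians: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LIPO_MEDIANS))
    lipo_log_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LIPO_LOG_SD))
    hdl_split: Tuple[float, float, float] = (0.38, 0.27, 0.35)  # HDL1:HDL2:HDL3 of HDL1-3
    hdl_split_concentration: float = 200.0
    icc: float = 0.5  # participant-level intraclass correlation of log markers
    smoker_rate: float = 0.12
    conditions_lambda: float = 1.23  # Poisson rate of reported medical conditions
    bp_normal_rate: float = 0.60
    self_rated_weights: Tuple[float, ...] = (0.02, 0.13, 0.38, 0.33, 0.14)
    healthy_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0 or self.n_basque < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.timepoints_per_participant < 1:
            raise ValueError("need at least one timepoint per participant")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("icc must lie in [0, 1]")
        w = [self.bmi_class_weights.get(c, 0.0) for c in BMI_CLASSES]
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-8:
            raise ValueError(f"bmi_class_weights must be non-negative and sum to 1, got {w}")
        sr = list(self.self_rated_weights)
        if any(x < 0 for x in sr) or abs(sum(sr) - 1.0) > 1e-8:
            raise ValueError("self_rated_weights must be non-negative and sum to 1")
        for m in MARKERS:
            if not self.log_sd.get(m, 0.0) > 0:
                raise ValueError(f"log_sd[{m!r}] must be positive")
            for sex in SEXES:
                for cls in BMI_CLASSES:
                    if not self.median_table[m][sex][cls] > 0:
                        raise ValueError(f"median_table[{m}][{sex}][{cls}] must be positive")
        for pair, r in {**self.marker_corr, **self.copula_r}.items():
            if not abs(r) < 1.0:
                raise ValueError(f"correlation target {pair} must satisfy |r| < 1")
        for frac, sd in self.lipo_log_sd.items():
            if not sd > 0:
                raise ValueError(f"lipo_log_sd[{frac!r}] must be positive")
        if any(p <= 0 for p in self.hdl_split) or abs(sum(self.hdl_split) - 1.0) > 1e-8:
            raise ValueError("hdl_split must be positive and sum to 1")

    @property
    def n_samples(self) -> int:
        return (
            self.n_participants * self.timepoints_per_participant
            - self.n_missing_followup
            + self.n_basque
        )

    @classmethod
    def population_default(cls, seed: int = 0) -> "GeneratorConfig":
        """Free-living population preset: 1976 x 2 timepoints - 7 missed
        follow-ups + 80 reference participants = 4025 samples."""
        return cls(seed=seed)

    @classmethod
    def healthy_default(cls, seed: int = 0) -> "GeneratorConfig":
        """Healthy-reference preset: 1960 x 2 + 80 = 4000 samples, flat
        age/BMI medians, uniform 33.7% female SPC2 excess, no obese class."""
        return cls(
            n_participants=1960,
            n_missing_followup=0,
            n_basque=80,
            bmi_class_weights=dict(HEALTHY_BMI_WEIGHTS),
            median_table=json.loads(json.dumps(HEALTHY_MEDIANS)),
            healthy_mode=True,
            seed=seed,
        )


@dataclass
class AcquisitionConfig:
    """Synthetic acquisition settings for the DIRE-like spectrum emulator.

    One Lorentzian line stands in for each composite marker signal; a
    residual-water line, a smooth baseline (low-order polynomial plus broad
    Gaussian humps) and white noise complete the artefact model.  Line
    half-widths default to 0.001 ppm so that >= 95% of every line's area
    falls inside its own integration window.
    """

    ppm_min: float = 0.40
    ppm_max: float = 9.50
    ppm_step: float = 0.0005
    water_ppm: float = 4.70
    peak_centers: Dict[str, float] = field(
        default_factory=lambda: {
            "glyca": 2.070,
            "glycb": 2.105,
            "spc1": 3.218,
            "spc2": 3.249,
            "spc3": 3.281,
        }
    )
    peak_halfwidths: Dict[str, float] = field(
        default_factory=lambda: {m: 0.001 for m in MARKERS}
    )
    water_halfwidth: float = 0.010
    water_height: float = 300.0
    baseline_amplitude: float = 10.0
    noise_sd: float = 0.05
    eretic_factor_range: Tuple[float, float] = (0.8, 1.25)

    def validate(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValueError("need ppm_min < ppm_max")
        if not self.ppm_step > 0:
            raise ValueError("ppm_step must be positive")
        lo, hi = self.eretic_factor_range
        if not 0 < lo <= hi:
            raise ValueError("eretic_factor_range must be a positive interval")
        if self.noise_sd < 0 or self.baseline_amplitude < 0 or self.water_height < 0:
            raise ValueError("artefact amplitudes must be non-negative")
        for m in MARKERS:
            c = self.peak_centers[m]
            g = self.peak_halfwidths[m]
            w = CANONICAL_WINDOWS[m]
            if not (w.lo < c < w.hi):
                raise ValueError(f"peak center of {m} ({c}) must lie inside [{w.lo}, {w.hi})")
            if g < 2 * self.ppm_step:
                raise ValueError(
                    f"grid too coarse to resolve {m}: half-width {g} < 2 x step {self.ppm_step}"
                )
            # Lorentzian closed form: fraction of area inside the window
            frac = (math.atan((w.hi - c) / g) + math.atan((c - w.lo) / g)) / math.pi
            if frac < 0.95:
                raise ValueError(
                    f"{m}: only {frac:.3f} of the line area falls inside its window; "
                    "narrow the half-width or move the center"
                )

    def grid(self):
        import numpy as np

        n = int(round((self.ppm_max - self.ppm_min) / self.ppm_step)) + 1
        return np.linspace(self.ppm_min, self.ppm_max, n)


@dataclass
class BaselineParams:
    """Asymmetric least-squares (Whittaker) baseline parameters.

    ``lam`` is the second-difference smoothness penalty, ``p`` the
    asymmetry weight applied to points above the running baseline (1 - p
    below), iterated ``n_iter`` times.  The defaults are chosen for
    quantitative window integration of tall, narrow lines on a smooth
    baseline: the asymmetric bump the smoother places under a peak cluster
    scales with ``p`` times the cluster area, and ``lam = 1e8`` /
    ``p = 1e-5`` keeps that bias below 0.3% of every panel window while
    still tracking baseline structure broader than ~0.05 ppm.
    """

    lam: float = 1e8
    p: float = 1e-5
    n_iter: int = 10

    def validate(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class ExclusionRegions:
    """Spectral regions removed from analysis: the residual water band
    (closed interval) and the noise-dominated axis ends (strict
    inequalities, so the 0.4 and 9.5 ppm boundary points are kept)."""

    water: Tuple[float, float] = (4.50, 4.90)
    low_noise: float = 0.4
    high_noise: float = 9.5

    def validate(self) -> None:
        lo, hi = self.water
        if not lo < hi:
            raise ValueError("water interval must have lo < hi")
        if not (self.low_noise < lo and hi < self.high_noise):
            raise ValueError("water interval must lie inside (low_noise, high_noise)")


@dataclass
class PipelineConfig:
    """Everything one seeded end-to-end run needs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    baseline: BaselineParams = field(default_factory=BaselineParams)
    exclusions: ExclusionRegions = field(default_factory=ExclusionRegions)
    first_timepoint_only: bool = False
    star_levels: int = 4
    out_dir: str = "spcpanel_run"
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        self.acquisition.validate()
        self.baseline.validate()
        self.exclusions.validate()
        if self.star_levels not in (3, 4):
            raise ValueError("star_levels must be 3 or 4")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["marker_corr"] = _pairs_to_str(self.generator.marker_corr)
        d["generator"]["copula_r"] = _pairs_to_str(self.generator.copula_r)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = json.loads(json.dumps(d))  # deep copy, normalise tuples->lists
        g = d.get("generator", {})
        if "marker_corr" in g:
            g["marker_corr"] = _pairs_from_str(g["marker_corr"])
        if "copula_r" in g:
            g["copula_r"] = _pairs_from_str(g["copula_r"])
        if "age_range" in g:
            g["age_range"] = tuple(g["age_range"])
        if "hdl_split" in g:
            g["hdl_split"] = tuple(g["hdl_split"])
        if "self_rated_weights" in g:
            g["self_rated_weights"] = tuple(g["self_rated_weights"])
        a = d.get("acquisition", {})
        if "eretic_factor_range" in a:
            a["eretic_factor_range"] = tuple(a["eretic_factor_range"])
        e = d.get("exclusions", {})
        if "water" in e:
            e["water"] = tuple(e["water"])
        cfg = cls(
            generator=GeneratorConfig(**g),
            acquisition=AcquisitionConfig(**a),
            baseline=BaselineParams(**d.get("baseline", {})),
            exclusions=ExclusionRegions(**e),
            first_timepoint_only=bool(d.get("first_timepoint_only", False)),
            star_levels=int(d.get("star_levels", 4)),
            out_dir=str(d.get("out_dir", "spcpanel_run")),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where a run lands must not change its identity
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
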