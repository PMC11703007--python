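"""Cohort statistics for the inflammatory panel.

Implements the statistical battery applied to the quantified panel:
healthy-participant selection, BMI and age stratification, two-sided
Mann-Whitney rank-sum comparisons between sexes (or BMI classes) with
Benjamini-Hochberg adjustment and star annotation, sex adjustment by
residualisation with grand-mean add-back, Pearson correlations between SPC
sub-regions and lipoprotein phospholipid fractions, percent-excess
summaries and per-group descriptive tables.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AGE_STRATA = ("20-29", "30-39", "40-49", "50-59", "60-70")
HEALTHY_SELF_RATED = {"good", "very good", "excellent"}


def classify_bmi(bmi: float) -> str:
    """WHO BMI classes: underweight < 18.5, normal [18.5, 25),
    overweight [25, 30), obese >= 30 kg/m^2."""
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def age_stratum(age: float) -> Optional[str]:
    """Decade strata 20-29 ... 50-59 plus the closed top stratum 60-70.

    Ages outside [20, 70] do not belong to any stratum and return None (the
    caller logs and excludes such records from age-stratified analyses
    only)."""
    if age < 20.0 or age > 70.0:
        return None
    lo = min(int(age // 10) * 10, 60)
    return "60-70" if lo == 60 else f"{lo}-{lo + 9}"


def filter_healthy(records: pd.DataFrame) -> pd.DataFrame:
    """Select the healthy reference subset.

    Population-cohort records must be non-smokers with no reported medical
    conditions, normal blood pressure, BMI < 30 and self-rated health of at
    least "good".  Basque-cohort records pass unconditionally (recruited as
    healthy controls)."""
    if records.empty:
        return records.copy()
    basque = records["cohort"].eq("basque") if "cohort" in records else pd.Series(False, index=records.index)
    ok = (
        ~records["smoker"].astype(bool)
        & records["n_conditions"].eq(0)
        & records["bp_normal"].astype(bool)
        & (records["bmi"] < 30.0)
        & records["self_rated_health"].isin(HEALTHY_SELF_RATED)
    )
    return records[basque | ok].copy()


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Returns ``(U, p)`` with U the statistic of the first sample (midranks
    for ties).  The p-value is exact (full enumeration of the null
    distribution) when the smaller group has at most 8 observations and
    there are no ties, and otherwise uses the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires two non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stars(p_adjusted: float, levels: int = 4) -> str:
    """Significance stars: * < 0.05, ** < 0.01, *** < 0.001 and, in the
    four-level scheme, **** < 0.0001."""
    thresholds = [0.05, 0.01, 0.001, 0.0001][: levels if levels in (3, 4) else 4]
    out = ""
    for t in thresholds:
        if p_adjusted < t:
            out += "*"
        else:
            break
    return out


@dataclass
class StratumComparison:
    """One group-vs-group rank test inside one stratum."""

    stratum: str
    groups: Tuple[str, str]
    n: Tuple[int, int]
    medians: Tuple[float, float]
    u_stat: float
    p_raw: float
    p_adjusted: float = math.nan
    stars: str = ""
    extra: Dict[str, object] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, object]:
        return {
            "stratum": self.stratum,
            "group_a": self.groups[0],
            "group_b": self.groups[1],
            "n_a": self.n[0],
            "n_b": self.n[1],
            "median_a": self.medians[0],
            "median_b": self.medians[1],
            "U": self.u_stat,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "stars": self.stars,
            **self.extra,
        }


def compare_by_stratum(
    samples: pd.DataFrame,
    marker: str,
    stratifier: str,
    grouping: str = "sex",
    group_order: Optional[Sequence[str]] = None,
    stratum_order: Optional[Sequence[str]] = None,
    star_levels: int = 4,
) -> List[StratumComparison]:
    """Mann-Whitney comparison of two groups inside every stratum.

    One test per stratum; Benjamini-Hochberg adjustment is applied across
    the strata of this one marker/analysis (the BH family).  Strata where
    either group is empty are skipped with a log entry.
    """
    if group_order is None:
        group_order = sorted(samples[grouping].dropna().unique())
    if len(group_order) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly two levels, got {group_order}")
    ga, gb = group_order
    strata = (
        list(stratum_order)
        if stratum_order is not None
        else sorted(samples[stratifier].dropna().unique())
    )
    results: List[StratumComparison] = []
    for st in strata:
        sub = samples[samples[stratifier] == st]
        a = sub.loc[sub[grouping] == ga, marker].dropna().to_numpy()
        b = sub.loc[sub[grouping] == gb, marker].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            logger.info("stratum %r skipped for %s: empty group (%s n=%d, %s n=%d)",
                        st, marker, ga, a.size, gb, b.size)
            continue
        u, p = mann_whitney(a, b)
        results.append(
            StratumComparison(
                stratum=str(st),
                groups=(str(ga), str(gb)),
                n=(a.size, b.size),
                medians=(float(np.median(a)), float(np.median(b))),
                u_stat=u,
                p_raw=p,
            )
        )
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
            r.stars = stars(float(pa), star_levels)
    return results


def adjust_for_sex(values: Sequence[float], sex_labels: Sequence[str]) -> np.ndarray:
    """Residualise on a sex indicator and add back the grand mean.

    Equivalent to an ordinary least-squares fit of the variable on sex:
    within each sex the values are shifted by a constant so both
    post-adjustment sex means equal the grand mean of the unadjusted
    variable; within-sex ordering and spread are untouched."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(sex_labels)
    if v.shape != s.shape:
        raise ValueError("values and sex_labels must have equal length")
    levels = pd.unique(s)
    if len(levels) < 2:
        raise ValueError("adjust_for_sex requires both sexes to be present")
    grand = v.mean()
    out = v.copy()
    for lvl in levels:
        m = s == lvl
        out[m] = v[m] - v[m].mean() + grand
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (with a warning) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson_r: zero variance input, correlation undefined")
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def percent_excess(median_f: float, median_m: float) -> float:
    """Female-over-male percent excess, 100 * (med_f - med_m) / med_m."""
    if not median_m > 0:
        raise ValueError("reference (male) median must be positive")
    return 100.0 * (median_f - median_m) / median_m


def summary_table(
    samples: pd.DataFrame, marker: str, groupers: Sequence[str]
) -> pd.DataFrame:
    """Per-group n, median, quartiles and range of one marker."""
    rows = []
    for key, sub in samples.groupby(list(groupers), observed=True):
        vals = sub[marker].dropna().to_numpy()
        if vals.size == 0:
            logger.info("summary group %r omitted: no observations", key)
            continue
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(groupers, key)),
                "n": vals.size,
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def comparisons_frame(results: List[StratumComparison], **labels: object) -> pd.DataFrame:
    """Tidy one-row-per-comparison frame, with optional constant columns."""
    df = pd.DataFrame([r.as_dict() for r in results])
    for k, v in labels.items():
        df[k] = v
    return df
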