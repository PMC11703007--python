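"""End-to-end orchestration: simulate -> quantify -> analyze.

The pipeline runs either through files (cohort CSV, per-sample spectrum
CSV+JSON pairs and a manifest, as written by ``simulate``) or fully in
memory (``roundtrip_quantify``), which the acceptance machinery and the
tests use to push thousands of spectra through preprocessing without
touching the disk.  Every analysis output is stamped with the
configuration hash, package version and seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    AGE_STRATA,
    adjust_for_sex,
    age_stratum,
    classify_bmi,
    compare_by_stratum,
    comparisons_frame,
    filter_healthy,
    pearson_r,
    percent_excess,
)
from .config import PipelineConfig
from .processing import preprocess
from .quantify import MARKERS, quantify_panel
from .spectrum import read_manifest, read_spectrum, write_manifest, write_spectrum
from .synthetic import generate_cohort, iter_cohort_spectra

logger = logging.getLogger(__name__)

QUANT_COLUMNS = [m + "_q" for m in MARKERS] + [
    "spc_total_q",
    "glyc_total_q",
    "spc_glyc_ratio_q",
]

#: Fig-3-style correlation pairs: (marker column, lipoprotein column).
CORRELATION_PAIRS: List[Tuple[str, str]] = [
    ("spc2", "hdl123_pl"),
    ("spc1", "hdl123_pl"),
    ("spc1", "hdl4_pl"),
    ("spc3", "ldl_pl"),
]


def _provenance(config: PipelineConfig) -> Dict[str, object]:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


# ---------------------------------------------------------------------------
# simulate


def simulate(config: PipelineConfig, out_dir: Optional[str] = None,
             write_spectra: bool = True) -> Dict[str, str]:
    """Generate the cohort (and optionally all spectra) into ``out_dir``.

    Writes ``cohort.csv``, per-sample spectra under ``spectra/`` with a
    ``manifest.csv``, and a ``run.json`` provenance stamp.  Returns the
    paths written.
    """
    config.validate()
    out = out_dir or config.out_dir
    os.makedirs(out, exist_ok=True)
    gen = config.generator
    cohort = generate_cohort(gen)
    cohort_path = os.path.join(out, "cohort.csv")
    cohort.to_csv(cohort_path, index=False)
    paths = {"cohort": cohort_path}

    if write_spectra:
        spec_dir = os.path.join(out, "spectra")
        os.makedirs(spec_dir, exist_ok=True)
        rows = []
        for sample_id, spec in iter_cohort_spectra(cohort, config.acquisition, config.seed):
            csv_path = os.path.join(spec_dir, f"{sample_id}.csv")
            json_path = os.path.join(spec_dir, f"{sample_id}.json")
            write_spectrum(spec, csv_path, json_path, sample_id)
            # manifest paths are relative to the manifest itself, so a run
            # directory can be moved (and reruns are byte-identical)
            rows.append(
                {
                    "sample_id": sample_id,
                    "spectrum_csv": os.path.join("spectra", f"{sample_id}.csv"),
                    "sidecar_json": os.path.join("spectra", f"{sample_id}.json"),
                }
            )
        manifest_path = os.path.join(out, "manifest.csv")
        write_manifest(rows, manifest_path)
        paths["manifest"] = manifest_path

    run_path = os.path.join(out, "run.json")
    with open(run_path, "w") as fh:
        json.dump({**_provenance(config), "n_samples": int(len(cohort))}, fh, indent=1)
    paths["run"] = run_path
    logger.info("simulated %d samples into %s", len(cohort), out)
    return paths


# ---------------------------------------------------------------------------
# quantify


class GridMismatchError(ValueError):
    """Raised when spectra quantified into one cohort use different grids."""


@dataclass
class QuantifyResult:
    panel: pd.DataFrame
    missing: List[str] = field(default_factory=list)
    qc_flags: Dict[str, List[str]] = field(default_factory=dict)


def _panel_row(sample_id: str, spec, config: PipelineConfig,
               grid_sig: List[Tuple[float, int]], qc: Dict[str, List[str]]) -> Dict[str, object]:
    sig = (round(spec.ppm_step, 9), spec.ppm.size)
    if not grid_sig:
        grid_sig.append(sig)
    elif sig != grid_sig[0]:
        raise GridMismatchError(
            f"sample {sample_id}: grid {sig} differs from cohort grid {grid_sig[0]}; "
            "point-sum A.U. are only comparable on a fixed grid"
        )
    pre = preprocess(spec, config.baseline, config.exclusions)
    panel = quantify_panel(pre)
    for flag in panel.flags:
        qc.setdefault(flag, []).append(sample_id)
    d = panel.as_dict()
    return {"sample_id": sample_id, **{k + "_q": v for k, v in d.items()}}


def quantify_manifest(manifest_path: str, config: PipelineConfig) -> QuantifyResult:
    """Preprocess and quantify every spectrum listed in a manifest.

    Missing spectrum files are recorded and skipped; the run continues so
    one bad sample cannot void a cohort (callers decide the exit status).
    """
    manifest = read_manifest(manifest_path)
    root = os.path.dirname(os.path.abspath(manifest_path))
    rows, missing = [], []
    grid_sig: List[Tuple[float, int]] = []
    qc: Dict[str, List[str]] = {}
    for _, entry in manifest.iterrows():
        sid = str(entry["sample_id"])
        csv_path = os.path.join(root, entry["spectrum_csv"])
        json_path = os.path.join(root, entry["sidecar_json"])
        if not (os.path.exists(csv_path) and os.path.exists(json_path)):
            logger.error("sample %s: spectrum files missing", sid)
            missing.append(sid)
            continue
        spec = read_spectrum(csv_path, json_path)
        rows.append(_panel_row(sid, spec, config, grid_sig, qc))
    return QuantifyResult(pd.DataFrame(rows), missing, qc)


def roundtrip_quantify(cohort: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Synthesize, preprocess and quantify every sample in memory.

    Returns the cohort joined with the quantified panel columns
    (``*_q``).  This is the full spectral round trip minus disk I/O.
    """
    rows = []
    grid_sig: List[Tuple[float, int]] = []
    qc: Dict[str, List[str]] = {}
    for sample_id, spec in iter_cohort_spectra(cohort, config.acquisition, config.seed):
        rows.append(_panel_row(sample_id, spec, config, grid_sig, qc))
    panel = pd.DataFrame(rows)
    if qc:
        logger.info("QC flags raised: %s", {k: len(v) for k, v in qc.items()})
    return cohort.merge(panel, on="sample_id", validate="one_to_one")


def passthrough_quantify(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level-only mode: copy generator panels into the quantified
    columns, skipping the spectral layer entirely."""
    out = cohort.copy()
    for m in MARKERS:
        out[m + "_q"] = out[m]
    out["spc_total_q"] = out[["spc1_q", "spc2_q", "spc3_q"]].sum(axis=1)
    out["glyc_total_q"] = out[["glyca_q", "glycb_q"]].sum(axis=1)
    out["spc_glyc_ratio_q"] = out["spc_total_q"] / out["glyc_total_q"]
    return out


# ---------------------------------------------------------------------------
# analyze


PANEL_ANALYSIS_COLUMNS = [m + "_q" for m in MARKERS] + ["spc_total_q", "spc_glyc_ratio_q"]


def analyze(samples: pd.DataFrame, config: PipelineConfig) -> Dict[str, pd.DataFrame]:
    """Run the three study-style analyses on a quantified cohort table.

    * healthy subset: sex comparison per age stratum, per marker;
    * full population (underweight removed): sex comparison per BMI class,
      raw and after sex adjustment (BMI-class comparisons);
    * marker vs lipoprotein-phospholipid Pearson correlations.

    Returns tidy frames keyed ``healthy_age_sex``, ``bmi_sex``,
    ``bmi_adjusted``, ``correlations``, ``healthy_excess`` — each stamped
    with config hash, seed and version.
    """
    config.validate()
    df = samples.copy()
    if config.first_timepoint_only:
        df = df[df["timepoint"] == 1]
    if "bmi_class" not in df:
        df["bmi_class"] = df["bmi"].map(classify_bmi)
    df["age_stratum"] = df["age"].map(age_stratum)
    n_out = int(df["age_stratum"].isna().sum())
    if n_out:
        logger.info("%d records outside 20-70 y excluded from age strata", n_out)
    prov = _provenance(config)
    results: Dict[str, pd.DataFrame] = {}

    # healthy subset, Fig-1 style: male vs female per age stratum
    healthy = filter_healthy(df)
    frames = []
    for marker in PANEL_ANALYSIS_COLUMNS:
        if marker not in healthy:
            continue
        comps = compare_by_stratum(
            healthy.dropna(subset=["age_stratum"]),
            marker,
            stratifier="age_stratum",
            grouping="sex",
            group_order=("male", "female"),
            stratum_order=AGE_STRATA,
            star_levels=3,
        )
        frames.append(comparisons_frame(comps, marker=marker, analysis="healthy_age_sex"))
    results["healthy_age_sex"] = _stamp(pd.concat(frames, ignore_index=True), prov)

    # female-over-male percent excess per age stratum (healthy subset)
    excess_rows = []
    for marker in ("spc2_q", "spc_total_q"):
        if marker not in healthy:
            continue
        for st in AGE_STRATA:
            sub = healthy[healthy["age_stratum"] == st]
            med = sub.groupby("sex")[marker].median()
            if {"male", "female"} <= set(med.index) and med["male"] > 0:
                excess_rows.append(
                    {
                        "marker": marker,
                        "stratum": st,
                        "median_male": med["male"],
                        "median_female": med["female"],
                        "percent_excess": percent_excess(med["female"], med["male"]),
                    }
                )
    results["healthy_excess"] = _stamp(pd.DataFrame(excess_rows), prov)

    # healthy-subset descriptive tables: per-sex n / median / IQR / range
    from .cohort import summary_table

    summaries = []
    for marker in PANEL_ANALYSIS_COLUMNS:
        if marker in healthy and not healthy.empty:
            summaries.append(summary_table(healthy, marker, ["sex"]).assign(marker=marker))
    results["healthy_summary"] = _stamp(
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame(), prov
    )

    # full population, Fig-2 style (underweight removed): sex per BMI class
    pop = df[df["bmi_class"] != "underweight"]
    cls_order = ("normal", "overweight", "obese")
    frames = []
    for marker in PANEL_ANALYSIS_COLUMNS:
        if marker not in pop:
            continue
        comps = compare_by_stratum(
            pop, marker, stratifier="bmi_class", grouping="sex",
            group_order=("male", "female"), stratum_order=cls_order,
            star_levels=config.star_levels,
        )
        frames.append(comparisons_frame(comps, marker=marker, analysis="bmi_sex"))
    results["bmi_sex"] = _stamp(pd.concat(frames, ignore_index=True), prov)

    # sex-adjusted BMI-class comparisons (successive class pairs)
    frames = []
    if pop["sex"].nunique() == 2:
        adj = pop.copy()
        for marker in PANEL_ANALYSIS_COLUMNS:
            if marker not in adj:
                continue
            adj[marker + "_adj"] = adjust_for_sex(adj[marker].to_numpy(), adj["sex"].to_numpy())
            comps = []
            for ca, cb in zip(cls_order[:-1], cls_order[1:]):
                pair = adj[adj["bmi_class"].isin([ca, cb])]
                comps.extend(
                    compare_by_stratum(
                        pair.assign(_pair=f"{ca} vs {cb}"),
                        marker + "_adj", stratifier="_pair", grouping="bmi_class",
                        group_order=(ca, cb), star_levels=config.star_levels,
                    )
                )
            if comps:
                padj = np.asarray([c.p_raw for c in comps])
                from .cohort import bh_adjust, stars as star_fn

                for c, pa in zip(comps, bh_adjust(padj)):
                    c.p_adjusted = float(pa)
                    c.stars = star_fn(float(pa), config.star_levels)
                frames.append(
                    comparisons_frame(comps, marker=marker, analysis="bmi_adjusted")
                )
    if frames:
        results["bmi_adjusted"] = _stamp(pd.concat(frames, ignore_index=True), prov)
    else:
        results["bmi_adjusted"] = _stamp(pd.DataFrame(), prov)

    # Fig-3 style correlations
    corr_rows = []
    have_lipo = all(c in df for c in ("hdl123_pl", "hdl4_pl", "ldl_pl"))
    if have_lipo:
        for marker, frac in CORRELATION_PAIRS:
            mcol = marker + "_q" if marker + "_q" in df else marker
            sub = df[[mcol, frac]].dropna()
            corr_rows.append(
                {
                    "marker": marker,
                    "fraction": frac,
                    "r": pearson_r(sub[mcol], sub[frac]),
                    "n": len(sub),
                }
            )
    else:
        logger.warning("lipoprotein columns missing; correlation analysis skipped")
    results["correlations"] = _stamp(pd.DataFrame(corr_rows), prov)
    return results


def _stamp(df: pd.DataFrame, prov: Dict[str, object]) -> pd.DataFrame:
    out = df.copy()
    for k, v in prov.items():
        out[k] = v
    return out


def write_results(results: Dict[str, pd.DataFrame], out_dir: str) -> Dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame in results.items():
        path = os.path.join(out_dir, f"{name}.csv")
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def run_all(config: PipelineConfig, out_dir: Optional[str] = None,
            no_spectra: bool = False) -> Dict[str, object]:
    """simulate -> quantify -> analyze, writing everything under out_dir."""
    t0 = time.time()
    out = out_dir or config.out_dir
    os.makedirs(out, exist_ok=True)
    cohort = generate_cohort(config.generator)
    cohort.to_csv(os.path.join(out, "cohort.csv"), index=False)
    if no_spectra:
        quantified = passthrough_quantify(cohort)
    else:
        quantified = roundtrip_quantify(cohort, config)
    quantified.to_csv(os.path.join(out, "quantified.csv"), index=False)
    results = analyze(quantified, config)
    paths = write_results(results, os.path.join(out, "results"))
    from .report import render_report

    report = render_report(results, _provenance(config))
    report_path = os.path.join(out, "report.md")
    with open(report_path, "w") as fh:
        fh.write(report)
    summary = {
        **_provenance(config),
        "n_samples": int(len(cohort)),
        "elapsed_s": round(time.time() - t0, 2),
        "results": paths,
        "report": report_path,
    }
    with open(os.path.join(out, "run.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
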