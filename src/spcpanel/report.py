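"""Plain-markdown rendering of the analysis results."""

from __future__ import annotations

from typing import Dict

import pandas as pd

_PROV_COLS = ("config_hash", "seed", "version")


def _table(df: pd.DataFrame) -> str:
    if df.empty:
        return "_no rows_\n"
    show = df.drop(columns=[c for c in _PROV_COLS if c in df])
    num = show.select_dtypes("number").columns
    show[num] = show[num].map(lambda v: f"{v:.4g}")
    header = "| " + " | ".join(show.columns) + " |"
    sep = "|" + "|".join(["---"] * len(show.columns)) + "|"
    rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in show.itertuples(index=False)]
    return "\n".join([header, sep, *rows]) + "\n"


_SECTIONS = [
    ("healthy_age_sex", "Healthy subset: male vs female per age stratum"),
    ("healthy_excess", "Healthy subset: female-over-male percent excess"),
    ("healthy_summary", "Healthy subset: per-sex medians and ranges"),
    ("bmi_sex", "Full population: male vs female per BMI class"),
    ("bmi_adjusted", "Full population, sex-adjusted: successive BMI classes"),
    ("correlations", "SPC sub-regions vs lipoprotein phospholipids (Pearson r)"),
]


def render_report(results: Dict[str, pd.DataFrame], provenance: Dict[str, object]) -> str:
    """Render all result tables as one markdown document."""
    lines = ["# Inflammatory-panel cohort report", ""]
    lines.append(
        "config hash `{config_hash}` | seed {seed} | spcpanel {version}".format(**provenance)
    )
    lines.append("")
    for key, title in _SECTIONS:
        if key not in results:
            continue
        lines.append(f"## {title}")
        lines.append("")
        lines.append(_table(results[key]))
        lines.append("")
    return "\n".join(lines)
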