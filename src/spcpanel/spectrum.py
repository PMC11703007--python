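"""The Spectrum container and its plain-text on-disk dialect.

A spectrum is a (ppm, intensity) pair plus the per-sample acquisition
metadata needed for quantitative comparison: the ERETIC quantification
factor (electronic reference scale) and the water reference position.  On
disk a sample is a two-column CSV (``ppm,intensity``) with a JSON sidecar
carrying the metadata; a manifest CSV maps sample ids to the two files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd


@dataclass
class Spectrum:
    """One 1D spectrum: strictly monotone ppm axis, matching intensities,
    acquisition metadata, and a usable-point mask (True = usable)."""

    ppm: np.ndarray
    intensity: np.ndarray
    eretic_factor: float = 1.0
    water_ppm: float = 4.70
    mask: Optional[np.ndarray] = None
    steps: List[str] = field(default_factory=list)
    flags: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if self.ppm.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not self.eretic_factor > 0:
            raise ValueError(f"eretic_factor must be positive, got {self.eretic_factor}")
        if self.mask is None:
            self.mask = np.ones(self.ppm.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.ppm.shape:
                raise ValueError("mask length must match ppm axis")

    @property
    def ppm_step(self) -> float:
        return float(np.median(np.diff(self.ppm)))

    @property
    def is_preprocessed(self) -> bool:
        return "baseline" in self.steps and "mask" in self.steps

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.ppm.copy(),
            self.intensity.copy(),
            self.eretic_factor,
            self.water_ppm,
            self.mask.copy(),
            list(self.steps),
            dict(self.flags),
        )


# ---------------------------------------------------------------------------
# CSV + JSON dialect


def write_spectrum(s: Spectrum, csv_path: str, json_path: str, sample_id: str = "") -> None:
    pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(csv_path, index=False)
    meta = {
        "sample_id": sample_id,
        "eretic_factor": s.eretic_factor,
        "water_ppm": s.water_ppm,
        "ppm_step": s.ppm_step,
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_spectrum(csv_path: str, json_path: str) -> Spectrum:
    df = pd.read_csv(csv_path)
    with open(json_path) as fh:
        meta = json.load(fh)
    return Spectrum(
        df["ppm"].to_numpy(),
        df["intensity"].to_numpy(),
        eretic_factor=float(meta["eretic_factor"]),
        water_ppm=float(meta.get("water_ppm", 4.70)),
    )


def write_manifest(rows: List[Dict[str, str]], path: str) -> None:
    pd.DataFrame(rows, columns=["sample_id", "spectrum_csv", "sidecar_json"]).to_csv(
        path, index=False
    )


def read_manifest(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)


# ---------------------------------------------------------------------------
# Minimal Bruker-style processed-folder reader (experimental)


def read_bruker_like(folder: str) -> Spectrum:
    """Read a minimal Bruker-style processed-spectrum folder. Experimental.

    Expects ``procs`` (``##$KEY= value`` lines with OFFSET, SW_p, SF, SI),
    an ASCII real-part vector ``1r.txt`` (one intensity per line, ordered
    from the high-field end of the axis), and optionally
    ``QuantFactorSample.xml`` whose ``<QuantFactorSample>`` element holds
    the ERETIC quantification factor.
    """
    params: Dict[str, float] = {}
    with open(os.path.join(folder, "procs")) as fh:
        for line in fh:
            if line.startswith("##$"):
                key, _, val = line[3:].partition("=")
                try:
                    params[key.strip()] = float(val.strip())
                except ValueError:
                    pass
    si = int(params["SI"])
    offset = params["OFFSET"]  # ppm of the first (downfield) point
    sw_ppm = params["SW_p"] / params["SF"]
    intensity = np.loadtxt(os.path.join(folder, "1r.txt"))
    if intensity.size != si:
        raise ValueError(f"1r.txt has {intensity.size} points, procs says SI={si}")
    ppm_desc = offset - np.arange(si) * sw_ppm / (si - 1)
    eretic = 1.0
    xml_path = os.path.join(folder, "QuantFactorSample.xml")
    if os.path.exists(xml_path):
        import xml.etree.ElementTree as ET

        root = ET.parse(xml_path).getroot()
        node = root if root.tag == "QuantFactorSample" else root.find(".//QuantFactorSample")
        if node is not None and node.text:
            eretic = float(node.text)
    # store ascending for integration convenience
    return Spectrum(ppm_desc[::-1].copy(), intensity[::-1].copy(), eretic_factor=eretic)
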