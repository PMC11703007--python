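"""Fixed-window quantification of the five-marker inflammatory panel.

The panel is read off a preprocessed 1D plasma spectrum by plain summation of
intensities over fixed chemical-shift windows (no peak fitting):

* GlycA  2.05-2.09 ppm   (N-acetyl methyls of acute-phase glycoproteins)
* GlycB  2.09-2.12 ppm   (N-acetylneuraminic acid N-acetyls)
* SPC1   3.20-3.236 ppm  (choline headgroups, HDL subfraction 4)
* SPC2   3.236-3.262 ppm (choline headgroups, HDL subfractions 1-3)
* SPC3   3.262-3.30 ppm  (choline headgroups, LDL-associated)

Windows are half-open ``[lo, hi)`` so the shared SPC boundaries (3.236,
3.262) and the Glyc boundary (2.09) are counted exactly once.  Integrals are
raw point-sums at the acquisition grid, so values are in grid-dependent
arbitrary units (A.U.); cohorts must therefore be quantified on a single
grid, which the pipeline layer enforces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, NamedTuple

import numpy as np

from .spectrum import Spectrum

MARKERS = ("glyca", "glycb", "spc1", "spc2", "spc3")


class EmptyWindowError(ValueError):
    """Raised when a ppm window contains no usable (unmasked) grid point."""


@dataclass(frozen=True)
class PpmWindow:
    """Half-open integration window ``[lo, hi)`` in ppm."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window {self.label!r}: need lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        return (ppm >= self.lo) & (ppm < self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: Published integration windows of the five-marker panel (ppm).
CANONICAL_WINDOWS: Dict[str, PpmWindow] = {
    "glyca": PpmWindow(2.05, 2.09, "glyca"),
    "glycb": PpmWindow(2.09, 2.12, "glycb"),
    "spc1": PpmWindow(3.20, 3.236, "spc1"),
    "spc2": PpmWindow(3.236, 3.262, "spc2"),
    "spc3": PpmWindow(3.262, 3.30, "spc3"),
}


class WindowIntegral(NamedTuple):
    value: float
    n_points: int


def integrate_window(s: Spectrum, w: PpmWindow) -> WindowIntegral:
    """Sum intensities at unmasked grid points with ``lo <= ppm < hi``.

    Returns the raw point-sum (A.U.) together with the number of
    contributing points.  Raises :class:`EmptyWindowError` when the window
    holds no usable point — an empty window is distinct from a zero
    integral.
    """
    sel = w.contains(s.ppm) & s.mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyWindowError(f"no usable grid point in window {w.label!r} [{w.lo}, {w.hi})")
    return WindowIntegral(float(s.intensity[sel].sum()), n)


@dataclass
class MarkerPanel:
    """The five marker integrals plus derived totals for one sample.

    ``spc_total`` and ``glyc_total`` are exact sums of their components; the
    SPC/Glyc ratio is NaN (and flagged) when the Glyc total is not positive.
    Negative integrals can arise from noise and are retained, flagged rather
    than clipped, to keep rank-based statistics valid.
    """

    glyca: float
    glycb: float
    spc1: float
    spc2: float
    spc3: float
    flags: Dict[str, object] = field(default_factory=dict)

    @property
    def spc_total(self) -> float:
        return self.spc1 + self.spc2 + self.spc3

    @property
    def glyc_total(self) -> float:
        return self.glyca + self.glycb

    @property
    def spc_glyc_ratio(self) -> float:
        if self.glyc_total > 0:
            return self.spc_total / self.glyc_total
        return math.nan

    def as_dict(self) -> Dict[str, float]:
        d = {m: getattr(self, m) for m in MARKERS}
        d["spc_total"] = self.spc_total
        d["glyc_total"] = self.glyc_total
        d["spc_glyc_ratio"] = self.spc_glyc_ratio
        return d

    def __post_init__(self) -> None:
        neg = [m for m in MARKERS if getattr(self, m) < 0]
        if neg:
            self.flags["negative_integrals"] = neg
        if not self.glyc_total > 0:
            self.flags["ratio_undefined"] = True


def quantify_panel(
    s: Spectrum, windows: Mapping[str, PpmWindow] = CANONICAL_WINDOWS
) -> MarkerPanel:
    """Quantify the five-marker panel from a preprocessed spectrum.

    Requires the spectrum to have been through ``preprocess`` (ERETIC
    scaling, referencing, baseline removal, masking); raw spectra are
    rejected so accidental un-normalised quantification cannot occur.
    """
    if not s.is_preprocessed:
        raise ValueError(
            "spectrum has not been preprocessed (steps seen: %r)" % (s.steps,)
        )
    values = {m: integrate_window(s, windows[m]).value for m in MARKERS}
    panel = MarkerPanel(**values)
    if s.flags.get("calibration_warning"):
        panel.flags["calibration_warning"] = True
    return panel
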