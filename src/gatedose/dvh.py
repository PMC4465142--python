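"""Dose-volume histogram containers, conversions, and dose/volume metrics.

A differential DVH stores the fraction of a structure's volume receiving
dose within each bin; a cumulative DVH stores the fraction receiving at
least a given dose.  All metrics operate on normalized volume fractions;
the absolute structure volume (cm^3) rides along as metadata.

Conventions
-----------
* Differential bins are uniform and identified by their **centers**; the
  default clinical bin width is 0.05 Gy.
* Cumulative values sit on the **left edges** of the differential bins, so
  ``differential_to_cumulative`` followed by ``cumulative_to_differential``
  on the same grid is the identity.
* ``V_xGy`` / ``D_x%`` metrics interpolate linearly between grid points;
  ``dose_at_volume`` also offers a nearest-bin mode for matching treatment
  planning systems that do not interpolate.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialDVH",
    "CumulativeDVH",
    "StructurePlan",
    "differential_to_cumulative",
    "cumulative_to_differential",
    "mean_dose",
    "volume_at_dose",
    "volume_at_relative_dose",
    "dose_at_volume",
    "read_dvh_csv",
    "write_dvh_csv",
    "ORGANS",
    "TECHNIQUES",
    "PLAN_TYPES",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_PRESCRIPTION",
]

ORGANS = ("PTV", "CTV-T", "heart", "LAD", "lung")
TECHNIQUES = ("FB", "EIG")
PLAN_TYPES = ("tangential", "locoregional")

DEFAULT_BIN_WIDTH = 0.05  # Gy
DEFAULT_PRESCRIPTION = 50.0  # Gy, 25 x 2 Gy

#: normalization tolerance accepted on file read (renormalize with warning)
READ_NORM_TOL = 1e-3
#: normalization tolerance enforced internally
NORM_TOL = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialDVH:
    """Normalized differential DVH on a uniform dose grid.

    Parameters
    ----------
    bin_center
        Dose at each bin center, Gy, strictly increasing with constant
        spacing equal to ``bin_width``.
    volume_fraction
        Fraction of the structure volume in each bin (``dV_i``);
        non-negative, summing to 1.
    bin_width
        Bin width in Gy (default 0.05).
    total_volume
        Absolute structure volume in cm^3, optional metadata.
    structure_label
        Free-text structure name.
    """

    bin_center: np.ndarray
    volume_fraction: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    total_volume: Optional[float] = None
    structure_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_center",
                           np.asarray(self.bin_center, dtype=float))
        object.__setattr__(self, "volume_fraction",
                           np.asarray(self.volume_fraction, dtype=float))
        self.validate()

    def validate(self) -> None:
        d, v, w = self.bin_center, self.volume_fraction, self.bin_width
        if d.ndim != 1 or v.ndim != 1 or d.shape != v.shape or d.size == 0:
            raise ValueError("bin_center and volume_fraction must be "
                             "non-empty 1-D arrays of equal length")
        if w <= 0:
            raise ValueError(f"bin_width must be positive, got {w}")
        if np.any(v < 0):
            raise ValueError("volume fractions must be non-negative")
        s = float(v.sum())
        if abs(s - 1.0) > NORM_TOL:
            raise ValueError(
                f"differential DVH not normalized: sum(dV)={s!r} "
                f"deviates from 1 by more than {NORM_TOL}")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if d.size > 1:
            spacing = np.diff(d)
            if np.any(spacing <= 0) or np.any(np.abs(spacing - w) > 1e-9):
                raise ValueError("bin centers must be strictly increasing "
                                 "with constant spacing equal to bin_width")

    @property
    def bin_edges(self) -> np.ndarray:
        """Left bin edges plus the final right edge (length n+1)."""
        left = self.bin_center - self.bin_width / 2.0
        return np.append(left, left[-1] + self.bin_width)

    def rebin(self, bin_width: float) -> "DifferentialDVH":
        """Rebin onto a coarser uniform grid of the given width."""
        return cumulative_to_differential(differential_to_cumulative(self),
                                          bin_width)


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving at least each dose."""

    dose: np.ndarray
    volume_fraction_at_or_above: np.ndarray
    total_volume: Optional[float] = None
    structure_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose", np.asarray(self.dose, dtype=float))
        object.__setattr__(self, "volume_fraction_at_or_above",
                           np.asarray(self.volume_fraction_at_or_above,
                                      dtype=float))
        self.validate()

    def validate(self) -> None:
        d, v = self.dose, self.volume_fraction_at_or_above
        if d.ndim != 1 or v.ndim != 1 or d.shape != v.shape or d.size == 0:
            raise ValueError("dose and volume fraction must be non-empty "
                             "1-D arrays of equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if np.any(np.diff(v) > 1e-9):
            raise ValueError("cumulative DVH must be monotone non-increasing")
        if v[-1] < -1e-12:
            raise ValueError("volume fractions must be non-negative")
        if d[0] <= 1e-12 and abs(v[0] - 1.0) > NORM_TOL:
            raise ValueError(
                f"cumulative DVH value at dose 0 is {v[0]!r}, expected 1")


@dataclass(frozen=True)
class StructurePlan:
    """One structure's DVH within one treatment plan."""

    organ: str
    technique: str
    plan_type: str
    dvh: DifferentialDVH
    prescription_dose: float = DEFAULT_PRESCRIPTION

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}; "
                             f"expected one of {ORGANS}")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; "
                             f"expected one of {TECHNIQUES}")
        if self.plan_type not in PLAN_TYPES:
            raise ValueError(f"unknown plan_type {self.plan_type!r}; "
                             f"expected one of {PLAN_TYPES}")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")

    @property
    def cumulative(self) -> CumulativeDVH:
        return differential_to_cumulative(self.dvh)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def differential_to_cumulative(ddvh: DifferentialDVH) -> CumulativeDVH:
    """Convert a differential DVH to cumulative form.

    The cumulative grid is the left bin edges of the differential grid;
    the value at edge ``e`` is the total fraction in bins with center
    at or above ``e``.
    """
    s = float(ddvh.volume_fraction.sum())
    if abs(s - 1.0) > READ_NORM_TOL:
        raise ValueError(
            f"differential DVH not normalized (sum={s!r}); refusing to "
            "convert — renormalize explicitly first")
    edges = ddvh.bin_center - ddvh.bin_width / 2.0
    # reverse cumulative sum: V(edge_i) = sum_{j>=i} dV_j
    values = np.cumsum(ddvh.volume_fraction[::-1])[::-1]
    # clip fp noise, enforce exact normalization at the lowest edge
    values = np.clip(values, 0.0, None)
    values[0] = s
    edges = np.where(np.abs(edges) < 1e-12, 0.0, edges)
    return CumulativeDVH(dose=edges, volume_fraction_at_or_above=values,
                         total_volume=ddvh.total_volume,
                         structure_label=ddvh.structure_label)


def cumulative_to_differential(cdvh: CumulativeDVH,
                               bin_width: float = DEFAULT_BIN_WIDTH,
                               ) -> DifferentialDVH:
    """Difference a cumulative DVH onto a uniform grid of the given width.

    ``dV_i = V(edge_i) - V(edge_{i+1})``; doses below the input grid carry
    the grid's first value, doses above carry 0, so the differential masses
    sum to ``V(dose[0])``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d, v = cdvh.dose, cdvh.volume_fraction_at_or_above
    # reuse the native grid when it already is a uniform edge grid of the
    # requested width — this makes the differential<->cumulative round trip
    # exact instead of resampling
    if d.size > 1 and np.allclose(np.diff(d), bin_width, atol=1e-9):
        edges = np.append(d, d[-1] + bin_width)
    else:
        start = d[0] - (d[0] % bin_width)
        if start < 0:
            start = 0.0
        n = int(np.ceil((d[-1] - start) / bin_width)) + 1
        edges = start + bin_width * np.arange(n + 1)
    vals = np.interp(edges, d, v, left=v[0], right=0.0)
    dv = vals[:-1] - vals[1:]
    dv = np.clip(dv, 0.0, None)
    # drop empty trailing bins introduced by padding past the grid
    last = int(np.max(np.nonzero(dv))) if np.any(dv > 0) else 0
    dv = dv[:last + 1]
    edges = edges[:last + 2]
    total = float(dv.sum())
    if abs(total - v[0]) > 1e-6:
        # only possible for pathological input; renormalize defensively
        logger.warning("cumulative differencing lost mass (%g vs %g); "
                       "renormalizing", total, v[0])
    if total <= 0:
        raise ValueError("cumulative DVH carries no volume")
    dv = dv / total
    centers = edges[:-1] + bin_width / 2.0
    return DifferentialDVH(bin_center=centers, volume_fraction=dv,
                           bin_width=bin_width,
                           total_volume=cdvh.total_volume,
                           structure_label=cdvh.structure_label)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mean_dose(ddvh: DifferentialDVH) -> float:
    """Mean absorbed dose ``D_mean = sum_i D_i * dV_i`` in Gy."""
    return float(np.dot(ddvh.bin_center, ddvh.volume_fraction))


def volume_at_dose(cdvh: CumulativeDVH, threshold: float) -> float:
    """Fraction of volume receiving more than ``threshold`` Gy (``V_xGy``).

    Linearly interpolated on the cumulative curve; thresholds below the
    grid return 1, above the grid return 0.
    """
    if threshold < 0:
        raise ValueError("dose threshold must be non-negative")
    d, v = cdvh.dose, cdvh.volume_fraction_at_or_above
    if threshold < d[0]:
        return 1.0
    return float(np.interp(threshold, d, v, left=1.0, right=0.0))


def volume_at_relative_dose(cdvh: CumulativeDVH,
                            percent_of_prescription: float,
                            prescription: float = DEFAULT_PRESCRIPTION,
                            ) -> float:
    """``V_x%``: fraction receiving more than x% of the prescription dose."""
    if percent_of_prescription <= 0:
        raise ValueError("percent_of_prescription must be positive")
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    return volume_at_dose(cdvh, prescription * percent_of_prescription / 100.0)


def dose_at_volume(cdvh: CumulativeDVH, volume_fraction: float,
                   method: str = "interpolate") -> float:
    """Dose received by the hottest ``volume_fraction`` of the structure.

    ``D_2%`` is ``dose_at_volume(cdvh, 0.02)``: the smallest dose D with
    V(D) <= volume_fraction, linearly interpolated on the cumulative curve.
    ``method="nearest"`` instead returns the nearest grid dose, matching
    planning systems that do not interpolate DVH exports.
    """
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume_fraction must be in (0, 1]")
    if method not in ("interpolate", "nearest"):
        raise ValueError("method must be 'interpolate' or 'nearest'")
    d, v = cdvh.dose, cdvh.volume_fraction_at_or_above
    if volume_fraction >= v[0]:
        if volume_fraction > v[0] + 1e-12:
            warnings.warn("requested volume fraction exceeds V(0); "
                          "returning 0 Gy", stacklevel=2)
        return 0.0
    if volume_fraction <= v[-1]:
        return float(d[-1])
    # first index where the curve has dropped to <= volume_fraction
    i = int(np.argmax(v <= volume_fraction))
    if method == "nearest":
        return float(d[i] if abs(v[i] - volume_fraction)
                     <= abs(v[i - 1] - volume_fraction) else d[i - 1])
    v0, v1, d0, d1 = v[i - 1], v[i], d[i - 1], d[i]
    if v0 == v1:
        return float(d0)
    return float(d0 + (d1 - d0) * (v0 - volume_fraction) / (v0 - v1))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
#
# One structure per file:
#   # structure=heart
#   # technique=FB
#   # plan_type=tangential
#   # prescription_Gy=50.0
#   # kind=differential
#   # total_volume_cm3=593.2
#   dose_Gy,volume_fraction
#   0.025000,0.000871
#   ...
# The reader auto-detects kind; the writer uses 6-decimal fixed-point
# formatting so re-serialization is byte-stable.

_FLOAT_FMT = "{:.6f}"


def write_dvh_csv(path: Union[str, Path, TextIO],
                  dvh: Union[DifferentialDVH, CumulativeDVH],
                  technique: str = "", plan_type: str = "",
                  prescription_dose: Optional[float] = None) -> None:
    """Write a DVH to the package CSV dialect (see module docstring)."""
    if isinstance(dvh, DifferentialDVH):
        kind = "differential"
        doses, fracs = dvh.bin_center, dvh.volume_fraction
        extra = [f"# bin_width_Gy={_FLOAT_FMT.format(dvh.bin_width)}"]
    else:
        kind = "cumulative"
        doses, fracs = dvh.dose, dvh.volume_fraction_at_or_above
        extra = []
    lines = [f"# structure={dvh.structure_label}"]
    if technique:
        lines.append(f"# technique={technique}")
    if plan_type:
        lines.append(f"# plan_type={plan_type}")
    if prescription_dose is not None:
        lines.append(f"# prescription_Gy={_FLOAT_FMT.format(prescription_dose)}")
    lines.append(f"# kind={kind}")
    if dvh.total_volume is not None:
        lines.append(f"# total_volume_cm3={_FLOAT_FMT.format(dvh.total_volume)}")
    lines.extend(extra)
    lines.append("dose_Gy,volume_fraction")
    for d, f in zip(doses, fracs):
        lines.append(f"{_FLOAT_FMT.format(d)},{_FLOAT_FMT.format(f)}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_dvh_csv(path: Union[str, Path, TextIO]
                 ) -> tuple[Union[DifferentialDVH, CumulativeDVH], dict]:
    """Read a DVH CSV file; returns ``(dvh, metadata)``.

    The kind is auto-detected from the ``# kind=`` header.  Differential
    DVHs whose mass deviates from 1 by more than 1e-3 are rejected; smaller
    deviations are renormalized with a warning.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    meta: dict = {}
    doses, fracs = [], []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        elif line[0].isdigit() or line[0] in "+-.":
            d, _, f = line.partition(",")
            doses.append(float(d))
            fracs.append(float(f))
        # else: column header row, skipped
    if not doses:
        raise ValueError(f"no DVH rows found in {path!r}")
    kind = meta.get("kind", "differential")
    total_volume = (float(meta["total_volume_cm3"])
                    if "total_volume_cm3" in meta else None)
    label = meta.get("structure", "")
    doses_a = np.asarray(doses)
    fracs_a = np.asarray(fracs)
    if kind == "cumulative":
        dvh: Union[DifferentialDVH, CumulativeDVH] = CumulativeDVH(
            dose=doses_a, volume_fraction_at_or_above=fracs_a,
            total_volume=total_volume, structure_label=label)
    elif kind == "differential":
        s = float(fracs_a.sum())
        if abs(s - 1.0) > READ_NORM_TOL:
            raise ValueError(
                f"differential DVH in {path!r} is not normalized "
                f"(sum={s!r}, tolerance {READ_NORM_TOL})")
        if abs(s - 1.0) > NORM_TOL:
            # deviations below 1e-4 are expected 6-decimal rounding noise
            if abs(s - 1.0) > 1e-4:
                warnings.warn(
                    f"renormalizing DVH (sum deviated by {s - 1.0:g})",
                    stacklevel=2)
            else:
                logger.debug("renormalizing DVH (rounding noise %g)", s - 1.0)
            fracs_a = fracs_a / s
        width = float(meta.get("bin_width_Gy", 0.0))
        if width <= 0:
            width = (float(np.median(np.diff(doses_a))) if len(doses_a) > 1
                     else DEFAULT_BIN_WIDTH)
        dvh = DifferentialDVH(bin_center=doses_a, volume_fraction=fracs_a,
                              bin_width=width, total_volume=total_volume,
                              structure_label=label)
    else:
        raise ValueError(f"unknown DVH kind {kind!r}")
    return dvh, meta
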