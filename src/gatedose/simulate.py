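"""Seeded generator of paired free-breathing / gated DVH cohorts.

Real breathing-adapted planning studies compare, per patient, a
free-breathing (FB) plan against an enhanced-inspiration-gating (EIG) plan
computed on a second CT of the same anatomy.  No public DVH data exist for
such cohorts, so this module emulates them parametrically: each organ at
risk gets a two-component cumulative DVH

    V(D) = (1 - f_hi) * exp(-D / lambda) + f_hi * logistic((D_hi - D) / w)

— an exponential low-dose scatter tail plus a high-dose shoulder near the
field edge dose ``D_hi`` — differenced onto a 0.05 Gy grid.  The in-field
volume fraction ``f_hi`` is drawn log-normally per patient; gating
multiplies it by an organ-specific effect multiplier (default 0.10 for
heart and LAD: inspiration pulls the heart out of the tangential fields;
1.0 for the lung under tangential fields and 0.8 under locoregional
fields).  Targets get a Gaussian cumulative fall-off around the
prescription, renormalized to a mean dose of exactly 50 Gy.

Pairing structure is real: both techniques share the patient's latent
anatomy draw (f_hi location, shoulder position, structure-volume factor),
with small independent per-technique noise on top.  With all effect
multipliers set to 1 the two techniques are exchangeable, so paired tests
are calibrated at their nominal level; with multipliers < 1 the gated DVH
is, by construction, at or below the free-breathing DVH at every dose in
the shoulder region.

Default calibration constants are medians a tangential/locoregional breast
cohort of 16 patients per stratum would report (e.g. heart V_25Gy ~ 2.2%
FB vs ~ 0.2% EIG under tangential fields); they are stochastic targets at
n = 16, not exact claims, and every constant is overridable through
:class:`CohortConfig`.

Draw order (stable across versions, per patient): breathing amplitude;
then for each organ in ``(PTV, CTV-T, heart, LAD, lung)`` restricted to
``config.organs``, the organ's latent draws in the order documented in
:func:`draw_patient`; then the beam's-eye-view geometry draws.  Restricting
``config.organs`` therefore changes the stream for later organs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from scipy.special import expit

from .cohort import PatientPlanPair
from .dvh import (DEFAULT_BIN_WIDTH, DEFAULT_PRESCRIPTION, ORGANS,
                  DifferentialDVH, StructurePlan)
from .geometry import BeamsEyeViewScene

logger = logging.getLogger(__name__)

__all__ = [
    "OrganModel", "TargetModel", "MhdModel", "CohortConfig",
    "PatientDraw", "draw_patient",
    "generate_oar_dvh", "generate_target_dvh", "generate_cohort",
]

OAR_ORGANS = ("heart", "LAD", "lung")
TARGET_ORGANS = ("PTV", "CTV-T")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganModel:
    """Generative parameters for one organ at risk.

    ``f_hi_median``/``f_hi_sigma``: log-normal location and log-sd of the
    in-field volume fraction.  ``effect_multiplier``: factor applied to
    ``f_hi`` under gating (1 = no effect).  ``lam``: mean of the
    exponential low-dose tail, Gy.  ``d_hi``/``d_hi_sigma``: shoulder
    position draw, Gy.  ``shoulder_width``: logistic width, Gy.  Structure
    volumes (cm^3) are log-normal around per-technique medians.
    """

    f_hi_median: float
    f_hi_sigma: float
    effect_multiplier: float
    lam: float
    volume_median_fb: float
    volume_median_eig: float
    d_hi: float = 45.0
    d_hi_sigma: float = 1.5
    shoulder_width: float = 2.0
    volume_sigma: float = 0.18

    def __post_init__(self) -> None:
        if self.f_hi_median <= 0 or self.lam <= 0 or self.shoulder_width <= 0:
            raise ValueError("scale parameters must be positive")
        if not 0 < self.effect_multiplier <= 1:
            raise ValueError("effect_multiplier must be in (0, 1]")


@dataclass(frozen=True)
class TargetModel:
    """Gaussian fall-off width (Gy) and volume (cm^3) draws for a target."""

    falloff_median: float
    falloff_sigma: float
    volume_median_fb: float
    volume_median_eig: float
    volume_sigma: float = 0.5
    falloff_pair_sigma: float = 0.05


@dataclass(frozen=True)
class MhdModel:
    """Beam's-eye-view heart-penetration draws, cm.

    FB penetration depth is log-normal; the gated depth is the FB depth
    minus a log-normal inspiration shift, so a sufficiently large shift
    pulls the heart fully out of the field (MHD = 0).
    """

    depth_median_fb: float
    depth_sigma: float = 0.40
    shift_median: float = 0.9
    shift_sigma: float = 0.30
    heart_radius: float = 5.0


def _default_organ_models(plan_type: str) -> dict[str, OrganModel]:
    if plan_type == "tangential":
        return {
            "heart": OrganModel(0.022, 0.60, 0.10, lam=1.55,
                                volume_median_fb=593, volume_median_eig=580,
                                volume_sigma=0.15),
            "LAD": OrganModel(0.40, 0.80, 0.10, lam=2.2, d_hi=43.0,
                              volume_median_fb=1.8, volume_median_eig=1.8,
                              volume_sigma=0.25),
            "lung": OrganModel(0.091, 0.45, 1.0, lam=1.4,
                               volume_median_fb=1132,
                               volume_median_eig=1765),
        }
    return {
        "heart": OrganModel(0.033, 0.60, 0.10, lam=1.67,
                            volume_median_fb=613, volume_median_eig=615,
                            volume_sigma=0.15),
        "LAD": OrganModel(0.514, 0.60, 0.10, lam=6.8, d_hi=43.0,
                          volume_median_fb=1.7, volume_median_eig=1.8,
                          volume_sigma=0.25),
        "lung": OrganModel(0.27, 0.40, 0.8, lam=2.5,
                           volume_median_fb=1047, volume_median_eig=1683),
    }


def _default_target_models(plan_type: str) -> dict[str, TargetModel]:
    if plan_type == "tangential":
        return {
            "PTV": TargetModel(1.57, 0.09, 891, 888),
            "CTV-T": TargetModel(0.60, 0.25, 40, 43, volume_sigma=0.6),
        }
    return {
        "PTV": TargetModel(1.57, 0.09, 1136, 1092),
        "CTV-T": TargetModel(0.60, 0.25, 40, 41, volume_sigma=0.6),
    }


def _default_mhd_model(plan_type: str) -> MhdModel:
    if plan_type == "tangential":
        return MhdModel(depth_median_fb=1.3, shift_median=0.9)
    return MhdModel(depth_median_fb=1.7, shift_median=1.1)


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic paired cohort.

    ``pair_sigma`` is the per-technique log-noise on ``f_hi`` around the
    shared latent draw (smaller = more strongly correlated FB/EIG plans);
    ``volume_pair_sigma`` plays the same role for structure volumes.
    """

    n_patients: int = 16
    plan_type: str = "tangential"
    seed: int = 0
    organs: tuple[str, ...] = ORGANS
    include_geometry: bool = True
    pair_sigma: float = 0.25
    volume_pair_sigma: float = 0.05
    prescription_dose: float = DEFAULT_PRESCRIPTION
    bin_width: float = DEFAULT_BIN_WIDTH
    max_dose: float = 60.0
    amplitude_median_mm: float = 7.0
    amplitude_sigma: float = 0.28
    organ_models: dict[str, OrganModel] = field(default_factory=dict)
    target_models: dict[str, TargetModel] = field(default_factory=dict)
    mhd_model: Optional[MhdModel] = None

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.plan_type not in ("tangential", "locoregional"):
            raise ValueError(f"unknown plan_type {self.plan_type!r}")
        unknown = set(self.organs) - set(ORGANS)
        if unknown:
            raise ValueError(f"unknown organs {sorted(unknown)}")
        if self.pair_sigma < 0 or self.volume_pair_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        om = dict(_default_organ_models(self.plan_type))
        om.update(self.organ_models)
        object.__setattr__(self, "organ_models", om)
        tm = dict(_default_target_models(self.plan_type))
        tm.update(self.target_models)
        object.__setattr__(self, "target_models", tm)
        if self.mhd_model is None:
            object.__setattr__(self, "mhd_model",
                               _default_mhd_model(self.plan_type))
        if self.plan_type == "locoregional" and self.amplitude_median_mm == 7.0:
            object.__setattr__(self, "amplitude_median_mm", 6.9)

    def with_effect_multipliers(self, multipliers: dict[str, float]
                                ) -> "CohortConfig":
        """Return a config with per-organ effect multipliers overridden."""
        om = {organ: replace(model,
                             effect_multiplier=multipliers.get(
                                 organ, model.effect_multiplier))
              for organ, model in self.organ_models.items()}
        return replace(self, organ_models=om)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CohortConfig":
        """Load a config from YAML; unknown top-level keys are rejected.

        ``effect_multipliers: {organ: value}`` is accepted as a shorthand
        for overriding only that field of the organ models.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        multipliers = raw.pop("effect_multipliers", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "organs" in raw:
            raw["organs"] = tuple(raw["organs"])
        if "organ_models" in raw:
            raw["organ_models"] = {k: OrganModel(**v)
                                   for k, v in raw["organ_models"].items()}
        if "target_models" in raw:
            raw["target_models"] = {k: TargetModel(**v)
                                    for k, v in raw["target_models"].items()}
        if "mhd_model" in raw:
            raw["mhd_model"] = MhdModel(**raw["mhd_model"])
        config = cls(**raw)
        if multipliers:
            config = config.with_effect_multipliers(multipliers)
        return config


# ---------------------------------------------------------------------------
# per-patient latent draws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganDraw:
    """Latent DVH parameters for one organ of one patient, both techniques."""

    f_hi: dict[str, float]        # technique -> in-field fraction
    lam: float
    d_hi: float
    shoulder_width: float
    volume: dict[str, float]      # technique -> cm^3


@dataclass(frozen=True)
class TargetDraw:
    falloff: dict[str, float]     # technique -> Gy
    volume: dict[str, float]


@dataclass(frozen=True)
class PatientDraw:
    """All latent variables of one synthetic patient."""

    patient_id: str
    plan_type: str
    amplitude_mm: float
    organs: dict[str, OrganDraw]
    targets: dict[str, TargetDraw]
    mhd_depth: Optional[dict[str, float]] = None  # technique -> cm, signed
    scene_angle: float = 0.0
    scene_offset: tuple[float, float] = (0.0, 0.0)


def draw_patient(config: CohortConfig, patient_id: str,
                 rng: np.random.Generator) -> PatientDraw:
    """Draw one patient's latent parameters.

    Per organ at risk the draw order is: shared anatomy factor ``z``;
    shoulder position; per-technique ``f_hi`` noise (FB then EIG); shared
    volume factor; per-technique volume noise (FB then EIG).  Targets draw
    the shared fall-off width, per-technique fall-off noise (FB then EIG),
    then the shared and per-technique volume factors.  Geometry draws FB
    depth, inspiration shift, rotation angle and offset.
    """
    amplitude = config.amplitude_median_mm * float(
        np.exp(config.amplitude_sigma * rng.standard_normal()))
    organs: dict[str, OrganDraw] = {}
    targets: dict[str, TargetDraw] = {}
    for organ in ORGANS:
        if organ not in config.organs:
            continue
        if organ in TARGET_ORGANS:
            tm = config.target_models[organ]
            falloff_base = tm.falloff_median * float(
                np.exp(tm.falloff_sigma * rng.standard_normal()))
            falloff = {
                tech: falloff_base * float(
                    np.exp(tm.falloff_pair_sigma * rng.standard_normal()))
                for tech in ("FB", "EIG")}
            zv = rng.standard_normal()
            vol = {
                "FB": tm.volume_median_fb * float(
                    np.exp(tm.volume_sigma * zv
                           + config.volume_pair_sigma * rng.standard_normal())),
                "EIG": tm.volume_median_eig * float(
                    np.exp(tm.volume_sigma * zv
                           + config.volume_pair_sigma * rng.standard_normal())),
            }
            targets[organ] = TargetDraw(falloff=falloff, volume=vol)
        else:
            om = config.organ_models[organ]
            z = rng.standard_normal()
            f_base = om.f_hi_median * float(np.exp(om.f_hi_sigma * z))
            d_hi = om.d_hi + om.d_hi_sigma * float(rng.standard_normal())
            f_fb = f_base * float(
                np.exp(config.pair_sigma * rng.standard_normal()))
            f_eig = f_base * om.effect_multiplier * float(
                np.exp(config.pair_sigma * rng.standard_normal()))
            if om.effect_multiplier < 1.0:
                # gating reduces the in-field fraction by construction
                f_eig = min(f_eig, f_fb)
            cap = 0.95
            zv = rng.standard_normal()
            vol = {
                "FB": om.volume_median_fb * float(
                    np.exp(om.volume_sigma * zv
                           + config.volume_pair_sigma * rng.standard_normal())),
                "EIG": om.volume_median_eig * float(
                    np.exp(om.volume_sigma * zv
                           + config.volume_pair_sigma * rng.standard_normal())),
            }
            organs[organ] = OrganDraw(
                f_hi={"FB": min(f_fb, cap), "EIG": min(f_eig, cap)},
                lam=om.lam, d_hi=d_hi,
                shoulder_width=om.shoulder_width, volume=vol)
    mhd_depth = None
    angle = 0.0
    offset = (0.0, 0.0)
    if config.include_geometry:
        mm = config.mhd_model
        depth_fb = mm.depth_median_fb * float(
            np.exp(mm.depth_sigma * rng.standard_normal()))
        shift = mm.shift_median * float(
            np.exp(mm.shift_sigma * rng.standard_normal()))
        mhd_depth = {"FB": depth_fb, "EIG": depth_fb - shift}
        angle = float(rng.uniform(0.0, 2.0 * np.pi))
        offset = (float(rng.uniform(-3.0, 3.0)),
                  float(rng.uniform(-3.0, 3.0)))
    return PatientDraw(patient_id=patient_id, plan_type=config.plan_type,
                       amplitude_mm=amplitude, organs=organs,
                       targets=targets, mhd_depth=mhd_depth,
                       scene_angle=angle, scene_offset=offset)


# ---------------------------------------------------------------------------
# DVH construction
# ---------------------------------------------------------------------------

def _oar_cumulative(dose: np.ndarray, f_hi: float, lam: float,
                    d_hi: float, width: float) -> np.ndarray:
    """Two-component cumulative DVH: exponential tail + logistic shoulder."""
    return ((1.0 - f_hi) * np.exp(-dose / lam)
            + f_hi * expit((d_hi - dose) / width))


def _grid(config_or_width, max_dose: float) -> np.ndarray:
    width = (config_or_width.bin_width
             if isinstance(config_or_width, CohortConfig) else config_or_width)
    n = int(round(max_dose / width))
    return width * np.arange(n + 1)


def generate_oar_dvh(organ: str, technique: str, draw: PatientDraw,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     max_dose: float = 60.0) -> DifferentialDVH:
    """Differential DVH of one organ at risk under one technique.

    Deterministic given the patient's latent draw; paired FB/EIG DVHs share
    the draw so the pairing structure is real.
    """
    if organ not in draw.organs:
        raise ValueError(f"no draw for organ {organ!r}; "
                         f"available: {sorted(draw.organs)}")
    od = draw.organs[organ]
    edges = _grid(bin_width, max_dose)
    vals = _oar_cumulative(edges, od.f_hi[technique], od.lam,
                           od.d_hi, od.shoulder_width)
    dv = vals[:-1] - vals[1:]
    dv = np.clip(dv, 0.0, None)
    dv /= dv.sum()
    return DifferentialDVH(bin_center=edges[:-1] + bin_width / 2.0,
                           volume_fraction=dv, bin_width=bin_width,
                           total_volume=od.volume[technique],
                           structure_label=organ)


def generate_target_dvh(organ: str, technique: str, draw: PatientDraw,
                        bin_width: float = DEFAULT_BIN_WIDTH,
                        max_dose: float = 60.0,
                        prescription_dose: float = DEFAULT_PRESCRIPTION,
                        ) -> DifferentialDVH:
    """Differential DVH of a target volume (PTV or CTV-T).

    Gaussian dose spread around the prescription with the patient's drawn
    fall-off width; the grid is then shifted so the mean dose equals the
    prescription exactly, emulating normalization to the target mean dose.
    """
    if organ not in draw.targets:
        raise ValueError(f"no draw for target {organ!r}; "
                         f"available: {sorted(draw.targets)}")
    td = draw.targets[organ]
    edges = _grid(bin_width, max_dose)
    centers = edges[:-1] + bin_width / 2.0
    dv = np.exp(-0.5 * ((centers - prescription_dose)
                        / td.falloff[technique]) ** 2)
    dv /= dv.sum()
    mean = float(np.dot(centers, dv))
    centers = centers + (prescription_dose - mean)
    return DifferentialDVH(bin_center=centers, volume_fraction=dv,
                           bin_width=bin_width,
                           total_volume=td.volume[technique],
                           structure_label=organ)


def _make_scene(depth: float, angle: float, offset: tuple[float, float],
                radius: float, n_vertices: int = 24) -> BeamsEyeViewScene:
    """Circular heart polygon penetrating ``depth`` cm past the edge.

    Built axis-aligned (vertical edge at x=0, field at x<0, heart centered
    at ``x = radius - depth``) then rigidly rotated and translated; MHD is
    invariant under the rigid motion.  ``depth <= 0`` leaves the heart
    fully out of field.
    """
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    contour = np.column_stack([radius * np.cos(theta) + (radius - depth),
                               radius * np.sin(theta)])
    point = np.zeros(2)
    normal = np.array([-1.0, 0.0])
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    off = np.asarray(offset)
    return BeamsEyeViewScene(heart_contour=contour @ rot.T + off,
                             edge_point=rot @ point + off,
                             edge_normal=rot @ normal)


def generate_patient(config: CohortConfig, patient_id: str,
                     rng: np.random.Generator) -> PatientPlanPair:
    """Draw and materialize one patient's paired plans."""
    draw = draw_patient(config, patient_id, rng)
    pair = PatientPlanPair(patient_id=patient_id,
                           plan_type=config.plan_type,
                           breathing_amplitude_mm=draw.amplitude_mm)
    for organ in config.organs:
        for technique in ("FB", "EIG"):
            if organ in TARGET_ORGANS:
                dvh = generate_target_dvh(
                    organ, technique, draw, bin_width=config.bin_width,
                    max_dose=config.max_dose,
                    prescription_dose=config.prescription_dose)
            else:
                dvh = generate_oar_dvh(
                    organ, technique, draw, bin_width=config.bin_width,
                    max_dose=config.max_dose)
            pair.plans[(organ, technique)] = StructurePlan(
                organ=organ, technique=technique,
                plan_type=config.plan_type, dvh=dvh,
                prescription_dose=config.prescription_dose)
    if config.include_geometry:
        for technique in ("FB", "EIG"):
            pair.scenes[technique] = _make_scene(
                draw.mhd_depth[technique], draw.scene_angle,
                draw.scene_offset, config.mhd_model.heart_radius)
    return pair


def generate_cohort(config: CohortConfig) -> list[PatientPlanPair]:
    """Generate the full paired cohort, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    return [generate_patient(config, f"P{i + 1:02d}", rng)
            for i in range(config.n_patients)]
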