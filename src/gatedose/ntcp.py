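"""Relative seriality NTCP model with a Poisson dose-response curve.

The probability that a uniformly irradiated voxel responds is the Poisson
dose-response

    P(D) = 2 ** (-exp(e * gamma * (1 - D / D50)))

with ``e`` Euler's number, ``gamma`` the maximum normalized slope of the
dose-response curve and ``D50`` the uniform dose giving 50% response.
Whole-organ complication probability follows the relative seriality model

    NTCP = (1 - prod_i [1 - P(D_i)^s] ** dV_i) ** (1/s)

over the bins of a normalized differential DVH.  The seriality parameter
``s`` in (0, 1] encodes tissue architecture: s -> 1 is a serial organ
(complication driven by the hottest subvolume), s -> 0 a parallel one.

The product is accumulated in log space because for strongly parallel
organs (s ~ 0.01) each factor 1 - P^s is tiny and a naive product
underflows.

The built-in parameter registry covers excess cardiac mortality for the
whole heart and radiation pneumonitis for the ipsilateral lung, the latter
with technique-specific fits (tangential vs locoregional beam arrangements)
re-derived for a type-b photon dose algorithm.  No fractionation (LQ/EQD2)
correction is applied: the parameters are used at the 2 Gy/fraction
reference schedule of a 50 Gy / 25 fraction prescription.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dvh import DifferentialDVH

logger = logging.getLogger(__name__)

__all__ = [
    "EndpointParams",
    "poisson_response",
    "relative_seriality_ntcp",
    "get_endpoint_params",
    "register_endpoint_params",
    "ENDPOINTS",
]

ENDPOINTS = ("cardiac_mortality", "radiation_pneumonitis")

# clamps for the log-space product: P below this behaves as 0, above the
# upper clamp the factor 1 - P^s vanishes and NTCP saturates at 1
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-15


@dataclass(frozen=True)
class EndpointParams:
    """Parameters of one dose-response endpoint.

    ``s`` is the relative seriality factor in (0, 1], ``gamma`` the maximum
    normalized slope (unitless), ``D50`` the 50%-response uniform dose in Gy.
    """

    endpoint: str
    s: float
    gamma: float
    D50: float
    plan_scope: str = "any"
    source_label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.s <= 1:
            raise ValueError(f"seriality s must be in (0, 1], got {self.s}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.D50 <= 0:
            raise ValueError(f"D50 must be positive, got {self.D50}")


# registry keyed by (endpoint, plan_type); "any" matches every plan type
_REGISTRY: dict[tuple[str, str], EndpointParams] = {}


def register_endpoint_params(params: EndpointParams) -> None:
    """Add or override an entry in the endpoint parameter registry."""
    _REGISTRY[(params.endpoint, params.plan_scope)] = params


for _p in (
    EndpointParams("cardiac_mortality", s=1.0, gamma=1.28, D50=52.3,
                   plan_scope="any",
                   source_label="whole heart, excess cardiac mortality"),
    EndpointParams("radiation_pneumonitis", s=0.012, gamma=0.974, D50=27.52,
                   plan_scope="tangential",
                   source_label="ipsilateral lung, tangential fields, "
                                "type-b algorithm fit"),
    EndpointParams("radiation_pneumonitis", s=0.012, gamma=0.966, D50=29.23,
                   plan_scope="locoregional",
                   source_label="ipsilateral lung, locoregional fields, "
                                "type-b algorithm fit"),
):
    register_endpoint_params(_p)


def get_endpoint_params(endpoint: str, plan_type: str = "any",
                        ) -> EndpointParams:
    """Look up registered dose-response parameters.

    Falls back to a plan-scope of ``"any"`` when no technique-specific
    entry exists for ``plan_type``.
    """
    for key in ((endpoint, plan_type), (endpoint, "any")):
        if key in _REGISTRY:
            return _REGISTRY[key]
    known = sorted({k[0] for k in _REGISTRY})
    raise KeyError(
        f"no parameters registered for endpoint {endpoint!r} with plan "
        f"type {plan_type!r}; known endpoints: {known}")


def poisson_response(dose, params: EndpointParams):
    """Poisson dose-response ``P(D) = 2^(-exp(e*gamma*(1 - D/D50)))``.

    Accepts a scalar or array dose in Gy; strictly increasing in dose,
    with P(D50) = 1/2 exactly.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    p = np.exp2(-np.exp(math.e * params.gamma * (1.0 - d / params.D50)))
    if np.isscalar(dose) or d.ndim == 0:
        return float(p)
    return p


def relative_seriality_ntcp(ddvh: DifferentialDVH,
                            params: EndpointParams) -> float:
    """Whole-organ NTCP of a differential DVH under the seriality model.

    Accumulates ``sum_i dV_i * log(1 - P_i^s)`` and exponentiates once,
    clamping each ``P_i`` to ``[1e-300, 1 - 1e-15]`` so that strongly
    parallel organs (small ``s``) do not underflow.  Returns a probability
    in [0, 1].
    """
    s = params.s
    if s <= 0:
        raise ValueError("relative seriality model undefined for s <= 0")
    p = np.asarray(poisson_response(ddvh.bin_center, params))
    if np.any((p >= _P_CEIL) & (ddvh.volume_fraction > 0)):
        warnings.warn("P(D)^s reached 1 within machine precision; "
                      "NTCP saturates at 1", stacklevel=2)
        return 1.0
    p = np.clip(p, _P_FLOOR, _P_CEIL)
    log_ps = s * np.log(p)          # log(P^s)
    ps = np.exp(log_ps)
    # log(1 - P^s), accurate when P^s is close to 1
    log_terms = np.log1p(-ps)
    log_prod = float(np.dot(ddvh.volume_fraction, log_terms))
    inner = -math.expm1(log_prod)   # 1 - prod_i (1 - P_i^s)^dV_i
    if inner <= 0.0:
        return 0.0
    return min(1.0, inner ** (1.0 / s))
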