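"""Fuzzy-entropy reliability scoring of detected hotspots.

Each fuzzy cluster, viewed as a fuzzy set over the N event points, has a
De Luca–Termini entropy built from Shannon's function

    h(u) = -u log2 u - (1 - u) log2 (1 - u),     h(0) = h(1) = 0,

averaged over the points: H = (1/N) sum_j h(u_ij), normalized in [0, 1].
A crisp cluster (every membership 0 or 1) has H = 0; a maximally ambiguous
one (every membership 1/2) has H = 1.  The hotspot's reliability is the
complement R = 1 - H: high when memberships are polarized near 0/1, i.e.
when the cluster boundary is decisive, and low when they hover near 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import pi

import numpy as np
from scipy.special import xlogy

from .efcm_core import EFCMConfig, EFCMResult, EventSet, run_efcm

STD_CONVENTIONS = ("population", "sample")


class DomainError(ValueError):
    """Argument outside the mathematical domain of the operation."""


def entropy_function(u):
    """Shannon's function h(u) on [0, 1], the fuzzy-entropy kernel.

    Vectorized; h(0) = h(1) = 0 by the 0*log(0) := 0 convention, h(1/2) = 1,
    symmetric about 1/2, increasing on [0, 1/2] and decreasing on [1/2, 1].
    """
    arr = np.asarray(u, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("membership degree must lie in [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / np.log(2.0)
    # xlogy keeps the endpoints exact; clip the float noise just inside.
    h = np.clip(h, 0.0, 1.0) + 0.0  # clip float noise; +0.0 drops any -0.0
    return float(h) if np.isscalar(u) or arr.ndim == 0 else h


def cluster_entropy(memberships) -> float:
    """Normalized fuzziness of one cluster: H = (1/N) sum_j h(u_j) in [0, 1]."""
    v = np.asarray(memberships, dtype=float)
    if v.size == 0:
        raise DomainError("membership vector must be non-empty")
    return float(np.mean(entropy_function(v)))


def reliability(entropy: float) -> float:
    """Reliability of a hotspot: R = 1 - H."""
    if not 0.0 <= entropy <= 1.0:
        raise DomainError("fuzziness must lie in [0, 1]")
    return 1.0 - entropy


def membership_std(memberships, convention: str = "population") -> float:
    """Fluctuation of a cluster's membership degrees over all N points.

    The population convention (divide by N) is the default; ``sample``
    divides by N - 1.
    """
    v = np.asarray(memberships, dtype=float)
    if v.size == 0:
        raise DomainError("membership vector must be non-empty")
    if convention not in STD_CONVENTIONS:
        raise DomainError(f"convention must be one of {STD_CONVENTIONS}")
    ddof = 0 if convention == "population" else 1
    if ddof and v.size < 2:
        raise DomainError("sample convention needs at least 2 values")
    return float(np.std(v, ddof=ddof))


@dataclass(frozen=True)
class HotspotReport:
    """Everything reported about one detected hotspot.

    ``center_xy`` is in the projected plane (meters); ``center_lonlat`` is
    filled in by the geographic layer when a projection is known, else None.
    ``area_km2`` is the circle area pi r^2 converted from m^2.
    ``reliability_class`` is attached by the classification layer.
    """

    hotspot_id: int
    center_xy: tuple[float, float]
    radius_m: float
    area_km2: float
    membership_std: float
    entropy: float
    reliability: float
    center_lonlat: tuple[float, float] | None = None
    reliability_class: str | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.reliability, 1.0 - self.entropy):
            raise DomainError("reliability must equal 1 - entropy")
        if not (0.0 <= self.entropy <= 1.0 and 0.0 <= self.reliability <= 1.0):
            raise DomainError("entropy and reliability must lie in [0, 1]")
        if self.area_km2 < 0 or self.radius_m < 0:
            raise DomainError("radius and area must be non-negative")

    def with_class(self, label: str) -> "HotspotReport":
        return replace(self, reliability_class=label)

    def with_lonlat(self, lon: float, lat: float) -> "HotspotReport":
        return replace(self, center_lonlat=(lon, lat))


def reports_from_result(result: EFCMResult,
                        std_convention: str = "population"
                        ) -> list[HotspotReport]:
    """Score every cluster of a finished EFCM run.

    For each final cluster: fuzzy entropy H over all N points, reliability
    R = 1 - H, the membership standard deviation (same N points), and the
    circle area pi r^2 in km^2.
    """
    reports = []
    for i, proto in enumerate(result.prototypes):
        row = result.partition.u[i]
        h = cluster_entropy(row)
        reports.append(HotspotReport(
            hotspot_id=i + 1,
            center_xy=(float(proto.center[0]), float(proto.center[1])),
            radius_m=float(proto.radius),
            area_km2=pi * float(proto.radius) ** 2 * 1e-6,
            membership_std=membership_std(row, std_convention),
            entropy=h,
            reliability=reliability(h),
        ))
    return reports


def evaluate_hotspots(events: EventSet, config: EFCMConfig | None = None,
                      std_convention: str = "population"
                      ) -> list[HotspotReport]:
    """End-to-end pipeline: run EFCM, then score each hotspot's reliability."""
    result = run_efcm(events, config or EFCMConfig())
    return reports_from_result(result, std_convention)
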