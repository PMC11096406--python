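"""Nominal stress-strain conversion and mechanical-property extraction.

Force-displacement records from uniaxial tension are converted to nominal
(engineering) measures, sigma_N = F/A0 and eps_N = dL/L0, and three
properties are read off each curve: ultimate tensile (UT) stress and strain
at the failure peak, and toughness as the area under the curve up to that
peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StressStrainCurve",
    "MechanicalProperties",
    "to_stress_strain",
    "extract_properties",
    "clean_monotone",
]


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired nominal strain (dimensionless) and stress (MPa) for one specimen."""

    strain: np.ndarray
    stress: np.ndarray
    sample_id: str = ""
    rate_class: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        if self.strain.shape != self.stress.shape or self.strain.size < 2:
            raise ValueError("strain and stress must be equal-length series of >= 2 points")
        if self.strain[0] != 0:
            raise ValueError("strain series must start at 0")

    def truncated(self, index: int) -> "StressStrainCurve":
        """Curve restricted to points 0..index inclusive."""
        return replace(self, strain=self.strain[: index + 1], stress=self.stress[: index + 1])


@dataclass(frozen=True)
class MechanicalProperties:
    """UT stress (MPa), UT strain (-), toughness (MPa) and the peak index."""

    ut_stress: float
    ut_strain: float
    toughness: float
    failure_index: int


def to_stress_strain(record) -> StressStrainCurve:
    """Convert a force-displacement record to a nominal stress-strain curve.

    sigma_N = F/A0 in N/mm^2 = MPa; eps_N = dL/L0.  Point order is
    preserved; geometry must be strictly positive.
    """
    if not (record.area > 0) or not (record.gauge_length > 0):
        raise ValueError("gauge area and length must be positive")
    return StressStrainCurve(
        strain=np.asarray(record.displacement, dtype=float) / record.gauge_length,
        stress=np.asarray(record.force, dtype=float) / record.area,
        sample_id=record.sample_id,
        rate_class=record.rate_class,
    )


def _failure_index(stress: np.ndarray) -> int:
    # First occurrence of the global maximum, extended through any
    # contiguous plateau of equal values.  Non-contiguous ties keep the
    # first occurrence; a constant curve therefore resolves to its last
    # index and retains its full area.
    i = int(np.argmax(stress))
    while i + 1 < stress.size and stress[i + 1] == stress[i]:
        i += 1
    return i


def extract_properties(curve: StressStrainCurve) -> MechanicalProperties:
    """Read UT stress/strain and toughness off a nominal stress-strain curve.

    The failure peak is the global stress maximum (plateau convention in
    ``_failure_index``); toughness is the trapezoidal integral of stress
    over strain from the origin up to that peak, so any post-peak tail is
    excluded.
    """
    i = _failure_index(curve.stress)
    toughness = float(np.trapezoid(curve.stress[: i + 1], curve.strain[: i + 1]))
    return MechanicalProperties(
        ut_stress=float(curve.stress[i]),
        ut_strain=float(curve.strain[i]),
        toughness=toughness,
        failure_index=i,
    )


def clean_monotone(record):
    """Drop points whose displacement does not increase on the previous kept one.

    Raw grip-displacement series can stall or jitter backwards; the cleaned
    record keeps a strictly nondecreasing displacement (first point always
    kept).  A warning is emitted when points are dropped.  Returns a new
    record of the same type.
    """
    disp = np.asarray(record.displacement, dtype=float)
    force = np.asarray(record.force, dtype=float)
    keep = np.ones(disp.size, dtype=bool)
    last = disp[0]
    for j in range(1, disp.size):
        if disp[j] < last:
            keep[j] = False
        else:
            last = disp[j]
    if not keep.all():
        warnings.warn(
            f"{record.sample_id or 'record'}: dropped {int((~keep).sum())} "
            "non-monotone displacement points",
            stacklevel=2,
        )
    return replace(record, displacement=disp[keep], force=force[keep])
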