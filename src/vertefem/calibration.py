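"""Linear HU -> apparent-density calibration with a non-negativity floor.

The CT attenuation of excised cortical cores is related to their measured
apparent density by an ordinary-least-squares line

    rho = a + HU * b      (g/cm^3),

clamped from below at a small positive floor (default 0.01 g/cm^3) so
that low-attenuation voxels never receive a non-physical density.  The
default constants are a = 0.48 g/cm^3 and b = 4.6e-4 g/cm^3 per HU.

Note on the default slope: the source table for these constants prints a
slope of 4.6e+4, which would yield densities of ~1e7 g/cm^3 at a few
hundred HU; this package assumes a sign-of-exponent typo and defaults to
4.6e-4, emitting a log line whenever the default is instantiated.  Both
constants are overridable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_INTERCEPT = 0.48  # g/cm^3
DEFAULT_SLOPE = 4.6e-4  # g/cm^3 per HU (printed-exponent typo assumed; see module docstring)
DEFAULT_FLOOR = 0.01  # g/cm^3


@dataclass
class CalibrationLine:
    """rho = max(a + HU*b, floor), densities in g/cm^3."""

    a: float = DEFAULT_INTERCEPT
    b: float = DEFAULT_SLOPE
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("density floor must be > 0")
        if not np.isfinite(self.b):
            raise ValueError("slope must be finite")
        if self.b <= 0:
            warnings.warn("calibration slope b <= 0: density decreases with HU", stacklevel=2)
        if self.b == DEFAULT_SLOPE:
            logger.info(
                "using default calibration slope 4.6e-4 g/cm^3/HU "
                "(sign-of-exponent typo in the printed constant assumed)"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"a": self.a, "b": self.b, "floor": self.floor}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationLine":
        with open(path) as fh:
            d = json.load(fh)
        return cls(a=d["a"], b=d["b"], floor=d.get("floor", DEFAULT_FLOOR))


@dataclass
class DensityField:
    """Apparent densities aligned with a voxel volume or with mesh elements.

    ``values`` has the source volume's 3-D shape when ``per_element`` is
    False, or one entry per mesh element otherwise.  In-mask / per-element
    values are always >= the calibration floor.
    """

    values: np.ndarray
    per_element: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def fit_calibration(samples) -> CalibrationLine:
    """OLS fit of the density line through ``(HU, density)`` core samples.

    Needs at least two samples with non-identical HU; the floor is left at
    its default (the fit concerns only the linear part).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (HU, density) sample pairs")
    hu, rho = arr[:, 0], arr[:, 1]
    if np.ptp(hu) == 0:
        raise ValueError("all HU values identical: calibration design is rank-deficient")
    b, a = np.polyfit(hu, rho, 1)
    return CalibrationLine(a=float(a), b=float(b))


def hu_to_density(volume, line: CalibrationLine) -> DensityField:
    """Apply the calibration line to the in-mask voxels of ``volume``.

    Out-of-mask (air) voxels are set to the floor so the returned grid is
    uniformly valid; they are excluded from meshing by the mask anyway.
    """
    volume.validate()
    rho = np.maximum(line.a + volume.values * line.b, line.floor)
    rho[~volume.mask] = line.floor
    return DensityField(values=rho, per_element=False)


def density_to_hu(rho, line: CalibrationLine) -> np.ndarray:
    """Inverse map HU = (rho - a)/b, used to build phantoms with known density."""
    if line.b == 0:
        raise ValueError("slope is zero: density line is not invertible")
    return (np.asarray(rho, dtype=float) - line.a) / line.b
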