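"""Synthetic CT phantoms and synthetic compression experiments.

Every downstream stage of the pipeline (calibration, meshing, solving,
post-processing, comparison) is exercised on data produced here, so the
generators are first-class, deterministic, and seeded.

Coordinate convention, used everywhere in this package:

* axis 0 — mediolateral (ML),
* axis 1 — anteroposterior (AP, anterior = +),
* axis 2 — axial (cranial = +),

with voxel centers at ``origin + (index + 0.5) * spacing`` (mm).
Air is -1000 HU and is excluded by the mask before any calibration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .postprocess import LoadDisplacementCurve

AIR_HU = -1000.0


class DegenerateGeometryError(ValueError):
    """Raised when a phantom request cannot produce a sensible voxel mask."""


@dataclass
class VoxelVolume:
    """A 3-D grid of Hounsfield-unit values with spacing metadata.

    Stands in for a quantitative CT acquisition of an excised vertebral
    body: ``values`` are HU, ``mask`` marks bone voxels, ``spacing`` and
    ``origin`` are in mm.  Optional acquisition metadata (tube current,
    kVp, ...) may ride along in ``meta`` but is never interpreted.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical dimensions")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        if not self.mask.any():
            raise ValueError("mask is empty")
        # 6-connectivity: structure of squared distance 1
        _, n_comp = ndimage.label(self.mask)
        if n_comp != 1:
            raise ValueError(f"mask has {n_comp} 6-connected components, expected 1")

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinate vectors (mm)."""
        return tuple(
            self.origin[a] + (np.arange(self.values.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )


@dataclass
class PhantomSpec:
    """Geometry and HU parameters of the vertebral-body phantom.

    The phantom is an elliptical cylinder (semi-axes ``semi_axis_ap`` and
    ``semi_axis_ml``) with a cosine-modulated concave waist, a bright
    cortical shell of ``shell_thickness`` mm and a dimmer, heterogeneous
    trabecular core.  All HU defaults are plausible-but-invented: no
    quantitative HU statistics of real specimens back them.
    """

    height: float = 22.0
    semi_axis_ap: float = 14.0
    semi_axis_ml: float = 11.0
    waist_fraction: float = 0.85
    shell_thickness: float = 2.0
    hu_cortical: float = 1300.0
    hu_trabecular_mean: float = 350.0
    hu_trabecular_sd: float = 60.0
    voxel: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("height", "semi_axis_ap", "semi_axis_ml", "shell_thickness", "voxel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.waist_fraction <= 1):
            raise ValueError("waist_fraction must lie in (0, 1]")
        if self.hu_cortical <= self.hu_trabecular_mean:
            raise ValueError("hu_cortical must exceed hu_trabecular_mean")
        if self.hu_trabecular_sd < 0:
            raise ValueError("hu_trabecular_sd must be >= 0")
        if self.voxel > min(self.semi_axis_ap, self.semi_axis_ml) or self.voxel > self.height:
            raise DegenerateGeometryError(
                "voxel size exceeds a phantom semi-axis; geometry would degenerate"
            )


def _waist_scale(z_frac: np.ndarray, waist_fraction: float) -> np.ndarray:
    """In-plane scale factor: 1 at both endplates, waist_fraction at mid-height."""
    return waist_fraction + (1.0 - waist_fraction) * (1.0 + np.cos(2.0 * np.pi * z_frac)) / 2.0


def make_vertebra_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Generate a vertebral-body-like HU volume from a :class:`PhantomSpec`.

    The mask is an elliptical cylinder whose semi-axes shrink to
    ``waist_fraction`` of their endplate values at mid-height (concave
    waist).  Voxels within ``shell_thickness`` of the lateral boundary get
    ``hu_cortical``; interior voxels carry a smoothed, seeded Gaussian HU
    field with the requested mean and standard deviation; everything
    outside the mask is air (-1000 HU).  Endplates are flat (the phantom
    emulates polished, plate-cut specimens).
    """
    spec.validate()
    v = spec.voxel
    # one-voxel lateral air margin; flat endplates flush with the grid in z
    nx = int(np.ceil(2 * spec.semi_axis_ml / v)) + 2
    ny = int(np.ceil(2 * spec.semi_axis_ap / v)) + 2
    nz = int(np.ceil(spec.height / v))
    origin = np.array([-nx * v / 2.0, -ny * v / 2.0, 0.0])
    spacing = np.array([v, v, v])

    x = origin[0] + (np.arange(nx) + 0.5) * v
    y = origin[1] + (np.arange(ny) + 0.5) * v
    z = origin[2] + (np.arange(nz) + 0.5) * v
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    s = _waist_scale(Z / spec.height, spec.waist_fraction)
    r2 = (X / (spec.semi_axis_ml * s)) ** 2 + (Y / (spec.semi_axis_ap * s)) ** 2
    mask = r2 <= 1.0

    # lateral cortical shell: in-plane erosion so only the side wall is shell
    n_erode = max(1, int(round(spec.shell_thickness / v)))
    cross_2d = np.zeros((3, 3, 1), dtype=bool)
    cross_2d[1, :, 0] = True
    cross_2d[:, 1, 0] = True
    interior = ndimage.binary_erosion(mask, structure=cross_2d, iterations=n_erode)
    shell = mask & ~interior

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(size=(nx, ny, nz))
    if spec.hu_trabecular_sd > 0:
        smooth = ndimage.uniform_filter(noise, size=3, mode="wrap")
        smooth = (smooth - smooth.mean()) / smooth.std()
        trab = spec.hu_trabecular_mean + spec.hu_trabecular_sd * smooth
    else:
        trab = np.full_like(noise, spec.hu_trabecular_mean)

    values = np.full((nx, ny, nz), AIR_HU)
    values[interior] = trab[interior]
    values[shell] = spec.hu_cortical

    vol = VoxelVolume(values=values, spacing=spacing, origin=origin, mask=mask)
    vol.validate()
    return vol


def make_bar_phantom(
    length_mm: float, cross_section_mm: float, hu_value: float, voxel: float
) -> VoxelVolume:
    """Rectangular-prism verification phantom of uniform HU.

    The bar is ``cross_section_mm`` square in the transverse plane and
    ``length_mm`` tall along the axial axis.  Both dimensions must be
    integer multiples of ``voxel``.
    """
    if length_mm <= 0 or cross_section_mm <= 0 or voxel <= 0:
        raise ValueError("all dimensions must be > 0")
    n_axial = length_mm / voxel
    n_cross = cross_section_mm / voxel
    if abs(n_axial - round(n_axial)) > 1e-9 or abs(n_cross - round(n_cross)) > 1e-9:
        raise ValueError("bar dimensions must be integer multiples of the voxel size")
    n_axial, n_cross = int(round(n_axial)), int(round(n_cross))

    # one-voxel air margin laterally, flat ends axially
    nx = ny = n_cross + 2
    nz = n_axial
    values = np.full((nx, ny, nz), AIR_HU)
    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[1:-1, 1:-1, :] = True
    values[mask] = hu_value
    origin = np.array([-nx * voxel / 2.0, -ny * voxel / 2.0, 0.0])
    vol = VoxelVolume(
        values=values, spacing=np.array([voxel] * 3), origin=origin, mask=mask
    )
    vol.validate()
    return vol


@dataclass
class SpecimenRecord:
    """One synthetic specimen: ground truth plus its emitted bilinear curve."""

    true_stiffness: float  # kN/mm
    true_strength: float  # kN
    curve: LoadDisplacementCurve


@dataclass
class SyntheticExperiment:
    """A set of synthetic 'experimental' load-displacement records.

    Emulates the dispersion of bench-top axial compression tests on
    vertebral bodies: per specimen, stiffness and strength are drawn from
    normals truncated at zero and a bilinear curve (linear ramp, then a
    plateau at the strength) is sampled on a fixed displacement grid.
    """

    records: list[SpecimenRecord]
    stiffness_mean_sd: tuple[float, float]
    strength_mean_sd: tuple[float, float]
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def stiffnesses(self) -> np.ndarray:
        return np.array([r.true_stiffness for r in self.records])

    @property
    def strengths(self) -> np.ndarray:
        return np.array([r.true_strength for r in self.records])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at zero (redraw; degenerate when sd == 0)."""
    if sd == 0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    else:
        raise ValueError("could not draw positive truncated-normal samples")
    return out


def make_synthetic_experiment(
    n_specimens: int,
    stiffness_mean_sd: tuple[float, float] = (9.54, 1.1),
    strength_mean_sd: tuple[float, float] = (10.2, 0.86),
    seed: int = 0,
    d_max: float = 2.5,
    n_points: int = 101,
) -> SyntheticExperiment:
    """Draw per-specimen (stiffness, strength) pairs and emit bilinear curves.

    Defaults reproduce the dispersion observed across bench compression
    tests of lower-thoracic porcine vertebral bodies (stiffness
    9.54 +/- 1.1 kN/mm, strength 10.2 +/- 0.86 kN).  Each curve is
    ``load = K*d`` up to ``d = F/K`` and constant ``F`` beyond, sampled on
    a fixed grid of ``n_points`` displacements spanning [0, d_max] mm.
    """
    if n_specimens < 1:
        raise ValueError("n_specimens must be >= 1")
    if stiffness_mean_sd[1] < 0 or strength_mean_sd[1] < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    K = _truncated_normal(rng, *stiffness_mean_sd, n_specimens)
    F = _truncated_normal(rng, *strength_mean_sd, n_specimens)
    d = np.linspace(0.0, d_max, n_points)
    records = []
    for k, f in zip(K, F):
        load = np.minimum(k * d, f)
        records.append(
            SpecimenRecord(
                true_stiffness=float(k),
                true_strength=float(f),
                curve=LoadDisplacementCurve(displacement=d.copy(), load=load),
            )
        )
    return SyntheticExperiment(
        records=records,
        stiffness_mean_sd=tuple(stiffness_mean_sd),
        strength_mean_sd=tuple(strength_mean_sd),
        seed=seed,
    )
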