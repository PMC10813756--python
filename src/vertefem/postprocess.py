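"""Stiffness, strength and fracture-pattern extraction.

Simulated and experimental load-displacement curves pass through the same
extractors (single code path): stiffness is the ordinary-least-squares
slope over the ascending branch restricted to loads in a configurable
fraction window of the peak (default 20-80 %), and strength is the curve
maximum.  The fracture map labels elements into anterior / lateral /
posterior sectors around the axial axis through the center of mass and
flags elements whose equivalent plastic strain (PEEQ) exceeds a small
threshold as failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SECTORS = ("anterior", "lateral-left", "lateral-right", "posterior")


@dataclass
class LoadDisplacementCurve:
    """Sampled load-displacement curve: displacement in mm, load in kN."""

    displacement: np.ndarray
    load: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)

    def validate(self) -> None:
        if self.displacement.shape != self.load.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and load must be 1-D arrays of equal length")
        if len(self.displacement) < 3:
            raise ValueError("curve needs at least 3 samples")
        if self.displacement[0] != 0.0:
            raise ValueError("displacement must start at 0")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")


@dataclass
class SpecimenResult:
    """Extracted scalar outcomes of one specimen (simulated or experimental)."""

    stiffness: float  # kN/mm
    strength: float  # kN
    fit_window: tuple[int, int]  # [first, last] curve indices used for the slope
    source: str = "simulated"


def extract_stiffness(
    curve: LoadDisplacementCurve, window: tuple[float, float] = (0.2, 0.8)
) -> tuple[float, tuple[int, int]]:
    """OLS slope (kN/mm) of the linear trajectory of the curve.

    Points are taken from the ascending branch (up to the load maximum)
    whose load lies within ``window`` fractions of the peak load; the
    index window actually used is returned alongside the slope.
    """
    curve.validate()
    peak = float(np.max(curve.load))
    if peak <= 0:
        raise ValueError("peak load must be positive")
    i_peak = int(np.argmax(curve.load))
    lo, hi = window
    idx = np.nonzero(
        (np.arange(len(curve.load)) <= i_peak)
        & (curve.load >= lo * peak)
        & (curve.load <= hi * peak)
    )[0]
    if len(idx) < 3:
        raise ValueError(
            f"only {len(idx)} curve points fall in the {lo:.0%}-{hi:.0%} fit window; "
            "need at least 3 (refine the displacement schedule)"
        )
    d, f = curve.displacement[idx], curve.load[idx]
    slope = float(np.polyfit(d, f, 1)[0])
    return slope, (int(idx[0]), int(idx[-1]))


def extract_strength(curve: LoadDisplacementCurve) -> float:
    """Peak load (kN) of the curve.

    For an elastic-perfectly-plastic solve the global maximum coincides
    with the highest point of the elastic response (plateau onset), so the
    global maximum is used.
    """
    curve.validate()
    return float(np.max(curve.load))


def specimen_result(
    curve: LoadDisplacementCurve,
    window: tuple[float, float] = (0.2, 0.8),
    source: str = "simulated",
) -> SpecimenResult:
    """Run both extractors on one curve."""
    k, w = extract_stiffness(curve, window)
    return SpecimenResult(stiffness=k, strength=extract_strength(curve), fit_window=w, source=source)


@dataclass
class FractureMap:
    """Per-element failure flags and the anterior/lateral/posterior breakdown."""

    peeq: np.ndarray  # final PEEQ per element
    sector: np.ndarray  # str labels per element, values in SECTORS
    yielded: np.ndarray  # bool per element
    sector_fraction: dict  # sector -> yielded-element fraction within the sector
    sector_mean_peeq: dict  # sector -> mean final PEEQ over the sector
    threshold: float


def sector_labels(
    centroids: np.ndarray,
    center: np.ndarray,
    anterior_direction: np.ndarray,
    axial_direction: np.ndarray,
    half_angle_deg: float = 45.0,
) -> np.ndarray:
    """Angular sector of each centroid about the axial axis through ``center``.

    Anterior within +/- ``half_angle_deg`` of the anterior direction,
    posterior within the mirrored cone, lateral-left / lateral-right
    otherwise (split by the sign of the mediolateral coordinate).
    """
    axial = axial_direction / np.linalg.norm(axial_direction)
    ant = anterior_direction - np.dot(anterior_direction, axial) * axial
    ant = ant / np.linalg.norm(ant)
    ml = np.cross(axial, ant)
    rel = centroids - center
    a = rel @ ant
    m = rel @ ml
    phi = np.degrees(np.arctan2(m, a))  # 0 deg = anterior
    labels = np.where(
        np.abs(phi) <= half_angle_deg,
        "anterior",
        np.where(
            np.abs(phi) >= 180.0 - half_angle_deg,
            "posterior",
            np.where(m > 0, "lateral-left", "lateral-right"),
        ),
    )
    return labels.astype(object)


def fracture_map(solution, mesh, frame, peeq_threshold: float = 1e-8) -> FractureMap:
    """Label failed elements and summarize the sector pattern.

    ``peeq_threshold`` = 0 reproduces the literal "nonzero plastic strain"
    failure rule; the small default absorbs round-off.
    """
    if peeq_threshold < 0:
        raise ValueError("peeq_threshold must be >= 0")
    if not solution.peeq_history:
        raise ValueError("solution holds no increments")
    peeq = np.asarray(solution.peeq_history[-1])
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    labels = sector_labels(
        centroids, frame.center_of_mass, frame.anterior_direction, frame.transverse_normal
    )
    yielded = peeq > peeq_threshold
    frac, mean_p = {}, {}
    for s in SECTORS:
        in_s = labels == s
        frac[s] = float(yielded[in_s].mean()) if in_s.any() else 0.0
        mean_p[s] = float(peeq[in_s].mean()) if in_s.any() else 0.0
    return FractureMap(
        peeq=peeq,
        sector=labels,
        yielded=yielded,
        sector_fraction=frac,
        sector_mean_peeq=mean_p,
        threshold=peeq_threshold,
    )
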