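"""Parallel-beam forward model over a short-scan arc, with polychromatic noise.

The forward projector computes line integrals through a 2-D slice by Joseph
style interpolating ray sampling (bilinear interpolation at half-voxel steps
along each ray).  The measurement model attenuates a small tabulated photon
spectrum through the phantom's material map and optionally draws Poisson
counts; this is the mechanism that produces beam-hardening bands and photon
starvation streaks around metal, the corruption the correction pipeline has
to remove.

Geometry is a short scan: view angles span 220 degrees by default, mirroring
rotational flat-detector acquisition.  Protocol presets fix the number of
views (5 s -> 133, 10 s -> 248, 20 s -> 496 projections).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .phantoms import Phantom

__all__ = [
    "AcquisitionGeometry",
    "ProtocolPreset",
    "PROTOCOL_PRESETS",
    "Sinogram",
    "PhysicsModel",
    "make_geometry",
    "default_geometry",
    "forward_project",
    "simulate_measurement",
    "to_line_integrals",
]


@dataclass(frozen=True)
class ProtocolPreset:
    """Acquisition protocol: name, projection count, injection route."""

    name: str
    n_views: int
    injection_route: str


PROTOCOL_PRESETS: dict[str, ProtocolPreset] = {
    "5s": ProtocolPreset("5s", 133, "intraarterial"),
    "10s": ProtocolPreset("10s", 248, "intravenous"),
    "20s": ProtocolPreset("20s", 496, "intravenous"),
}


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Short-scan parallel-beam sampling of the sinogram.

    ``angles_deg`` are strictly increasing and span ``span_deg``; detector
    bins are centered on the rotation axis with ``bin_spacing_mm`` pitch.
    """

    angles_deg: tuple[float, ...]
    n_bins: int
    bin_spacing_mm: float
    beam: str = "parallel"

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg)
        if a.ndim != 1 or len(a) < 2 or np.any(np.diff(a) <= 0):
            raise ValueError("angles_deg must be strictly increasing, length >= 2")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if self.bin_spacing_mm <= 0:
            raise ValueError("bin_spacing_mm must be positive")
        if self.beam != "parallel":
            raise ValueError(f"beam={self.beam!r}: only parallel geometry is supported")

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    @property
    def span_deg(self) -> float:
        return self.angles_deg[-1] - self.angles_deg[0]

    @property
    def bin_positions_mm(self) -> np.ndarray:
        """Signed detector coordinates of bin centers (mm)."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing_mm


@dataclass
class Sinogram:
    """views x bins grid of either line integrals or pre-log photon counts."""

    values: np.ndarray
    kind: str  # "line_integral" | "photon_count"
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_views, self.geometry.n_bins):
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_bins})"
            )
        if self.kind not in ("line_integral", "photon_count"):
            raise ValueError(f"unknown sinogram kind {self.kind!r}")
        if self.kind == "photon_count" and np.any(self.values < 0):
            raise ValueError("photon counts must be non-negative")
        if self.kind == "line_integral" and not np.all(np.isfinite(self.values)):
            raise ValueError("line integrals must be finite")

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Sinogram":
        return Sinogram(values, kind or self.kind, self.geometry)


@dataclass(frozen=True)
class PhysicsModel:
    """Photon spectrum, incident fluence and noise switch.

    ``energies_kev``/``weights`` tabulate the source spectrum (weights are
    normalized on construction); ``incident_photons`` is the unattenuated
    count per detector bin.  ``noise`` is "none" or "poisson".
    """

    energies_kev: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0, 90.0)
    weights: tuple[float, ...] = (0.15, 0.25, 0.30, 0.20, 0.10)
    incident_photons: float = 1e5
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if len(self.energies_kev) != len(w):
            raise ValueError("spectrum energies and weights differ in length")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("spectrum weights must be non-negative, not all zero")
        object.__setattr__(self, "weights", tuple(w / w.sum()))
        if self.incident_photons <= 0:
            raise ValueError(f"incident_photons={self.incident_photons} invalid; must be > 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise={self.noise!r} invalid; expected 'none' or 'poisson'")

    @property
    def spectrum(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        return (self.energies_kev, self.weights)

    def monochromatic(self, energy_kev: float = 70.0) -> "PhysicsModel":
        """Single-bin noiseless variant, for exactness checks."""
        return replace(self, energies_kev=(energy_kev,), weights=(1.0,), noise="none")


def make_geometry(preset: str | ProtocolPreset, n_bins: int, bin_spacing_mm: float,
                  span_deg: float = 220.0, start_deg: float = 0.0) -> AcquisitionGeometry:
    """Equally spaced short-scan geometry for a named protocol preset."""
    if isinstance(preset, str):
        try:
            preset = PROTOCOL_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown protocol preset {preset!r}; expected one of "
                f"{sorted(PROTOCOL_PRESETS)}"
            ) from None
    angles = start_deg + np.linspace(0.0, span_deg, preset.n_views)
    return AcquisitionGeometry(tuple(angles), n_bins, bin_spacing_mm)


def default_geometry(preset: str = "5s", grid_size: int = 512,
                     voxel_size_mm: float | None = None) -> AcquisitionGeometry:
    """Geometry whose detector just covers a grid's inscribed field of view."""
    from .phantoms import FOV_MM

    voxel = FOV_MM / grid_size if voxel_size_mm is None else voxel_size_mm
    n_bins = grid_size + 1 - grid_size % 2  # odd, center bin on the axis
    return make_geometry(preset, n_bins=n_bins, bin_spacing_mm=voxel)


def forward_project(image: np.ndarray, geometry: AcquisitionGeometry,
                    voxel_size_mm: float, step_fraction: float = 0.5) -> Sinogram:
    """Line integrals (mm x 1/mm) of a square image over the scan arc.

    Rays are sampled at ``step_fraction`` of a voxel with bilinear
    interpolation; samples outside the grid contribute zero.  The operation
    is linear in the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    n = image.shape[0]
    c = (n - 1) / 2.0
    step = step_fraction * voxel_size_mm
    half_diag = 0.5 * np.sqrt(2.0) * n * voxel_size_mm
    n_steps = int(np.ceil(2 * half_diag / step)) + 1
    t = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step  # along-ray parameter

    s = geometry.bin_positions_mm
    out = np.empty((geometry.n_views, geometry.n_bins))
    for i, ang in enumerate(geometry.angles_deg):
        th = np.deg2rad(ang)
        # Detector axis u, ray direction v.
        ux, uy = np.cos(th), np.sin(th)
        vx, vy = -np.sin(th), np.cos(th)
        px = s[:, None] * ux + t[None, :] * vx
        py = s[:, None] * uy + t[None, :] * vy
        rows = py / voxel_size_mm + c
        cols = px / voxel_size_mm + c
        samples = ndimage.map_coordinates(image, [rows.ravel(), cols.ravel()],
                                          order=1, mode="constant", cval=0.0)
        out[i] = samples.reshape(geometry.n_bins, n_steps).sum(axis=1) * step
    return Sinogram(out, "line_integral", geometry)


def _material_line_integrals(phantom: Phantom, geometry: AcquisitionGeometry) -> dict[int, np.ndarray]:
    """Per-material path lengths (mm) through the label map, one projection each."""
    out = {}
    for label in sorted(phantom.materials):
        indicator = (phantom.labels == label).astype(float)
        if not indicator.any():
            continue
        out[label] = forward_project(indicator, geometry, phantom.voxel_size_mm).values
    return out


def simulate_measurement(phantom: Phantom, geometry: AcquisitionGeometry,
                         physics: PhysicsModel) -> Sinogram:
    """Polychromatic photon-count sinogram of a phantom.

    Expected counts are ``I0 * sum_E w_E exp(-int mu_E dl)`` where the
    per-energy attenuation integral is assembled from per-material path
    lengths, so any number of energy bins costs one projection per material.
    With ``noise="poisson"`` counts are drawn from a generator seeded by
    ``physics.seed``; with a single energy bin and no noise the log-transform
    recovers the reference line integrals exactly.

    ``contrast_level`` in the scenario scales the iodine attenuation; the
    same factor is applied here so measurement and ground truth agree.
    """
    missing = set(np.unique(phantom.labels)) - set(phantom.materials) - {0}
    if missing:
        raise ValueError(f"phantom labels {sorted(missing)} have no material assigned")
    paths = _material_line_integrals(phantom, geometry)
    energies = np.asarray(physics.energies_kev)
    weights = np.asarray(physics.weights)
    contrast_level = float(phantom.truth.get("contrast_level", 1.0))

    mean_counts = np.zeros((geometry.n_views, geometry.n_bins))
    for w, e in zip(weights, energies):
        t_e = np.zeros_like(mean_counts)
        for label, path in paths.items():
            mu = phantom.materials[label].mu_at([e])[0]
            from .phantoms import LABEL_CONTRAST

            if label == LABEL_CONTRAST:
                mu = mu * contrast_level
            t_e += mu * path
        mean_counts += w * np.exp(-t_e)
    mean_counts *= physics.incident_photons

    if physics.noise == "poisson":
        rng = np.random.default_rng(physics.seed)
        counts = rng.poisson(mean_counts).astype(float)
    else:
        counts = mean_counts
    return Sinogram(counts, "photon_count", geometry)


def to_line_integrals(sino: Sinogram, physics: PhysicsModel) -> Sinogram:
    """Log-transform counts to effective line integrals.

    Zero counts are clamped to one photon before the log (photon-starvation
    floor), so the maximum representable attenuation is ``log(I0)``.
    """
    if sino.kind != "photon_count":
        raise TypeError(f"expected photon_count sinogram, got {sino.kind!r}")
    counts = np.maximum(sino.values, 1.0)
    return sino.with_values(-np.log(counts / physics.incident_photons), "line_integral")
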