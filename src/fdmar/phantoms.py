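"""Seeded axial head phantoms with vessels, a treated aneurysm and metal implants.

Each phantom is a 2-D attenuation slice plus an integer label map and a table
of named regions of interest.  The scenarios emulate the implant situations
seen after endovascular or neurosurgical aneurysm therapy: a coil mass, one or
several clips, or stent-assisted coiling, with optional residual contrast
filling at the aneurysm neck ("reperfusion").  Geometry is stylized: shapes
are parametric primitives, not device models, but the attenuation contrasts
(soft tissue < iodinated blood < bone << metal) and the spatial relations
(implant abutting a contrast-filled parent vessel, neck remnant between the
two) are the ones that drive metal-artifact physics and detectability.

All stochastic geometry is driven by a single integer seed through a local
``numpy.random.Generator``; no global random state is touched.  The field of
view is fixed at 153.6 mm (512 pixels x 0.3 mm); coarser grids keep the same
field of view with proportionally larger voxels, so anatomy measured in mm
does not depend on the grid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MaterialSpec",
    "Phantom",
    "ScenarioConfig",
    "DEFAULT_SPECTRUM",
    "MATERIALS",
    "LABEL_AIR",
    "LABEL_SOFT",
    "LABEL_BONE",
    "LABEL_CONTRAST",
    "LABEL_METAL",
    "generate_phantom",
    "list_rois",
    "export_phantom",
]

LABEL_AIR = 0
LABEL_SOFT = 1
LABEL_BONE = 2
LABEL_CONTRAST = 3
LABEL_METAL = 4

#: Reference field of view in mm: 512 voxels at 0.3 mm isotropic.
FOV_MM = 153.6

IMPLANT_KINDS = ("coil", "clip", "multi_clip", "stent_coil", "none")


@dataclass(frozen=True)
class MaterialSpec:
    """A tissue/implant material with a tabulated attenuation curve.

    ``energies_kev`` and ``mu_per_mm`` tabulate the linear attenuation
    coefficient (1/mm) over a small set of energy bins; intermediate energies
    are linearly interpolated.
    """

    name: str
    energies_kev: tuple[float, ...]
    mu_per_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.energies_kev) != len(self.mu_per_mm):
            raise ValueError("energy and attenuation tables differ in length")
        if any(m <= 0 for m in self.mu_per_mm):
            raise ValueError(f"material {self.name!r}: attenuation must be positive")

    def mu_at(self, energies_kev) -> np.ndarray:
        """Linear attenuation (1/mm) at the requested energies."""
        return np.interp(np.asarray(energies_kev, float), self.energies_kev, self.mu_per_mm)


def _power_law_curve(mu_70: float, exponent: float,
                     energies=(50.0, 60.0, 70.0, 80.0, 90.0)) -> tuple[tuple, tuple]:
    mus = tuple(mu_70 * (70.0 / e) ** exponent for e in energies)
    return tuple(energies), mus


def _material(name: str, mu_70: float, exponent: float) -> MaterialSpec:
    e, m = _power_law_curve(mu_70, exponent)
    return MaterialSpec(name, e, m)


#: Four-class material table.  Values at 70 keV are stylized but ordered as in
#: reality (water ~0.019/mm); the energy exponents make iodine and metal harden
#: the beam much more strongly than soft tissue.
MATERIALS: dict[int, MaterialSpec] = {
    LABEL_SOFT: _material("soft_tissue", 0.020, 0.4),
    LABEL_BONE: _material("bone", 0.048, 1.6),
    LABEL_CONTRAST: _material("contrast_blood", 0.034, 2.5),
    LABEL_METAL: _material("metal", 0.80, 2.0),
}

#: Default polychromatic spectrum: 5 bins, weights sum to 1, peaked mid-band.
DEFAULT_SPECTRUM: tuple[tuple[float, ...], tuple[float, ...]] = (
    (50.0, 60.0, 70.0, 80.0, 90.0),
    (0.15, 0.25, 0.30, 0.20, 0.10),
)


def reference_attenuation(label: int, spectrum=DEFAULT_SPECTRUM,
                          materials: Mapping[int, MaterialSpec] = MATERIALS) -> float:
    """Spectrum-weighted mean attenuation of a label's material (1/mm).

    Using the weighted mean (rather than the value at one nominal energy) as
    the reference makes the polychromatic measured attenuation a strict lower
    bound of the reference-energy line integral, which is the beam-hardening
    direction the simulator is built to exhibit.
    """
    if label == LABEL_AIR:
        return 0.0
    energies, weights = spectrum
    mat = materials[label]
    return float(np.dot(weights, mat.mu_at(energies)) / np.sum(weights))


@dataclass(frozen=True)
class ScenarioConfig:
    """One implant scenario: which device, whether the neck still fills.

    ``contrast_level`` scales the iodine attenuation relative to its nominal
    table value (1.0 = nominal bolus).  ``grid_size`` is the square matrix
    size; 512 is the full-head default.
    """

    implant_kind: str = "coil"
    residual_filling_present: bool = False
    contrast_level: float = 1.0
    noise_seed: int = 0
    grid_size: int = 512

    def __post_init__(self) -> None:
        if self.implant_kind not in IMPLANT_KINDS:
            raise ValueError(
                f"implant_kind={self.implant_kind!r} invalid; expected one of {IMPLANT_KINDS}"
            )
        if self.grid_size < 64:
            raise ValueError(f"grid_size={self.grid_size} invalid; must be >= 64")
        if self.contrast_level < 0:
            raise ValueError(f"contrast_level={self.contrast_level} invalid; must be >= 0")


@dataclass
class Phantom:
    """Ground-truth slice: reference attenuation, labels, named ROIs.

    ``attenuation_ref`` holds the spectrum-weighted reference attenuation in
    1/mm.  ``roi_table`` maps roi names to boolean masks over the grid; the
    ``neck_site`` roi marks the candidate residual-neck location in every
    scenario, while ``residual_neck`` is present only when the neck actually
    fills with contrast.
    """

    attenuation_ref: np.ndarray
    labels: np.ndarray
    voxel_size_mm: float
    roi_table: dict[str, np.ndarray]
    truth: dict
    materials: dict[int, MaterialSpec] = field(default_factory=lambda: dict(MATERIALS))
    spectrum: tuple = DEFAULT_SPECTRUM

    @property
    def grid_size(self) -> int:
        return self.attenuation_ref.shape[0]

    def validate(self) -> None:
        if self.attenuation_ref.shape != self.labels.shape:
            raise ValueError("attenuation and label grids differ in shape")
        for name, mask in self.roi_table.items():
            if mask.shape != self.labels.shape:
                raise ValueError(f"roi {name!r} shape mismatch")
            if not mask.any():
                raise ValueError(f"roi {name!r} is empty")
        has_neck = "residual_neck" in self.roi_table
        if has_neck != bool(self.truth.get("residual_filling_present")):
            raise ValueError("residual_neck roi presence inconsistent with truth flag")


def _disk(n: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ellipse(n: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _bar(n: int, cy: float, cx: float, length: float, width: float, angle_rad: float) -> np.ndarray:
    """Rotated rectangle (clip blade)."""
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle_rad) + dy * np.sin(angle_rad)
    v = -dx * np.sin(angle_rad) + dy * np.cos(angle_rad)
    return (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)


def generate_phantom(config: ScenarioConfig) -> Phantom:
    """Deterministically generate one phantom for a scenario.

    The anatomy (head outline, skull, vessels, aneurysm site) is drawn from
    the seed alone, independently of ``implant_kind`` and of the residual
    flag, so that phantoms differing only in those fields are pixel-identical
    outside the implant and neck regions.  This paired-twin construction is
    what makes controlled artifact-index and detectability comparisons
    possible downstream.
    """
    n = config.grid_size
    voxel = FOV_MM / n  # mm per pixel; 0.3 at the default 512 grid
    rng = np.random.default_rng(config.noise_seed)

    labels = np.zeros((n, n), dtype=np.uint8)
    c = (n - 1) / 2.0

    # Head outline and skull: slightly jittered ellipse, bone ring ~4 mm.
    head_ry = n * (0.43 + 0.01 * rng.uniform(-1, 1))
    head_rx = n * (0.39 + 0.01 * rng.uniform(-1, 1))
    outer = _ellipse(n, c, c, head_ry, head_rx)
    skull_mm = 4.0 + rng.uniform(-0.5, 0.5)
    t = skull_mm / voxel
    inner = _ellipse(n, c, c, head_ry - t, head_rx - t)
    labels[outer] = LABEL_BONE
    labels[inner] = LABEL_SOFT

    # Implant site: off-center within the brain so the mirrored contralateral
    # region is disjoint from it.
    site_angle = rng.uniform(-0.5, 0.5)  # radians around the +x axis
    site_r = n * rng.uniform(0.14, 0.20)
    site_cy = c + site_r * np.sin(site_angle)
    site_cx = c + site_r * np.cos(site_angle)

    mu_contrast = reference_attenuation(LABEL_CONTRAST) * config.contrast_level

    # Parent vessel: a contrast-filled tube running past the implant site.
    vessel_w = max(2.0, 3.2 / voxel)  # ~3 mm lumen
    vessel_angle = rng.uniform(0, np.pi)
    vessel_len = n * 0.28
    vessel_cy = site_cy + (5.0 / voxel) * np.sin(vessel_angle + np.pi / 2)
    vessel_cx = site_cx + (5.0 / voxel) * np.cos(vessel_angle + np.pi / 2)
    vessel = _bar(n, vessel_cy, vessel_cx, vessel_len, vessel_w, vessel_angle) & inner

    # Two distant small vessels as incidental contrast.
    small_vessels = np.zeros((n, n), bool)
    for _ in range(2):
        a = rng.uniform(0, 2 * np.pi)
        rr = n * rng.uniform(0.22, 0.30)
        sv = _disk(n, c + rr * np.sin(a + np.pi), c + rr * np.cos(a + np.pi),
                   max(1.5, 1.2 / voxel))
        small_vessels |= sv & inner
    labels[vessel | small_vessels] = LABEL_CONTRAST

    # Aneurysm sac: ~10 mm dome at the site; the implant occupies it.
    sac_r = (5.0 + rng.uniform(-0.5, 0.5)) / voxel
    sac = _disk(n, site_cy, site_cx, sac_r) & inner

    # Residual neck: ~3 mm pocket at the sac base facing the parent vessel.
    # The remnant is by definition not packed with coil, so a ~1 mm gap is
    # carved between the device and the neck; this also keeps the detection
    # ROI clear of the worst metal blooming.
    neck_t = (3.0 + rng.uniform(-0.5, 0.5)) / voxel
    toward = np.array([vessel_cy - site_cy, vessel_cx - site_cx])
    nrm = np.hypot(*toward)
    toward = toward / nrm if nrm > 0 else np.array([0.0, 1.0])
    neck_cy = site_cy + sac_r * toward[0]
    neck_cx = site_cx + sac_r * toward[1]
    neck_r = max(1.5, neck_t)
    neck_site = _disk(n, neck_cy, neck_cx, neck_r) & inner & ~vessel
    if not neck_site.any():  # coarse grids: relax the exclusions stepwise
        neck_site = _disk(n, neck_cy, neck_cx, neck_r) & inner
    if not neck_site.any():
        neck_site = _disk(n, neck_cy, neck_cx, 1.5 * neck_r + 1) & inner

    gap_px = max(1, int(round(1.8 / voxel)))
    raw_metal = _implant_mask(config.implant_kind, n, site_cy, site_cx, sac_r, sac, rng)
    raw_metal &= inner
    metal = raw_metal & ~ndimage.binary_dilation(neck_site, iterations=gap_px)
    if config.implant_kind != "none" and not metal.any():
        metal = raw_metal & ~neck_site  # keep the device at coarse resolution

    if config.implant_kind == "none":
        # No-metal twin: the sac region stays soft tissue.
        metal = np.zeros((n, n), bool)

    labels[sac] = LABEL_SOFT
    labels[metal] = LABEL_METAL
    if config.residual_filling_present:
        labels[neck_site & ~metal] = LABEL_CONTRAST

    # Reference attenuation from the label map (contrast scaled by level).
    att = np.zeros((n, n))
    att[labels == LABEL_SOFT] = reference_attenuation(LABEL_SOFT)
    att[labels == LABEL_BONE] = reference_attenuation(LABEL_BONE)
    att[labels == LABEL_CONTRAST] = mu_contrast
    att[labels == LABEL_METAL] = reference_attenuation(LABEL_METAL)

    # ROIs -----------------------------------------------------------------
    yy, xx = np.mgrid[0:n, 0:n]
    dist_site_mm = np.hypot(yy - site_cy, xx - site_cx) * voxel
    soft = labels == LABEL_SOFT
    # Brain parenchyma within 2 cm of the implant, excluding the sac itself.
    adjacent = soft & (dist_site_mm <= 20.0) & ~sac
    # Mirror about the vertical midline for the contralateral hemisphere.
    mirror_cx = 2 * c - site_cx
    dist_mirror_mm = np.hypot(yy - site_cy, xx - mirror_cx) * voxel
    contralateral = soft & (dist_mirror_mm <= 20.0) & (dist_site_mm > 20.0)

    roi_table: dict[str, np.ndarray] = {
        "parent_vessel": vessel,
        "adjacent_parenchyma": adjacent,
        "contralateral_parenchyma": contralateral,
        "neck_site": neck_site,
    }
    if config.residual_filling_present:
        roi_table["residual_neck"] = neck_site & (labels == LABEL_CONTRAST)
    if metal.any():
        roi_table["implant"] = metal

    phantom = Phantom(
        attenuation_ref=att,
        labels=labels,
        voxel_size_mm=voxel,
        roi_table=roi_table,
        truth={
            "residual_filling_present": config.residual_filling_present,
            "implant_kind": config.implant_kind,
            "noise_seed": config.noise_seed,
            "contrast_level": config.contrast_level,
        },
    )
    phantom.validate()
    return phantom


def _implant_mask(kind: str, n: int, cy: float, cx: float, sac_r: float,
                  sac: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stylized device geometry per implant kind.

    coil: dense irregular blob filling most of the sac; clip: one thin
    high-attenuation bar; multi_clip: 2-3 disjoint bars; stent_coil: coil
    blob plus sparse thin struts on a surrounding arc.  All random draws
    happen for every kind so the anatomy stream stays aligned across kinds.
    """
    # Draw everything unconditionally to keep the rng stream kind-independent.
    blob = np.zeros((n, n), bool)
    for _ in range(8):
        a = rng.uniform(0, 2 * np.pi)
        rr = rng.uniform(0, 0.5) * sac_r
        br = rng.uniform(0.45, 0.75) * sac_r
        blob |= _disk(n, cy + rr * np.sin(a), cx + rr * np.cos(a), br)
    blob &= sac

    bar_angles = rng.uniform(0, np.pi, size=3)
    bar_offsets = rng.uniform(1.2, 2.2, size=3)
    bars = []
    for i in range(3):
        off = bar_offsets[i] * sac_r
        a = bar_angles[i]
        bcy = cy + off * np.sin(a + np.pi / 2) * (1 if i % 2 else -1)
        bcx = cx + off * np.cos(a + np.pi / 2) * (1 if i % 2 else -1)
        bars.append(_bar(n, bcy, bcx, length=1.8 * sac_r, width=max(1.5, 0.12 * sac_r),
                         angle_rad=a))

    strut_angles = rng.uniform(0, 2 * np.pi, size=8)
    struts = np.zeros((n, n), bool)
    strut_r = 1.35 * sac_r
    for a in strut_angles:
        struts |= _disk(n, cy + strut_r * np.sin(a), cx + strut_r * np.cos(a),
                        max(1.0, 0.08 * sac_r))

    if kind == "coil":
        return blob
    if kind == "clip":
        return bars[0]
    if kind == "multi_clip":
        m = bars[0] | bars[1]
        # Guarantee disjointness: erode overlap if the random bars touch.
        lab, k = ndimage.label(m, structure=np.ones((3, 3), int))
        if k < 2:
            m = bars[0] | bars[2]
        return m
    if kind == "stent_coil":
        return blob | struts
    return np.zeros((n, n), bool)  # "none"


def list_rois(phantom: Phantom) -> pd.DataFrame:
    """Summarize the roi table: pixel counts and physical centroids (mm).

    Coordinates are physical, with the origin at the grid center and x along
    columns, y along rows.
    """
    n = phantom.grid_size
    c = (n - 1) / 2.0
    rows = []
    for name, mask in sorted(phantom.roi_table.items()):
        ys, xs = np.nonzero(mask)
        rows.append({
            "roi": name,
            "pixel_count": int(len(ys)),
            "centroid_x_mm": float((xs.mean() - c) * phantom.voxel_size_mm),
            "centroid_y_mm": float((ys.mean() - c) * phantom.voxel_size_mm),
        })
    return pd.DataFrame(rows, columns=["roi", "pixel_count", "centroid_x_mm", "centroid_y_mm"])


def export_phantom(phantom: Phantom, out_dir) -> dict[str, Path]:
    """Write attenuation/labels as MetaImage plus a TSV roi summary.

    Returns a dict of written paths.  A portable text header (TSV) records
    the voxel size and truth flags alongside the binary grids.
    """
    import SimpleITK as sitk

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, arr in (("attenuation", phantom.attenuation_ref),
                     ("labels", phantom.labels.astype(np.uint8))):
        img = sitk.GetImageFromArray(np.asarray(arr))
        img.SetSpacing((phantom.voxel_size_mm, phantom.voxel_size_mm))
        p = out / f"{key}.mhd"
        sitk.WriteImage(img, str(p))
        paths[key] = p
    roi_path = out / "rois.tsv"
    list_rois(phantom).to_csv(roi_path, sep="\t", index=False)
    paths["rois"] = roi_path
    hdr = out / "phantom.tsv"
    pd.DataFrame([{"voxel_size_mm": phantom.voxel_size_mm,
                   **{k: v for k, v in phantom.truth.items()}}]).to_csv(hdr, sep="\t", index=False)
    paths["header"] = hdr
    return paths
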