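"""Volume and sinogram I/O in standard medical-imaging formats.

Volumes round-trip through NIfTI (via nibabel) or MetaImage (via SimpleITK);
voxel size and a provenance tag survive both formats.  Sinograms are stored
as flat float64 binary alongside a TSV header carrying the geometry.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .projector import AcquisitionGeometry, Sinogram
from .recon import Volume

__all__ = ["read_volume", "write_volume", "read_sinogram", "write_sinogram"]

_VOLUME_EXTS = (".mhd", ".mha", ".nii", ".nii.gz")


def _format_error(path: Path) -> ValueError:
    return ValueError(
        f"unsupported volume format {path.suffix!r} for {path.name}; "
        f"supported extensions: {', '.join(_VOLUME_EXTS)}")


def write_volume(vol: Volume, path) -> Path:
    """Write a volume; format chosen by extension (.mhd/.mha/.nii/.nii.gz)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        img = sitk.GetImageFromArray(vol.values)
        img.SetSpacing((vol.voxel_size_mm, vol.voxel_size_mm))
        img.SetMetaData("provenance", vol.provenance)
        img.SetMetaData("fov", vol.fov)
        sitk.WriteImage(img, str(path))
    elif name.endswith((".nii", ".nii.gz")):
        affine = np.diag([vol.voxel_size_mm, vol.voxel_size_mm, 1.0, 1.0])
        img = nib.Nifti1Image(vol.values, affine)
        img.header["descrip"] = f"prov={vol.provenance};fov={vol.fov}".encode()
        nib.save(img, str(path))
    else:
        raise _format_error(path)
    return path


def read_volume(path) -> Volume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img)
        voxel = float(img.GetSpacing()[0])
        provenance = img.GetMetaData("provenance") if img.HasMetaDataKey("provenance") else "uncorrected"
        fov = img.GetMetaData("fov") if img.HasMetaDataKey("fov") else f"full_{values.shape[0]}"
        return Volume(values, voxel, fov=fov, provenance=provenance)
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        voxel = float(img.header.get_zooms()[0])
        descrip = img.header["descrip"].tobytes().split(b"\0")[0].decode(errors="replace")
        meta = dict(kv.split("=", 1) for kv in descrip.split(";") if "=" in kv)
        return Volume(values, voxel, fov=meta.get("fov", f"full_{values.shape[0]}"),
                      provenance=meta.get("prov", "uncorrected"))
    raise _format_error(path)


def write_sinogram(sino: Sinogram, path, seed: int | None = None) -> Path:
    """Write sinogram values as flat float64 binary plus a TSV header.

    ``path`` names the binary file; a sibling ``<path>.tsv`` carries the
    geometry (n_views, n_bins, span_deg, bin spacing, kind, seed).
    """
    path = Path(path)
    np.asarray(sino.values, dtype="<f8").tofile(path)
    header = pd.DataFrame([{
        "n_views": sino.geometry.n_views,
        "n_bins": sino.geometry.n_bins,
        "span_deg": sino.geometry.span_deg,
        "start_deg": sino.geometry.angles_deg[0],
        "bin_spacing_mm": sino.geometry.bin_spacing_mm,
        "kind": sino.kind,
        "seed": "" if seed is None else seed,
    }])
    header.to_csv(path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False)
    return path


def read_sinogram(path) -> Sinogram:
    """Read a sinogram written by :func:`write_sinogram`."""
    path = Path(path)
    hdr = pd.read_csv(path.with_suffix(path.suffix + ".tsv"), sep="\t").iloc[0]
    angles = np.linspace(float(hdr.get("start_deg", 0.0)),
                         float(hdr.get("start_deg", 0.0)) + float(hdr["span_deg"]),
                         int(hdr["n_views"]))
    geometry = AcquisitionGeometry(tuple(angles), int(hdr["n_bins"]),
                                   float(hdr["bin_spacing_mm"]))
    values = np.fromfile(path, dtype="<f8").reshape(int(hdr["n_views"]), int(hdr["n_bins"]))
    return Sinogram(values, str(hdr["kind"]), geometry)
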