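"""Data preparation: NEX averaging, normalization, patching, augmentation, NIfTI I/O.

Training-time normalization follows the acquisition convention: the noisy and
reference high-b volumes are divided by the global maximum of the *reference*
(so the reference peaks at 1 and the noisy volume may exceed 1 — no clipping),
and the guide is divided by its own global maximum.  At inference the
reference does not exist, so each volume is normalized by its own maximum and
the scales are returned for unit restoration.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile

import nibabel as nib
import numpy as np

from .containers import DWISeries, PatchTriple, RepetitionStack

__all__ = [
    "average_nex",
    "normalize_series",
    "normalize_for_inference",
    "denormalize",
    "extract_patches",
    "patch_grid",
    "augment",
    "dihedral",
    "read_nifti",
    "write_nifti",
    "write_series",
    "read_series",
]


def average_nex(stack: RepetitionStack, n: int) -> np.ndarray:
    """Arithmetic mean of the first ``n`` excitations of a repetition stack."""
    if not 1 <= n <= stack.nex:
        raise ValueError(f"n={n} out of range for a stack of {stack.nex} repetitions")
    return stack.repetitions[:n].mean(axis=0)


def normalize_series(series: DWISeries) -> DWISeries:
    """Scale a series to training units.

    Noisy and reference are divided by the reference's global max (over all
    slices); the guide by its own global max.  Idempotent: a second
    application finds maxima of 1 and changes nothing.
    """
    ref_max = float(np.max(series.reference))
    guide_max = float(np.max(series.guide))
    if ref_max <= 0:
        raise ValueError("reference volume is all-zero; cannot normalize")
    if guide_max <= 0:
        raise ValueError("guide volume is all-zero; cannot normalize")
    return DWISeries(
        guide=series.guide / guide_max,
        noisy={n: v / ref_max for n, v in series.noisy.items()},
        reference=series.reference / ref_max,
        subject_id=series.subject_id,
        norm_scale_highb=series.norm_scale_highb * ref_max,
        norm_scale_guide=series.norm_scale_guide * guide_max,
        b_low=series.b_low,
        b_high=series.b_high,
    )


def normalize_for_inference(noisy: np.ndarray, guide: np.ndarray):
    """Normalize a (noisy, guide) pair by their own maxima.

    Returns ``(noisy_n, guide_n, scale_noisy, scale_guide)``; multiplying the
    denoised output by ``scale_noisy`` restores input units.
    """
    sn = float(np.max(noisy))
    sg = float(np.max(guide))
    if sn <= 0 or sg <= 0:
        raise ValueError("all-zero volume cannot be normalized")
    return noisy / sn, guide / sg, sn, sg


def denormalize(volume: np.ndarray, scale: float) -> np.ndarray:
    return volume * scale


# -- patches ---------------------------------------------------------------


def patch_grid(length: int, size: int, stride: int) -> list[int]:
    """1-D patch start offsets; the last patch is clamped to the edge."""
    if size > length:
        raise ValueError(f"patch size {size} exceeds image extent {length}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = list(range(0, length - size + 1, stride))
    if starts[-1] != length - size:
        starts.append(length - size)
    return starts


def extract_patches(
    series: DWISeries, nex: int, size: int = 60, stride: int = 20
) -> list[PatchTriple]:
    """Cut co-located (guide, noisy, reference) patch triples on a regular grid.

    The grid is clamped at the right/bottom edge so the whole slice is covered
    for any stride <= size.
    """
    if nex not in series.noisy:
        raise ValueError(f"series has no noisy volume at NEX={nex}")
    noisy = series.noisy[nex]
    _, h, w = noisy.shape
    rows = patch_grid(h, size, stride)
    cols = patch_grid(w, size, stride)
    out = []
    for z in range(series.n_slices):
        for r in rows:
            for c in cols:
                out.append(
                    PatchTriple(
                        guide_patch=series.guide[z, r : r + size, c : c + size],
                        noisy_patch=noisy[z, r : r + size, c : c + size],
                        reference_patch=series.reference[z, r : r + size, c : c + size],
                        origin=(z, r, c),
                        nex=nex,
                    )
                )
    return out


# -- dihedral augmentation -------------------------------------------------


def dihedral(img: np.ndarray, op_id: int) -> np.ndarray:
    """Apply the op_id-th symmetry of the square to the last two axes.

    op_id 0..3 are counter-clockwise rotations by 90*op_id degrees; 4..7 are
    the same rotations after a horizontal (left-right) flip.
    """
    if not 0 <= op_id <= 7:
        raise ValueError(f"op_id must be in [0, 7], got {op_id}")
    if op_id >= 4:
        img = img[..., :, ::-1]
    return np.rot90(img, k=op_id % 4, axes=(-2, -1))


def augment(triple: PatchTriple, op_id: int) -> PatchTriple:
    """Apply one dihedral operation identically to all three patches."""
    return PatchTriple(
        guide_patch=dihedral(triple.guide_patch, op_id),
        noisy_patch=dihedral(triple.noisy_patch, op_id),
        reference_patch=dihedral(triple.reference_patch, op_id),
        origin=triple.origin,
        augmentation_id=op_id,
        nex=triple.nex,
    )


# -- NIfTI I/O -------------------------------------------------------------

# slice axis is the 3rd array axis on disk (H, W, S); in memory we use (S, H, W)


def write_nifti(path, volume: np.ndarray, voxel_size=(1.0, 1.0, 6.0)) -> None:
    """Write an (S, H, W) volume as a float32 NIfTI-1 file, atomically."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D (slices, H, W) volume, got shape {volume.shape}")
    data = np.transpose(volume.astype(np.float32), (1, 2, 0))
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(voxel_size)
    path = os.fspath(path)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".nii")
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_nifti(path):
    """Read a 3-D NIfTI file back to an (S, H, W) float32 array + voxel size."""
    try:
        img = nib.load(os.fspath(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return np.transpose(data.astype(np.float32), (2, 0, 1)), tuple(float(z) for z in img.header.get_zooms())


def write_series(series: DWISeries, outdir, voxel_size=(1.0, 1.0, 6.0)) -> dict:
    """Write one subject's series as NIfTI volumes + a JSON manifest."""
    os.makedirs(outdir, exist_ok=True)
    sid = series.subject_id
    files = {"guide": f"{sid}_b{int(series.b_low)}_guide.nii"}
    write_nifti(os.path.join(outdir, files["guide"]), series.guide, voxel_size)
    for n, vol in series.noisy.items():
        key = f"noisy_nex{n}"
        files[key] = f"{sid}_b{int(series.b_high)}_nex{n}.nii"
        write_nifti(os.path.join(outdir, files[key]), vol, voxel_size)
    files["reference"] = f"{sid}_b{int(series.b_high)}_reference.nii"
    write_nifti(os.path.join(outdir, files["reference"]), series.reference, voxel_size)
    manifest = {
        "subject_id": sid,
        "files": files,
        "b_low": series.b_low,
        "b_high": series.b_high,
        "norm_scale_highb": series.norm_scale_highb,
        "norm_scale_guide": series.norm_scale_guide,
        "nex_levels": list(series.nex_levels),
    }
    mpath = os.path.join(outdir, f"{sid}_manifest.json")
    fd, tmp = tempfile.mkstemp(dir=outdir, suffix=".json")
    with os.fdopen(fd, "w") as fh:
        json.dump(manifest, fh, indent=1)
    os.replace(tmp, mpath)
    return manifest


def read_series(outdir, subject_id: str) -> DWISeries:
    """Load a subject series previously written by :func:`write_series`."""
    mpath = os.path.join(outdir, f"{subject_id}_manifest.json")
    with open(mpath) as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    guide, _ = read_nifti(os.path.join(outdir, files["guide"]))
    reference, _ = read_nifti(os.path.join(outdir, files["reference"]))
    noisy = {}
    for n in manifest["nex_levels"]:
        vol, _ = read_nifti(os.path.join(outdir, files[f"noisy_nex{n}"]))
        noisy[int(n)] = vol
    return DWISeries(
        guide=guide,
        noisy=noisy,
        reference=reference,
        subject_id=manifest["subject_id"],
        norm_scale_highb=manifest["norm_scale_highb"],
        norm_scale_guide=manifest["norm_scale_guide"],
        b_low=manifest["b_low"],
        b_high=manifest["b_high"],
    )
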