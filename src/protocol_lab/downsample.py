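"""Spatial downsampling by k-space cropping.

Acquiring an MRI volume at half the resolution is, to first order,
acquiring only the central half of k-space along each axis.  The
simulation therefore transforms each 3D volume to centered k-space,
retains the central (dim/factor)^3 block, and inverse-transforms,
taking the magnitude (acquisition data are magnitude images).  The
cropped spectrum is scaled by 1/factor^3 so that the image mean (the DC
amplitude) is preserved: a constant image keeps its value.

Conventions: the DC bin sits at index floor(dim/2); for even
dimensions the crop window is the asymmetric [c - n'/2, c + n'/2)
block, i.e. the Nyquist plane is dropped.  Coarse voxel i' corresponds
to fine grid position i' * factor.
"""

from __future__ import annotations

import numpy as np

from .phantom import DWIVolume

__all__ = ["kspace_crop", "crop_kspace_array", "downsample_labels"]


def _crop_slices(dims: tuple[int, ...], factor: int) -> tuple[slice, ...]:
    slices = []
    for ax, n in enumerate(dims):
        if n % factor:
            raise ValueError(
                f"axis {ax} has size {n}, not divisible by factor {factor}"
            )
        c, n2 = n // 2, n // factor
        start = c - n2 // 2
        slices.append(slice(start, start + n2))
    return tuple(slices)


def crop_kspace_array(kspace: np.ndarray, factor: int) -> np.ndarray:
    """Retain the central block of a centered k-space array (4D: x, y, z, vol)."""
    sl = _crop_slices(kspace.shape[:3], factor)
    return kspace[sl[0], sl[1], sl[2], ...] / factor**3


def kspace_crop(dwi: DWIVolume, factor: int) -> DWIVolume:
    """Simulate acquisition at `factor` times larger voxels by k-space cropping."""
    if factor not in (1, 2, 4):
        raise ValueError(f"factor must be 1, 2 or 4, got {factor}")
    if factor == 1:
        return DWIVolume(
            data=dwi.data.copy(), scheme=dwi.scheme,
            voxel_size=dwi.voxel_size, snr=dwi.snr,
        )
    if not np.all(np.isfinite(dwi.data)):
        raise ValueError("non-finite voxel values cannot be transformed")
    sl = _crop_slices(dwi.data.shape[:3], factor)
    dims = tuple(n // factor for n in dwi.data.shape[:3])
    out = np.empty(dims + (dwi.data.shape[3],), dtype=dwi.data.dtype)
    for m in range(dwi.data.shape[3]):  # one volume at a time: bounded memory
        k = np.fft.fftshift(np.fft.fftn(dwi.data[..., m].astype(np.complex128)))
        k = k[sl] / factor**3
        out[..., m] = np.abs(np.fft.ifftn(np.fft.ifftshift(k)))
    return DWIVolume(
        data=out, scheme=dwi.scheme, voxel_size=dwi.voxel_size * factor, snr=dwi.snr
    )


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Label map at the coarse grid: rarest label present in each block wins.

    Majority voting would erase 1-voxel structures (the thin bundle);
    assigning each coarse voxel the globally rarest label present in its
    block keeps thin regions addressable at low resolution, which is how
    the per-region bookkeeping follows structures through downsampling.
    """
    labels = np.asarray(labels)
    if factor == 1:
        return labels.copy()
    for ax, n in enumerate(labels.shape):
        if n % factor:
            raise ValueError(f"axis {ax} has size {n}, not divisible by {factor}")
    dims = tuple(n // factor for n in labels.shape)
    blocks = labels.reshape(
        dims[0], factor, dims[1], factor, dims[2], factor
    ).transpose(0, 2, 4, 1, 3, 5).reshape(dims + (factor**3,))
    ids, counts = np.unique(labels, return_counts=True)
    # background is never "rare": give it the largest rank
    rank = {int(i): (np.inf if i == 0 else int(c)) for i, c in zip(ids, counts)}
    out = np.zeros(dims, dtype=labels.dtype)
    flat = blocks.reshape(-1, factor**3)
    res = np.zeros(flat.shape[0], dtype=labels.dtype)
    for pos in range(flat.shape[0]):
        present = np.unique(flat[pos])
        res[pos] = min(present, key=lambda i: (rank[int(i)], int(i)))
    return res.reshape(dims)
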