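"""Synthetic multi-fiber brain phantom and single-shell signal simulation.

The phantom stands in for an ex-vivo mouse brain imaged at very high
field: a brain-shaped ellipsoid of isotropic tissue containing a small
circuit of named regions chosen to echo the hippocampal system —

* a thick, straight white-matter bundle ("fi", fimbria-like) joining a
  septum-like blob to a hippocampus-like blob in each hemisphere,
* a thin, curved 1-2-voxel bundle ("fx", fornix-like, ~0.05% of the
  brain volume) arcing from the hippocampus to a hypothalamus-like blob,
* a commissural bundle ("cc") crossing the thick bundle at 90 degrees,
  with the intersection labelled as a two-fiber crossing zone,
* a curved association bundle ("ac") from a cortex-like blob to the
  hippocampus, whose orientation turns substantially along its arc,
* gray-matter blobs (hippocampus, septum, hypothalamus, thalamus,
  cortex) with a single weak fiber population whose orientation is
  drawn independently per voxel — gray matter is orientationally
  incoherent, so coarse voxels mix orientations, as in real cortex.

Curved thin bundles and incoherent gray matter matter: they are what
makes spatial downsampling mix fiber orientations inside a voxel
(partial volume), which is the mechanism by which resolution loss
degrades orientation estimates and connectomes.

Every labelled voxel carries ground-truth stick orientations and volume
fractions.  The diffusion-weighted signal follows the ball-and-stick
model at a single shell (default b = 4,000 s/mm^2)

    S(g) = S0 [ (1 - sum_i f_i) e^{-b d} + sum_i f_i e^{-b d (g.v_i)^2} ]

with optional Rician noise (magnitude of two Gaussian channels,
sigma = S0/SNR).  A centered Fourier representation of each 3D volume
is exposed so that lower spatial resolutions can be simulated by
cropping k-space.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .gradients import GradientScheme, interleave_b0s

__all__ = [
    "RegionInfo",
    "PhantomSpec",
    "PhantomVolume",
    "DWIVolume",
    "build_phantom",
    "simulate_signal",
    "to_kspace",
    "from_kspace",
    "save_nifti",
    "load_nifti",
]


@dataclasses.dataclass(frozen=True)
class RegionInfo:
    id: int
    name: str
    hemisphere: str  # "L" or "R"
    kind: str  # "wm" or "gm"


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the phantom, in fractions of the grid dimensions."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 43.0  # micrometres
    brain_semiaxes: tuple[float, float, float] = (0.46, 0.48, 0.44)
    fi_x: float = 0.32
    fi_z: float = 0.50
    fi_y_range: tuple[float, float] = (0.26, 0.68)
    fi_halfwidth_vox: float = 2.5
    cc_y: float = 0.47
    cc_z: float = 0.50
    cc_x_range: tuple[float, float] = (0.13, 0.87)
    cc_halfwidth_vox: float = 2.5
    hc_center: tuple[float, float, float] = (0.32, 0.74, 0.50)
    hc_radius: float = 0.110
    spt_center: tuple[float, float, float] = (0.32, 0.22, 0.50)
    spt_radius: float = 0.070
    hyp_center: tuple[float, float, float] = (0.42, 0.50, 0.28)
    hyp_radius: float = 0.070
    th_center: tuple[float, float, float] = (0.16, 0.50, 0.50)
    th_radius: float = 0.070
    ctx_center: tuple[float, float, float] = (0.24, 0.40, 0.78)
    ctx_radius: float = 0.070
    # quadratic Bezier control points (start, control, end) of the curved bundles
    fx_arc: tuple = ((0.32, 0.72, 0.48), (0.36, 0.64, 0.28), (0.42, 0.52, 0.28))
    fx_radius_vox: float = 0.3
    ac_arc: tuple = ((0.24, 0.42, 0.76), (0.22, 0.64, 0.76), (0.30, 0.72, 0.54))
    ac_radius_vox: float = 1.0
    f_bundle: float = 0.70
    f_crossing: float = 0.35
    f_thin: float = 0.65
    f_gray: float = 0.25
    single_bundle_only: bool = False  # debugging geometry: just the thick bundle


@dataclasses.dataclass
class PhantomVolume:
    """Voxel grid with region labels and ground-truth fiber populations."""

    shape: tuple[int, int, int]
    voxel_size: float
    labels: np.ndarray  # (X, Y, Z) int16, 0 = background/unlabelled tissue
    sticks: np.ndarray  # (X, Y, Z, 3, 3) float32 unit vectors (zero rows = absent)
    fractions: np.ndarray  # (X, Y, Z, 3) float32, 0 = absent
    brain_mask: np.ndarray  # (X, Y, Z) bool
    regions: dict[int, RegionInfo]
    spec: PhantomSpec
    seed: int

    def __post_init__(self) -> None:
        f = self.fractions
        present = f > 0
        norms = np.linalg.norm(self.sticks, axis=-1)
        if not np.allclose(norms[present], 1.0, atol=1e-5):
            raise ValueError("all present sticks must be unit vectors")
        if np.any(f.sum(axis=-1) > 1.0 + 1e-6):
            raise ValueError("per-voxel volume fractions must sum to <= 1")

    @property
    def n_sticks(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=-1)

    def region_id(self, name: str) -> int:
        for rid, info in self.regions.items():
            if info.name == name:
                return rid
        raise KeyError(name)

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.region_id(name)

    def volume_fraction(self, name_prefix: str) -> float:
        """Fraction of in-brain voxels carrying labels starting with the prefix."""
        ids = [rid for rid, r in self.regions.items() if r.name.split("_", 1)[-1].startswith(name_prefix)]
        count = int(np.isin(self.labels, ids).sum())
        return count / int(self.brain_mask.sum())


@dataclasses.dataclass
class DWIVolume:
    """4D diffusion-weighted data with its acquisition scheme."""

    data: np.ndarray  # (X, Y, Z, M), magnitude signal >= 0
    scheme: GradientScheme  # M volumes, b0s flagged by bvalue 0
    voxel_size: float  # micrometres
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.data.shape[-1] != self.scheme.n:
            raise ValueError(
                f"data has {self.data.shape[-1]} volumes but scheme has {self.scheme.n}"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _sphere(grid: tuple[np.ndarray, ...], center, radius, dims) -> np.ndarray:
    cx, cy, cz = (c * d for c, d in zip(center, dims))
    r = radius * min(dims)
    return (grid[0] - cx) ** 2 + (grid[1] - cy) ** 2 + (grid[2] - cz) ** 2 <= r**2


def _mirror_x(mask: np.ndarray) -> np.ndarray:
    return mask[::-1, :, :]


def _bezier(p0, c, p1, n: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic Bezier samples and unit tangents."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, c, p1 = (np.asarray(x, float) for x in (p0, c, p1))
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * c + t**2 * p1
    tan = 2 * (1 - t) * (c - p0) + 2 * t * (p1 - c)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def _tube_voxels(pts: np.ndarray, tangents: np.ndarray, radius: float, dims):
    """Voxels within `radius` of a polyline, with the nearest-point tangent.

    Returns (voxel index array (V, 3), tangent array (V, 3)).
    """
    best: dict[tuple[int, int, int], tuple[float, int]] = {}
    r = int(np.ceil(radius))
    offs = np.array(
        [(i, j, k) for i in range(-r, r + 1) for j in range(-r, r + 1)
         for k in range(-r, r + 1)]
    )
    for s, p in enumerate(pts):
        base = np.rint(p).astype(int)
        for off in offs:
            v = base + off
            if np.any(v < 0) or np.any(v >= dims):
                continue
            dist = float(np.linalg.norm(v - p))
            if dist > radius + 0.5:
                continue
            key = (int(v[0]), int(v[1]), int(v[2]))
            if key not in best or dist < best[key][0]:
                best[key] = (dist, s)
    if not best:
        return np.empty((0, 3), int), np.empty((0, 3))
    vox = np.array(list(best.keys()))
    tang = tangents[[best[tuple(v)][1] for v in vox]]
    return vox, tang


def build_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> PhantomVolume:
    """Construct the labelled phantom with ground-truth sticks.

    Deterministic for a fixed seed (the seed only sets gray-matter
    fiber orientations).  Overlapping shapes are painted in increasing
    priority so that the rarest structures win: gray blobs < commissure
    < thick bundle < crossing zone < thin bundle.
    """
    spec = spec or PhantomSpec()
    dims = spec.shape
    if any(d % 4 for d in dims):
        warnings.warn(
            f"phantom shape {dims} is not divisible by 4; k-space cropping "
            "by factor 4 will fail", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    X, Y, Z = np.indices(dims)
    grid = (X, Y, Z)

    brain = (
        ((X - 0.5 * dims[0]) / (spec.brain_semiaxes[0] * dims[0])) ** 2
        + ((Y - 0.5 * dims[1]) / (spec.brain_semiaxes[1] * dims[1])) ** 2
        + ((Z - 0.5 * dims[2]) / (spec.brain_semiaxes[2] * dims[2])) ** 2
    ) <= 1.0

    labels = np.zeros(dims, dtype=np.int16)
    sticks = np.zeros(dims + (3, 3), dtype=np.float32)
    fractions = np.zeros(dims + (3,), dtype=np.float32)

    regions: dict[int, RegionInfo] = {}
    next_id = [1]

    def register(base: str, kind: str) -> tuple[int, int]:
        lid, rid = next_id[0], next_id[0] + 1
        next_id[0] += 2
        regions[lid] = RegionInfo(lid, f"L_{base}", "L", kind)
        regions[rid] = RegionInfo(rid, f"R_{base}", "R", kind)
        return lid, rid

    def paint(mask: np.ndarray, rid: int, vlist, flist) -> None:
        mask = mask & brain
        labels[mask] = rid
        fractions[mask] = 0.0
        sticks[mask] = 0.0
        for i, (v, f) in enumerate(zip(vlist, flist)):
            sticks[mask, i, :] = np.asarray(v, dtype=np.float32)
            fractions[mask, i] = f

    def paint_lr(mask_l: np.ndarray, ids: tuple[int, int], vlist, flist, mirror_v=None) -> None:
        paint(mask_l, ids[0], vlist, flist)
        vm = mirror_v if mirror_v is not None else [np.array(v) * np.array([-1.0, 1.0, 1.0]) for v in vlist]
        paint(_mirror_x(mask_l), ids[1], vm, flist)

    def paint_gray(mask: np.ndarray, rid: int) -> None:
        """Gray matter: one weak stick per voxel, orientation random per voxel."""
        mask = mask & brain
        labels[mask] = rid
        fractions[mask] = 0.0
        sticks[mask] = 0.0
        nvox = int(mask.sum())
        v = rng.standard_normal((nvox, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sticks[mask, 0, :] = v.astype(np.float32)
        fractions[mask, 0] = spec.f_gray

    def paint_tube(arc, radius: float, ids: tuple[int, int], f: float) -> None:
        pts, tan = _bezier(*(np.asarray(p) * np.asarray(dims, float) for p in arc))
        vox, tang = _tube_voxels(pts, tan, radius, np.asarray(dims))
        for rid, flip in ((ids[0], False), (ids[1], True)):
            vx = vox.copy()
            tg = tang.copy()
            if flip:
                vx[:, 0] = dims[0] - 1 - vx[:, 0]
                tg = tg * np.array([-1.0, 1.0, 1.0])
            inb = brain[vx[:, 0], vx[:, 1], vx[:, 2]]
            vx, tg = vx[inb], tg[inb]
            labels[vx[:, 0], vx[:, 1], vx[:, 2]] = rid
            fractions[vx[:, 0], vx[:, 1], vx[:, 2]] = 0.0
            sticks[vx[:, 0], vx[:, 1], vx[:, 2]] = 0.0
            sticks[vx[:, 0], vx[:, 1], vx[:, 2], 0, :] = tg.astype(np.float32)
            fractions[vx[:, 0], vx[:, 1], vx[:, 2], 0] = f

    ex, ey = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])

    # --- gray-matter blobs (lowest priority) ---
    blobs = [
        ("Hc", spec.hc_center, spec.hc_radius),
        ("Spt", spec.spt_center, spec.spt_radius),
        ("Hyp", spec.hyp_center, spec.hyp_radius),
        ("Th", spec.th_center, spec.th_radius),
        ("Ctx", spec.ctx_center, spec.ctx_radius),
    ]
    if not spec.single_bundle_only:
        for base, center, radius in blobs:
            ids = register(base, "gm")
            m = _sphere(grid, center, radius, dims)
            paint_gray(m, ids[0])
            paint_gray(_mirror_x(m), ids[1])

    # --- commissural bundle along x ---
    if not spec.single_bundle_only:
        cc_ids = register("cc", "wm")
        w = spec.cc_halfwidth_vox
        cc_full = (
            (np.abs(Y - spec.cc_y * dims[1]) <= w)
            & (np.abs(Z - spec.cc_z * dims[2]) <= w)
            & (X >= spec.cc_x_range[0] * dims[0])
            & (X <= spec.cc_x_range[1] * dims[0])
        )
        left = X < dims[0] / 2
        paint(cc_full & left, cc_ids[0], [ex], [spec.f_bundle])
        paint(cc_full & ~left, cc_ids[1], [ex], [spec.f_bundle])

    # --- thick bundle (fimbria-like) along y ---
    fi_ids = register("fi", "wm")
    w = spec.fi_halfwidth_vox
    fi_l = (
        (np.abs(X - spec.fi_x * dims[0]) <= w)
        & (np.abs(Z - spec.fi_z * dims[2]) <= w)
        & (Y >= spec.fi_y_range[0] * dims[1])
        & (Y <= spec.fi_y_range[1] * dims[1])
    )
    paint_lr(fi_l, fi_ids, [ey], [spec.f_bundle], mirror_v=[ey])

    if not spec.single_bundle_only:
        # --- curved association bundle cortex -> hippocampus ---
        ac_ids = register("ac", "wm")
        paint_tube(spec.ac_arc, spec.ac_radius_vox, ac_ids, spec.f_bundle)

        # --- crossing zone: intersection of the two bundles ---
        cross_ids = register("cross", "wm")
        cross_l = fi_l & cc_full & left
        paint(cross_l, cross_ids[0], [ey, ex], [spec.f_crossing, spec.f_crossing])
        paint(_mirror_x(cross_l), cross_ids[1], [ey, ex], [spec.f_crossing, spec.f_crossing])

        # --- thin curved bundle (fornix-like), 1-2 voxels wide ---
        fx_ids = register("fx", "wm")
        paint_tube(spec.fx_arc, spec.fx_radius_vox, fx_ids, spec.f_thin)

    return PhantomVolume(
        shape=dims,
        voxel_size=spec.voxel_size,
        labels=labels,
        sticks=sticks,
        fractions=fractions,
        brain_mask=brain,
        regions=regions,
        spec=spec,
        seed=seed,
    )


def ball_and_stick_signal(
    bvals: np.ndarray,
    gdirs: np.ndarray,
    sticks: np.ndarray,
    fractions: np.ndarray,
    S0: float,
    d: float,
) -> np.ndarray:
    """Noiseless ball-and-stick signal for (V, ...) voxel arrays, (M,) volumes."""
    f = np.asarray(fractions, dtype=np.float64)
    v = np.asarray(sticks, dtype=np.float64)
    fball = 1.0 - f.sum(axis=-1)
    att_ball = np.exp(-bvals * d)  # (M,)
    dots = np.einsum("vkd,md->vkm", v, gdirs)
    att_stick = np.exp(-bvals[None, None, :] * d * dots**2)
    S = fball[:, None] * att_ball[None, :] + np.einsum("vk,vkm->vm", f, att_stick)
    return S0 * S


def simulate_signal(
    phantom: PhantomVolume,
    scheme: GradientScheme,
    b: float = 4000.0,
    S0: float = 1.0,
    d: float = 1.0e-3,
    snr: float | None = 30.0,
    seed: int = 0,
    b0_every: int = 12,
) -> DWIVolume:
    """Simulate the single-shell acquisition of the phantom.

    One b0 volume is interleaved before every `b0_every` weighted
    volumes.  Unlabelled brain tissue is a pure ball; outside the brain
    the signal is zero (noise floor only).  Noise is Rician: the
    magnitude of (S + e1, e2) with e ~ N(0, S0/snr) per channel.
    """
    if b < 0 or d <= 0 or S0 <= 0:
        raise ValueError("require b >= 0, d > 0, S0 > 0")
    if np.any(phantom.fractions.sum(axis=-1) > 1.0 + 1e-6):
        raise ValueError("invalid phantom: volume fractions sum to > 1")
    acq = interleave_b0s(scheme, every=b0_every)
    bvals = np.where(acq.bvalues > 0, b, 0.0)
    gdirs = acq.directions
    dims = phantom.shape
    M = acq.n

    data = np.zeros(dims + (M,), dtype=np.float32)
    idx = np.nonzero(phantom.brain_mask)
    S = ball_and_stick_signal(
        bvals, gdirs, phantom.sticks[idx], phantom.fractions[idx], S0, d
    )
    data[idx] = S.astype(np.float32)

    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = S0 / snr
        e1 = rng.normal(0.0, sigma, size=data.shape).astype(np.float32)
        e2 = rng.normal(0.0, sigma, size=data.shape).astype(np.float32)
        data = np.sqrt((data + e1) ** 2 + e2**2)

    return DWIVolume(data=data, scheme=acq, voxel_size=phantom.voxel_size, snr=snr)


def to_kspace(dwi: DWIVolume) -> np.ndarray:
    """Centered 3D DFT of every volume; DC lands at index floor(dim/2)."""
    if not np.all(np.isfinite(dwi.data)):
        raise ValueError("non-finite voxel values cannot be transformed")
    x = dwi.data.astype(np.complex128)
    k = np.fft.fftn(x, axes=(0, 1, 2))
    return np.fft.fftshift(k, axes=(0, 1, 2))


def from_kspace(kspace: np.ndarray, scheme: GradientScheme, voxel_size: float,
                snr: float | None = None) -> DWIVolume:
    """Inverse of `to_kspace`, returning magnitude data."""
    k = np.fft.ifftshift(np.asarray(kspace), axes=(0, 1, 2))
    x = np.fft.ifftn(k, axes=(0, 1, 2))
    return DWIVolume(
        data=np.abs(x), scheme=scheme, voxel_size=voxel_size, snr=snr
    )


def save_nifti(data: np.ndarray, voxel_size_um: float, path) -> None:
    """Write a volume as NIfTI-1 with isotropic voxel size (stored in mm)."""
    import nibabel as nib

    mm = voxel_size_um / 1000.0
    affine = np.diag([mm, mm, mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (data, voxel size in micrometres)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0]) * 1000.0
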