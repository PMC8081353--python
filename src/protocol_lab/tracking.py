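"""Probabilistic streamline tractography on fitted dyad fields.

Streamlines start at uniform random positions inside seed-region
voxels and are propagated bidirectionally in steps of a fixed fraction
of a voxel.  At every step the local voxel's dyad set is consulted: a
dyad is drawn with probability proportional to its volume fraction,
sign-aligned with the current heading, and perturbed by a tangent
Gaussian kick whose angular scale is asin-linked to the voxel's
bootstrap dispersion (dispersion delta ~ sigma^2 for a small-angle
spherical Gaussian, so sigma = asin(sqrt(delta))).  Propagation stops
on mask exit, a curvature violation, or a step cap.

All streamlines advance together in vectorized batches; voxel lookup
is nearest-voxel (voxel centers at integer coordinates, no
interpolation of orientations).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .fibers import FiberFit

__all__ = ["TrackingParams", "Streamline", "StreamlineSet", "DensityMap", "track", "density_map"]


@dataclasses.dataclass(frozen=True)
class TrackingParams:
    step: float = 0.5  # voxels
    curvature_deg: float = 80.0  # max turn between consecutive steps
    samples_per_voxel: int = 100
    max_steps: int = 2000  # per direction
    kick_floor: float = 0.02  # minimum angular scale (radians)


@dataclasses.dataclass(frozen=True)
class Streamline:
    points: np.ndarray  # (L, 3) voxel coordinates
    seed_region: int

    def __post_init__(self) -> None:
        if self.points.shape[0] < 2:
            raise ValueError("a streamline needs at least 2 points")


class StreamlineSet:
    """Compact container: concatenated points + offsets + seed regions."""

    def __init__(self, points: np.ndarray, offsets: np.ndarray, seed_regions: np.ndarray,
                 grid_shape: tuple[int, int, int], n_skipped: int = 0):
        self.points = points  # (sum L_i, 3) float32
        self.offsets = offsets  # (n+1,) int
        self.seed_regions = seed_regions  # (n,) int
        self.grid_shape = grid_shape
        self.n_skipped = n_skipped

    def __len__(self) -> int:
        return len(self.seed_regions)

    def __getitem__(self, i: int) -> Streamline:
        pts = self.points[self.offsets[i] : self.offsets[i + 1]]
        return Streamline(points=pts, seed_region=int(self.seed_regions[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) first and last point of each streamline."""
        first = self.points[self.offsets[:-1]]
        last = self.points[self.offsets[1:] - 1]
        return np.stack([first, last], axis=1)


@dataclasses.dataclass
class DensityMap:
    counts: np.ndarray  # 3D int array: streamlines visiting each voxel
    total_streamlines: int


def _dyad_field(fit: FiberFit):
    shape = fit.shape
    nsup = np.zeros(shape, dtype=np.int16)
    nsup[fit.mask_idx] = fit.n_supported
    dyads = np.zeros(shape + (4, 3), dtype=np.float32)
    dyads[fit.mask_idx] = fit.dyads
    fracs = np.zeros(shape + (4,), dtype=np.float32)
    fracs[fit.mask_idx] = np.where(
        fit.fractions >= fit.support_threshold, fit.fractions, 0.0
    )
    disp = np.zeros(shape + (4,), dtype=np.float32)
    disp[fit.mask_idx] = np.nan_to_num(fit.dispersion, nan=0.0)
    return nsup, dyads, fracs, disp


def _propagate(start_pos, start_dir, nsup, dyads, fracs, disp, params, rng):
    """Advance all samples until termination; returns (paths, lengths).

    paths: (M, max_steps + 1, 3) float32, NaN beyond each length.
    """
    shape = nsup.shape
    M = start_pos.shape[0]
    cos_thresh = np.cos(np.deg2rad(params.curvature_deg))
    paths = np.full((M, params.max_steps + 1, 3), np.nan, dtype=np.float32)
    paths[:, 0] = start_pos
    lengths = np.ones(M, dtype=np.int32)
    pos = start_pos.astype(np.float64).copy()
    heading = start_dir.astype(np.float64).copy()
    dims = np.array(shape)
    active = np.arange(M)  # invariant: active samples sit in an in-mask voxel
    for step_i in range(params.max_steps):
        if active.size == 0:
            break
        vox = np.rint(pos[active]).astype(int)
        f = fracs[vox[:, 0], vox[:, 1], vox[:, 2]]  # (n, 4)
        v = dyads[vox[:, 0], vox[:, 1], vox[:, 2]]  # (n, 4, 3)
        dsp = disp[vox[:, 0], vox[:, 1], vox[:, 2]]  # (n, 4)
        # draw a dyad with probability proportional to its supported fraction
        cum = np.cumsum(f, axis=1)
        u = rng.random(active.size) * cum[:, -1]
        choice = (u[:, None] >= cum).sum(axis=1)
        n = active.size
        vi = v[np.arange(n), choice].astype(np.float64)
        di = dsp[np.arange(n), choice].astype(np.float64)
        # sign-align with the current heading
        sgn = np.sign(np.sum(vi * heading[active], axis=1))
        sgn[sgn == 0] = 1.0
        vi *= sgn[:, None]
        # dispersion-scaled tangent Gaussian kick
        sigma = np.arcsin(np.clip(np.sqrt(np.clip(di, 0.0, 1.0)), 0.0, 1.0))
        sigma = np.maximum(sigma, params.kick_floor)
        xi = rng.standard_normal((n, 3))
        xi -= vi * np.sum(xi * vi, axis=1, keepdims=True)
        vi = vi + sigma[:, None] * xi
        vi /= np.linalg.norm(vi, axis=1, keepdims=True)
        turn_ok = np.sum(vi * heading[active], axis=1) >= cos_thresh
        if step_i == 0:
            turn_ok[:] = True
        new_pos = pos[active] + params.step * vi
        new_vox = np.rint(new_pos).astype(int)
        inb = np.all((new_vox >= 0) & (new_vox < dims), axis=1)
        cv = np.clip(new_vox, 0, dims - 1)
        in_mask = nsup[cv[:, 0], cv[:, 1], cv[:, 2]] >= 1
        ok = turn_ok & inb & in_mask
        active = active[ok]
        if active.size == 0:
            break
        pos[active] = new_pos[ok]
        heading[active] = vi[ok]
        paths[active, lengths[active]] = pos[active]
        lengths[active] += 1
    return paths, lengths


def track(
    fit: FiberFit,
    seeds,
    labels: np.ndarray,
    params: TrackingParams | None = None,
    seed: int = 0,
) -> StreamlineSet:
    """Probabilistic tractography seeded in the given label ids.

    Each seed voxel contributes `samples_per_voxel` bidirectional
    streamlines.  Samples landing in voxels without a supported dyad
    are skipped and counted (`n_skipped`).  Deterministic for a fixed
    seed.
    """
    params = params or TrackingParams()
    if labels.shape != fit.shape:
        raise ValueError("labels grid does not match the fit grid")
    rng = np.random.default_rng(seed)
    nsup, dyads, fracs, disp = _dyad_field(fit)
    seed_ids = np.atleast_1d(np.asarray(list(seeds) if not isinstance(seeds, np.ndarray) else seeds, dtype=int))
    seed_mask = np.isin(labels, seed_ids)
    seed_vox = np.argwhere(seed_mask)
    if seed_vox.shape[0] == 0:
        warnings.warn("seed regions contain no voxels; empty streamline set", stacklevel=2)
        return StreamlineSet(
            np.empty((0, 3), np.float32), np.zeros(1, int), np.empty(0, int), fit.shape
        )
    reps = np.repeat(np.arange(seed_vox.shape[0]), params.samples_per_voxel)
    start = seed_vox[reps].astype(np.float64) + rng.uniform(-0.5, 0.5, (reps.size, 3))
    seed_region = labels[seed_vox[reps, 0], seed_vox[reps, 1], seed_vox[reps, 2]]

    vox = np.rint(start).astype(int)
    vox = np.clip(vox, 0, np.array(fit.shape) - 1)
    ok = nsup[vox[:, 0], vox[:, 1], vox[:, 2]] >= 1
    n_skipped = int(np.sum(~ok))
    start, seed_region, vox = start[ok], seed_region[ok], vox[ok]
    if start.shape[0] == 0:
        return StreamlineSet(
            np.empty((0, 3), np.float32), np.zeros(1, int), np.empty(0, int),
            fit.shape, n_skipped,
        )

    # initial heading: dyad drawn once per sample at the seed voxel
    f = fracs[vox[:, 0], vox[:, 1], vox[:, 2]]
    v = dyads[vox[:, 0], vox[:, 1], vox[:, 2]]
    cum = np.cumsum(f, axis=1)
    u = rng.random(start.shape[0]) * cum[:, -1]
    choice = (u[:, None] >= cum).sum(axis=1)
    init_dir = v[np.arange(start.shape[0]), choice].astype(np.float64)

    fwd, lf = _propagate(start, init_dir, nsup, dyads, fracs, disp, params, rng)
    bwd, lb = _propagate(start, -init_dir, nsup, dyads, fracs, disp, params, rng)

    n = start.shape[0]
    total_lens = lf + lb - 1  # seed point shared
    keep = total_lens >= 2
    offsets = np.zeros(int(np.sum(keep)) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(total_lens[keep])
    pts = np.empty((int(offsets[-1]), 3), dtype=np.float32)
    j = 0
    for i in np.flatnonzero(keep):
        back = bwd[i, 1 : lb[i]][::-1]  # exclude duplicated seed point
        fwdp = fwd[i, : lf[i]]
        L = total_lens[i]
        pts[j : j + lb[i] - 1] = back
        pts[j + lb[i] - 1 : j + L] = fwdp
        j += L
    return StreamlineSet(pts, offsets, seed_region[keep].astype(int), fit.shape, n_skipped)


def density_map(streamlines: StreamlineSet, grid_shape=None) -> DensityMap:
    """Streamline visitation counts: each streamline increments a voxel
    at most once, however many of its points fall there."""
    shape = tuple(grid_shape or streamlines.grid_shape)
    counts = np.zeros(shape, dtype=np.int64)
    dims = np.array(shape)
    for i in range(len(streamlines)):
        pts = streamlines.points[streamlines.offsets[i] : streamlines.offsets[i + 1]]
        vox = np.rint(pts).astype(int)
        if np.any(vox < 0) or np.any(vox >= dims):
            raise ValueError(f"streamline {i} has points outside the grid")
        lin = np.unique(np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape))
        counts.ravel()[lin] += 1
    return DensityMap(counts=counts, total_streamlines=len(streamlines))
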