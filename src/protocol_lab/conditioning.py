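"""Rotational stability of gradient schemes via design-matrix condition numbers.

For a single-shell scheme the diffusion-tensor fit solves a linear
system whose design matrix has one row per direction g:

    (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)

The condition number sigma_max / sigma_min of that N x 6 matrix bounds
the worst-case noise amplification of the tensor fit.  Because the
object being imaged can sit at any orientation in the magnet, a scheme
is audited by applying Haar-uniform random rotations to its directions
and summarizing the condition number across rotations.

For a perfectly uniform distribution of directions, the second- and
fourth-moment structure of the sphere gives Gram eigenvalues N/3, 4N/15
(x2) and 2N/15 (x3), hence a condition-number floor of sqrt(5/2) ~
1.5811 that no unit-vector scheme can beat at any rotation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .gradients import GradientScheme

__all__ = [
    "ConditionStats",
    "design_matrix",
    "condition_number",
    "random_rotations",
    "rotation_stability",
    "rank_schemes",
    "CN_LOWER_BOUND",
]

CN_LOWER_BOUND = float(np.sqrt(2.5))


@dataclasses.dataclass(frozen=True)
class ConditionStats:
    """Condition-number summary for one scheme over a rotation Monte Carlo."""

    scheme_name: str
    n_directions: int
    n_rotations: int
    cn_unrotated: float
    cn_mean: float
    cn_std: float
    cn_min: float
    cn_max: float
    seed: int
    n_degenerate: int = 0  # rotations where sigma_min vanished

    def __post_init__(self) -> None:
        if not (self.cn_min <= self.cn_mean <= self.cn_max):
            raise ValueError("condition-number summary violates min <= mean <= max")
        if self.cn_std < 0:
            raise ValueError("cn_std must be non-negative")


def _design_rows(dirs: np.ndarray) -> np.ndarray:
    """Second-order design rows for direction array of shape (..., 3)."""
    gx, gy, gz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    return np.stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=-1
    )


def design_matrix(scheme: GradientScheme | np.ndarray) -> np.ndarray:
    """N x 6 second-order design matrix (b0 volumes excluded)."""
    dirs = scheme.dwi_directions if isinstance(scheme, GradientScheme) else np.asarray(scheme, float)
    return _design_rows(dirs)


def condition_number(matrix: np.ndarray) -> float:
    """sigma_max / sigma_min of a matrix; +inf when rank deficient."""
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty matrix has no condition number")
    s = np.linalg.svd(m, compute_uv=False)
    if s[-1] <= s[0] * np.finfo(float).eps * max(m.shape):
        return float("inf")
    return float(s[0] / s[-1])


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) Haar-uniform rotation matrices via normalized 4D Gaussians."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


def _batched_cn(dirs: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Condition numbers of the design matrix under each rotation.

    Works on the 6x6 Gram matrix: singular values of D are the square
    roots of the Gram eigenvalues, so cn(D) = sqrt(l_max / l_min).
    """
    rotated = np.einsum("bij,nj->bni", rotations, dirs)
    D = _design_rows(rotated)  # (B, N, 6)
    G = np.einsum("bni,bnj->bij", D, D)
    lam = np.linalg.eigvalsh(G)
    lo, hi = lam[:, 0], lam[:, -1]
    cn = np.full(lo.shape, np.inf)
    ok = lo > hi * np.finfo(float).eps * D.shape[1]
    cn[ok] = np.sqrt(hi[ok] / lo[ok])
    return cn


def rotation_stability(
    scheme: GradientScheme,
    n_rotations: int = 50_000,
    seed: int = 0,
    batch: int = 2048,
) -> ConditionStats:
    """Monte Carlo over Haar-uniform rotations of the whole direction set.

    Degenerate draws (rank-deficient design) are kept as +inf and
    reported through ``n_degenerate`` rather than silently dropped; the
    summary statistics are then +inf as well, which is the honest answer.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng(seed)
    dirs = scheme.dwi_directions
    cn0 = condition_number(design_matrix(scheme))
    cns = np.empty(n_rotations)
    done = 0
    while done < n_rotations:
        b = min(batch, n_rotations - done)
        cns[done : done + b] = _batched_cn(dirs, random_rotations(b, rng))
        done += b
    n_bad = int(np.sum(~np.isfinite(cns)))
    return ConditionStats(
        scheme_name=scheme.name,
        n_directions=dirs.shape[0],
        n_rotations=n_rotations,
        cn_unrotated=cn0,
        cn_mean=float(np.mean(cns)),
        cn_std=float(np.std(cns, ddof=0)) if n_bad == 0 else float("inf"),
        cn_min=float(np.min(cns)),
        cn_max=float(np.max(cns)),
        seed=seed,
        n_degenerate=n_bad,
    )


def rank_schemes(stats: list[ConditionStats]) -> pd.DataFrame:
    """Rank schemes by ascending mean CN and by ascending CN std.

    Dense ranks; ties broken in favor of the scheme with more directions.
    Columns mirror the usual stability-audit table: directions, CN of
    the unrotated set, Monte Carlo mean/std, std normalized by
    sqrt(directions), and the two rank columns.
    """
    if len(stats) < 2:
        raise ValueError("ranking needs at least two schemes")
    names = [s.scheme_name for s in stats]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scheme names in ranking input")
    df = pd.DataFrame(
        {
            "scheme": names,
            "n_directions": [s.n_directions for s in stats],
            "cn_unrotated": [s.cn_unrotated for s in stats],
            "cn_mean": [s.cn_mean for s in stats],
            "cn_std": [s.cn_std for s in stats],
        }
    )
    df["cn_std_per_sqrt_n"] = df["cn_std"] / np.sqrt(df["n_directions"])

    def dense_rank(col: str) -> np.ndarray:
        order = df.sort_values([col, "n_directions"], ascending=[True, False], kind="mergesort")
        ranks = np.empty(len(df), dtype=int)
        prev = None
        r = 0
        for pos, (_, row) in enumerate(order.iterrows()):
            if prev is None or row[col] != prev:
                r += 1
            ranks[df.index.get_loc(_)] = r
            prev = row[col]
        return ranks

    df["rank_cn_mean"] = dense_rank("cn_mean")
    df["rank_cn_std"] = dense_rank("cn_std")
    return df.sort_values("n_directions").reset_index(drop=True)
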