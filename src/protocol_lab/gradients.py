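"""Diffusion gradient schemes: generation, subsetting and FSL-style file IO.

A gradient scheme is a set of unit vectors on the sphere, one per
diffusion-weighted volume, plus per-volume b-values.  Because the
diffusion signal at a single shell is antipodally symmetric, a scheme is
really a set of *antipodal classes*: g and -g encode the same
measurement.  "Optimal" direction sets are built by electrostatic
repulsion of antipodal charge pairs (the classic Jones construction),
and angular subsets of an acquired table are extracted by snapping each
ideal direction to its best match in the table, maximizing the absolute
dot product.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "GradientScheme",
    "generate_uniform_directions",
    "subset_by_dot_product",
    "read_bvec_bval",
    "write_bvec_bval",
    "interleave_b0s",
    "electrostatic_energy",
]

DEFAULT_SEED = 20200421
_UNIT_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """N diffusion directions with b-values.

    b0 volumes are stored as zero vectors with b-value 0; they are kept
    for acquisition bookkeeping but excluded from all direction-set
    mathematics (`dwi_directions`).
    """

    directions: np.ndarray  # (N, 3) float
    bvalues: np.ndarray  # (N,) float, s/mm^2
    name: str = ""

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError(f"directions must be (N, 3), got {dirs.shape}")
        if dirs.shape[0] < 1:
            raise ValueError("a scheme needs at least one volume")
        if bvals.shape[0] != dirs.shape[0]:
            raise ValueError(
                f"bvalues length {bvals.shape[0]} != directions length {dirs.shape[0]}"
            )
        norms = np.linalg.norm(dirs, axis=1)
        dwi = bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > _UNIT_TOL):
            raise ValueError("all weighted directions must have unit norm")
        if np.any(norms[~dwi] > _UNIT_TOL):
            raise ValueError("b0 volumes must be encoded as zero vectors")
        d = dirs[dwi]
        if d.shape[0] > 1:
            dots = np.abs(d @ d.T)
            np.fill_diagonal(dots, 0.0)
            if np.any(dots > 1.0 - _UNIT_TOL):
                raise ValueError("directions contain duplicate antipodal classes")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)

    @property
    def n(self) -> int:
        return self.directions.shape[0]

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvalues > 0

    @property
    def dwi_directions(self) -> np.ndarray:
        """Unit directions of the weighted volumes only."""
        return self.directions[self.dwi_mask]

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(self.dwi_mask))

    def subset(self, indices: np.ndarray | list[int], name: str | None = None) -> "GradientScheme":
        idx = np.asarray(indices, dtype=int)
        return GradientScheme(
            self.directions[idx], self.bvalues[idx], name=name or f"{self.name}[{len(idx)}]"
        )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic near-uniform start: golden-angle spiral over one hemisphere."""
    i = np.arange(n, dtype=float) + 0.5
    z = i / n  # upper hemisphere only: antipodal classes
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def electrostatic_energy(directions: np.ndarray) -> float:
    """Antipodal Coulomb energy sum_{i<j} 1/|v_i - v_j| + 1/|v_i + v_j|."""
    v = np.asarray(directions, dtype=float)
    if v.shape[0] < 2:
        return 0.0
    diff = v[:, None, :] - v[None, :, :]
    summ = v[:, None, :] + v[None, :, :]
    dm = np.linalg.norm(diff, axis=-1)
    dp = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(v.shape[0], k=1)
    return float(np.sum(1.0 / dm[iu]) + np.sum(1.0 / dp[iu]))


def _energy_and_grad(x: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    X = x.reshape(n, 3)
    r = np.linalg.norm(X, axis=1, keepdims=True)
    V = X / r
    diff = V[:, None, :] - V[None, :, :]
    summ = V[:, None, :] + V[None, :, :]
    dm = np.linalg.norm(diff, axis=-1)
    dp = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dm, np.inf)
    np.fill_diagonal(dp, np.inf)  # self term 1/|2v| is constant (=1/2); drop it
    iu = np.triu_indices(n, k=1)
    energy = float(np.sum(1.0 / dm[iu]) + np.sum(1.0 / dp[iu]))
    # dE/dV_i = sum_j -(v_i - v_j)/dm^3 - (v_i + v_j)/dp^3
    Gv = -(diff / dm[..., None] ** 3).sum(axis=1) - (summ / dp[..., None] ** 3).sum(axis=1)
    # chain rule through normalization v = x/|x|
    Gx = (Gv - V * np.sum(Gv * V, axis=1, keepdims=True)) / r
    return energy, Gx.ravel()


def generate_uniform_directions(
    n: int,
    seed: int = DEFAULT_SEED,
    iterations: int = 1000,
    bvalue: float = 4000.0,
    n_restarts: int = 3,
    return_trace: bool = False,
):
    """Electrostatic-repulsion direction set: n antipodal charge pairs on the sphere.

    Minimizes sum_{i<j} (1/|v_i - v_j| + 1/|v_i + v_j|) with L-BFGS from a
    deterministic spiral start plus seeded random restarts, keeping the
    lowest-energy local optimum.  Deterministic for fixed seed.

    Parameters
    ----------
    n : number of directions (antipodal classes), >= 1.
    seed : RNG seed for the random restarts.
    iterations : maximum optimizer iterations per restart.
    bvalue : b-value assigned to every direction (s/mm^2).
    n_restarts : random restarts in addition to the spiral start.
    return_trace : if True, also return the per-iteration energy of the
        winning restart (non-increasing).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 1:
        v = np.array([[0.0, 0.0, 1.0]])
        scheme = GradientScheme(v, np.full(1, bvalue), name="uniform-1")
        return (scheme, [0.0]) if return_trace else scheme
    if iterations == 0:
        # no optimization requested: the deterministic spiral start, which is
        # already near-uniform (useful for very large n)
        V = _fibonacci_hemisphere(n)
        scheme = GradientScheme(V, np.full(n, bvalue), name=f"uniform-{n}")
        return (scheme, [electrostatic_energy(V)]) if return_trace else scheme

    starts = [_fibonacci_hemisphere(n)]
    for _ in range(n_restarts):
        x = rng.standard_normal((n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        starts.append(x)

    best = None
    for x0 in starts:
        trace: list[float] = []

        def cb(xk, _trace=trace):
            _trace.append(_energy_and_grad(xk, n)[0])

        res = minimize(
            _energy_and_grad,
            x0.ravel(),
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": iterations, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best[0]:
            V = res.x.reshape(n, 3)
            V /= np.linalg.norm(V, axis=1, keepdims=True)
            best = (res.fun, V, [_energy_and_grad(x0.ravel(), n)[0]] + trace)

    _, V, trace = best
    # canonical hemisphere orientation: positive z (ties: positive y, x)
    flip = (V[:, 2] < 0) | ((V[:, 2] == 0) & (V[:, 1] < 0))
    V = np.where(flip[:, None], -V, V)
    scheme = GradientScheme(V, np.full(n, bvalue), name=f"uniform-{n}")
    return (scheme, trace) if return_trace else scheme


def subset_by_dot_product(full: GradientScheme, target: GradientScheme) -> list[int]:
    """Snap each target direction to its best antipodal match in `full`.

    Matching maximizes |g_target . g_full|; selected indices are unique,
    assigned greedily in descending match quality over all (target, full)
    pairs so that collisions fall through to the next-best unused vector.
    Returns indices into `full`, one per target direction, in target order.
    """
    ft = full.dwi_directions
    tg = target.dwi_directions
    if tg.shape[0] > ft.shape[0]:
        raise ValueError(
            f"target has {tg.shape[0]} directions but full only {ft.shape[0]}"
        )
    M = np.abs(tg @ ft.T)  # (t, f)
    order = np.argsort(M, axis=None)[::-1]
    assigned = np.full(tg.shape[0], -1, dtype=int)
    used = np.zeros(ft.shape[0], dtype=bool)
    remaining = tg.shape[0]
    for flat in order:
        i, j = divmod(int(flat), ft.shape[0])
        if assigned[i] >= 0 or used[j]:
            continue
        assigned[i] = j
        used[j] = True
        remaining -= 1
        if remaining == 0:
            break
    if remaining:
        raise ValueError("no unique assignment of subset indices was possible")
    # map DWI-relative indices back into the full volume list
    dwi_idx = np.flatnonzero(full.dwi_mask)
    return [int(dwi_idx[j]) for j in assigned]


def interleave_b0s(scheme: GradientScheme, every: int = 12) -> GradientScheme:
    """Acquisition layout: one b0 volume before every `every` DWI volumes."""
    dirs: list[np.ndarray] = []
    bvals: list[float] = []
    for i in range(scheme.n):
        if i % every == 0:
            dirs.append(np.zeros(3))
            bvals.append(0.0)
        dirs.append(scheme.directions[i])
        bvals.append(scheme.bvalues[i])
    return GradientScheme(np.array(dirs), np.array(bvals), name=f"{scheme.name}+b0")


def _parse_numeric_rows(path: Path) -> list[list[float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            vals = []
            for tok in line.split():
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric token {tok!r} on line {lineno}"
                    ) from None
            rows.append(vals)
    return rows


def read_bvec_bval(path_bvec, path_bval, name: str | None = None) -> GradientScheme:
    """Read an FSL-style gradient table (bvec: 3 rows of N, bval: N floats)."""
    path_bvec, path_bval = Path(path_bvec), Path(path_bval)
    brows = _parse_numeric_rows(path_bvec)
    if len(brows) != 3:
        raise ValueError(f"{path_bvec}: expected 3 rows, found {len(brows)}")
    if len({len(r) for r in brows}) != 1:
        raise ValueError(f"{path_bvec}: rows have unequal lengths")
    vrows = _parse_numeric_rows(path_bval)
    bvals = np.array([v for row in vrows for v in row], dtype=float)
    dirs = np.array(brows, dtype=float).T
    if bvals.shape[0] != dirs.shape[0]:
        raise ValueError(
            f"{path_bval}: {bvals.shape[0]} b-values for {dirs.shape[0]} directions"
        )
    # renormalize weighted rows to absorb text truncation
    norms = np.linalg.norm(dirs, axis=1)
    w = bvals > 0
    dirs[w] /= norms[w][:, None]
    return GradientScheme(dirs, bvals, name=name or path_bvec.stem)


def write_bvec_bval(scheme: GradientScheme, path_bvec, path_bval) -> None:
    """Write an FSL-style bvec/bval pair (full precision, round-trip safe)."""
    with open(path_bvec, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.16g}" for v in scheme.directions[:, axis]) + "\n")
    with open(path_bval, "w") as fh:
        fh.write(" ".join(f"{v:.16g}" for v in scheme.bvalues) + "\n")
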