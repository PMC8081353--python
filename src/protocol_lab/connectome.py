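"""Connectome construction and comparison.

A connectome is a region-by-region matrix of streamline counts.  Two
comparison measures are provided:

* global similarity: Spearman rank correlation over the off-diagonal
  upper-triangle weight vectors of two connectomes on the same region
  set;
* per-node similarity: the Blondel coupled iteration
  S_{k+1} = B S_k A^T + B^T S_k A, started from the all-ones matrix and
  normalized to unit Frobenius norm each step.  The even iterates
  converge (the odd ones may oscillate), so convergence is tested on
  iterates two apart and the even-iterate limit is returned.  When both
  graphs share a region set, the diagonal of S scores how well each
  region's connectivity pattern is preserved between the two graphs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import RegionInfo
from .tracking import StreamlineSet

__all__ = [
    "Connectome",
    "VertexSimilarity",
    "build_connectome",
    "spearman_similarity",
    "blondel_similarity",
    "threshold_similarity",
]


@dataclasses.dataclass
class Connectome:
    """Region x region streamline-count matrix.

    The matrix is symmetrized on construction; self-connections are
    kept on the diagonal but excluded from similarity vectors.
    Endpoints in unlabelled voxels are tallied in `n_unassigned` and do
    not enter the matrix.
    """

    weights: np.ndarray  # (R, R) non-negative, symmetric
    region_ids: list[int]
    region_names: list[str]
    hemispheres: list[str]
    metadata: dict = dataclasses.field(default_factory=dict)
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def subgraph(self, hemisphere: str) -> "Connectome":
        """Rows/columns whose region carries the given hemisphere tag."""
        keep = [i for i, h in enumerate(self.hemispheres) if h == hemisphere]
        return Connectome(
            weights=self.weights[np.ix_(keep, keep)],
            region_ids=[self.region_ids[i] for i in keep],
            region_names=[self.region_names[i] for i in keep],
            hemispheres=[hemisphere] * len(keep),
            metadata=dict(self.metadata, subgraph=hemisphere),
            n_unassigned=self.n_unassigned,
        )

    def offdiag_vector(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.weights[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.region_names, columns=self.region_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, regions: dict[int, RegionInfo] | None = None) -> "Connectome":
        df = pd.read_csv(path, index_col=0)
        names = list(df.index)
        hemis = [n.split("_", 1)[0] if "_" in n else "" for n in names]
        return cls(
            weights=df.to_numpy(dtype=float),
            region_ids=list(range(1, len(names) + 1)),
            region_names=names,
            hemispheres=hemis,
        )


def build_connectome(
    streamlines: StreamlineSet,
    labels: np.ndarray,
    regions: dict[int, RegionInfo],
    metadata: dict | None = None,
) -> Connectome:
    """Count streamline terminations between regions.

    Each streamline contributes one count to (seed region, region of
    each terminal point); the matrix is then symmetrized as
    (W + W^T) / 2.  Terminal points in unlabelled voxels go to an
    unassigned tally instead of the matrix.
    """
    if labels.shape != streamlines.grid_shape:
        raise ValueError("labels grid does not match the tracking grid")
    ids = sorted(regions)
    pos = {rid: i for i, rid in enumerate(ids)}
    R = len(ids)
    W = np.zeros((R, R))
    unassigned = 0
    if len(streamlines):
        ends = np.rint(streamlines.endpoints()).astype(int)  # (n, 2, 3)
        dims = np.array(labels.shape)
        ends = np.clip(ends, 0, dims - 1)
        for e in range(2):
            lab = labels[ends[:, e, 0], ends[:, e, 1], ends[:, e, 2]]
            for sl_seed, sl_lab in zip(streamlines.seed_regions, lab):
                if sl_lab == 0 or int(sl_lab) not in pos:
                    unassigned += 1
                    continue
                W[pos[int(sl_seed)], pos[int(sl_lab)]] += 1.0
    W = (W + W.T) / 2.0
    return Connectome(
        weights=W,
        region_ids=ids,
        region_names=[regions[i].name for i in ids],
        hemispheres=[regions[i].hemisphere for i in ids],
        metadata=metadata or {},
        n_unassigned=unassigned,
    )


def spearman_similarity(a: Connectome, b: Connectome) -> tuple[float, float]:
    """Spearman rank correlation of off-diagonal upper-triangle weights.

    Average ranks for ties.  Raises on constant weight vectors, for
    which rank correlation is undefined.
    """
    if a.region_names != b.region_names:
        raise ValueError("connectomes must share the same region set and order")
    x, y = a.offdiag_vector(), b.offdiag_vector()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant weight vectors")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclasses.dataclass
class VertexSimilarity:
    """Blondel node-similarity matrix between two graphs."""

    S: np.ndarray  # (R_a, R_b), unit Frobenius norm
    iterations: int
    converged: bool
    region_names_a: list[str] = dataclasses.field(default_factory=list)
    region_names_b: list[str] = dataclasses.field(default_factory=list)

    def node_scores(self) -> pd.Series:
        """Diagonal scores for matched region pairs (same region sets)."""
        if self.S.shape[0] != self.S.shape[1]:
            raise ValueError("node scores need matching region sets")
        names = self.region_names_a or [str(i) for i in range(self.S.shape[0])]
        return pd.Series(np.diag(self.S), index=names)


def blondel_similarity(
    a: Connectome | np.ndarray,
    b: Connectome | np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> VertexSimilarity:
    """Even-iterate limit of S <- B S A^T + B^T S A from the all-ones start.

    A is the adjacency of graph `a` (columns of S), B of graph `b`
    (rows of S); each iterate is normalized to unit Frobenius norm and
    convergence is declared when consecutive even iterates differ by
    less than `tol` in Frobenius norm.

    For `Connectome` inputs the diagonal (self-connection counts) is
    excluded from the adjacency, matching the off-diagonal convention
    of the global comparison: seed-region self-counts otherwise swamp
    the between-region structure the similarity is meant to score.
    Raw arrays are used exactly as given.
    """
    A = a.weights if isinstance(a, Connectome) else np.asarray(a, float)
    B = b.weights if isinstance(b, Connectome) else np.asarray(b, float)
    if isinstance(a, Connectome):
        A = A - np.diag(np.diag(A))
    if isinstance(b, Connectome):
        B = B - np.diag(np.diag(B))
    if np.any(A < 0) or np.any(B < 0):
        raise ValueError("adjacency matrices must be non-negative")
    S = np.ones((B.shape[0], A.shape[0]))
    S /= np.linalg.norm(S)
    prev_even = S.copy()
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        S = B @ S @ A.T + B.T @ S @ A
        nrm = np.linalg.norm(S)
        if nrm == 0:
            break  # empty graphs: keep the flat matrix
        S /= nrm
        iterations = it
        if it % 2 == 0:
            if np.linalg.norm(S - prev_even) < tol:
                converged = True
                break
            prev_even = S.copy()
    return VertexSimilarity(
        S=S,
        iterations=iterations,
        converged=converged,
        region_names_a=a.region_names if isinstance(a, Connectome) else [],
        region_names_b=b.region_names if isinstance(b, Connectome) else [],
    )


def threshold_similarity(sim: VertexSimilarity, level: float):
    """Zero out similarity entries below `level`.

    Returns (thresholded matrix, per-node scores or None, sparsity),
    where sparsity is the fraction of entries surviving the threshold.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    S = np.where(sim.S >= level, sim.S, 0.0)
    surviving = float(np.count_nonzero(S)) / S.size
    scores = None
    if sim.S.shape[0] == sim.S.shape[1]:
        names = sim.region_names_a or [str(i) for i in range(S.shape[0])]
        scores = pd.Series(np.diag(sim.S), index=names)
    return S, scores, surviving
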