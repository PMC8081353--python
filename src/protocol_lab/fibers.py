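"""Per-voxel diffusion modelling: tensor fit, multi-stick ball-and-stick
fit with model selection, and bootstrap orientation uncertainty.

The ball-and-stick model describes the single-shell signal in a voxel
as an isotropic "ball" compartment plus up to four perfectly
anisotropic "stick" compartments sharing one diffusivity d:

    S(g) = A0 e^{-b d} + sum_i A_i e^{-b d (g.v_i)^2},
    S0 = A0 + sum_i A_i,   f_i = A_i / S0.

Amplitudes and diffusivity are fitted in log space (which enforces
positivity and makes sum f_i <= 1 automatic), orientations as spherical
angles.  All voxels are fitted simultaneously by a batched
Levenberg-Marquardt loop; the number of sticks (0-4) is chosen per
voxel by BIC, and sticks with volume fraction below a support threshold
are not counted as detected fiber populations ("dyads").

Orientation uncertainty is quantified by residual-bootstrap refits: the
dispersion of a dyad is 1 - ||mean of its sign-aligned bootstrap
replicates||, a scalar in [0, 1] that is 0 when every replicate agrees
(up to sign) and approaches 1/2 for isotropically scattered replicates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .phantom import DWIVolume

__all__ = [
    "TensorFit",
    "FiberFit",
    "DyadCensus",
    "fit_tensor",
    "fit_ball_and_stick",
    "dyad_dispersion",
    "dyad_census",
    "SUPPORT_THRESHOLD",
]

SUPPORT_THRESHOLD = 0.05
_EPS = 1e-12


# --------------------------------------------------------------------------
# tensor fit (log-linear least squares)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TensorFit:
    """Diffusion-tensor fit over the masked voxels."""

    mask_idx: tuple[np.ndarray, ...]  # voxel indices (3 arrays)
    shape: tuple[int, int, int]
    tensors: np.ndarray  # (V, 3, 3)
    evals: np.ndarray  # (V, 3) ascending
    evecs: np.ndarray  # (V, 3, 3), evecs[:, :, i] for evals[:, i]
    md: np.ndarray  # (V,)
    fa: np.ndarray  # (V,)
    s0: np.ndarray  # (V,)

    @property
    def principal(self) -> np.ndarray:
        """Principal eigenvector per voxel, (V, 3)."""
        return self.evecs[:, :, 2]

    def volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask_idx] = values
        return out


def _design6(dirs: np.ndarray) -> np.ndarray:
    gx, gy, gz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    return np.stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=-1
    )


def fit_tensor(dwi: DWIVolume, mask: np.ndarray) -> TensorFit:
    """Log-linear least-squares tensor fit (the standard DTIFIT procedure).

    The design couples the six tensor elements through the second-order
    direction monomials, augmented with a constant column for log S0.
    """
    bvals = dwi.scheme.bvalues
    if dwi.scheme.n < 7 or dwi.scheme.n_dwi < 6 or np.count_nonzero(bvals == 0) < 1:
        raise ValueError("tensor fit needs >= 6 weighted volumes and >= 1 b0")
    dirs = dwi.scheme.directions
    X = np.hstack([-bvals[:, None] * _design6(dirs), np.ones((dwi.scheme.n, 1))])
    idx = np.nonzero(mask)
    y = np.log(np.clip(dwi.data[idx], _EPS, None))  # (V, M)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, V)
    dxx, dyy, dzz, dxy, dxz, dyz, logs0 = coef
    T = np.empty((y.shape[0], 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = dxx, dyy, dzz
    T[:, 0, 1] = T[:, 1, 0] = dxy
    T[:, 0, 2] = T[:, 2, 0] = dxz
    T[:, 1, 2] = T[:, 2, 1] = dyz
    evals, evecs = np.linalg.eigh(T)
    md = evals.mean(axis=1)
    num = np.sum((evals - md[:, None]) ** 2, axis=1)
    den = np.sum(evals**2, axis=1)
    fa = np.sqrt(1.5 * num / np.clip(den, _EPS, None))
    return TensorFit(
        mask_idx=idx, shape=dwi.shape, tensors=T, evals=evals, evecs=evecs,
        md=md, fa=fa, s0=np.exp(logs0),
    )


# --------------------------------------------------------------------------
# batched ball-and-stick fit
# --------------------------------------------------------------------------

def _angles_to_vec(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=-1)


def _vec_to_angles(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    return theta, phi


def _predict(p: np.ndarray, bvals: np.ndarray, gdirs: np.ndarray, k: int):
    """Model signal and cached terms. p: (V, 3k+2)."""
    A = np.exp(p[:, : k + 1])  # (V, k+1)
    d = np.exp(p[:, k + 1])  # (V,)
    Eball = np.exp(-bvals[None, :] * d[:, None])  # (V, M)
    if k == 0:
        return A[:, 0:1] * Eball, (A, d, Eball, None, None)
    theta = p[:, k + 2 :: 2]
    phi = p[:, k + 3 :: 2]
    v = _angles_to_vec(theta, phi)  # (V, k, 3)
    c = np.einsum("vkd,md->vkm", v, gdirs)  # (V, k, M)
    Estick = np.exp(-(bvals[None, None, :] * d[:, None, None]) * c**2)
    S = A[:, 0:1] * Eball + np.einsum("vk,vkm->vm", A[:, 1:], Estick)
    return S, (A, d, Eball, c, Estick)


def _jacobian(p, bvals, gdirs, k, cache):
    A, d, Eball, c, Estick = cache
    V, M = Eball.shape
    P = 3 * k + 2
    J = np.empty((V, M, P))
    J[:, :, 0] = A[:, 0:1] * Eball
    bd = bvals[None, :] * d[:, None]  # (V, M)
    ddelta = -bd * A[:, 0:1] * Eball
    if k:
        theta = p[:, k + 2 :: 2]
        phi = p[:, k + 3 :: 2]
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        dv_dtheta = np.stack([ct * cp, ct * sp, -st], axis=-1)  # (V, k, 3)
        dv_dphi = np.stack([-st * sp, st * cp, np.zeros_like(st)], axis=-1)
        g_dtheta = np.einsum("vkd,md->vkm", dv_dtheta, gdirs)
        g_dphi = np.einsum("vkd,md->vkm", dv_dphi, gdirs)
        for i in range(k):
            AE = A[:, i + 1, None] * Estick[:, i]  # (V, M)
            J[:, :, 1 + i] = AE
            ddelta = ddelta - bd * c[:, i] ** 2 * AE
            base = AE * (-2.0 * bd * c[:, i])
            J[:, :, k + 2 + 2 * i] = base * g_dtheta[:, i]
            J[:, :, k + 3 + 2 * i] = base * g_dphi[:, i]
    J[:, :, k + 1] = ddelta
    return J


_LOGD_LO, _LOGD_HI = np.log(1e-5), np.log(1e-2)


def _lm_fit(y, bvals, gdirs, p0, k, n_iter=40, ftol=1e-12):
    """Batched Levenberg-Marquardt; returns (params, sse)."""
    p = p0.copy()
    V = p.shape[0]
    lam = np.full(V, 1e-2)
    S, cache = _predict(p, bvals, gdirs, k)
    sse = np.sum((y - S) ** 2, axis=1)
    active = np.arange(V)
    for _ in range(n_iter):
        if active.size == 0:
            break
        pa = p[active]
        ya = y[active]
        Sa, cache = _predict(pa, bvals, gdirs, k)
        r = ya - Sa
        J = _jacobian(pa, bvals, gdirs, k, cache)
        JTJ = np.einsum("vmi,vmj->vij", J, J)
        JTr = np.einsum("vmi,vm->vi", J, r)
        diag = np.einsum("vii->vi", JTJ)
        # Marquardt scaling: add lam * diag(JTJ) on the diagonal
        Aa = JTJ.copy()
        ii = np.arange(JTJ.shape[1])
        Aa[:, ii, ii] += lam[active, None] * np.clip(diag, 1e-12, None) + 1e-14
        try:
            step = np.linalg.solve(Aa, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            Aa[:, ii, ii] += 1e-8
            step = np.linalg.solve(Aa, JTr[..., None])[..., 0]
        p_new = pa + step
        p_new[:, : k + 1] = np.clip(p_new[:, : k + 1], -30.0, 10.0)
        p_new[:, k + 1] = np.clip(p_new[:, k + 1], _LOGD_LO, _LOGD_HI)
        S_new, _ = _predict(p_new, bvals, gdirs, k)
        sse_new = np.sum((ya - S_new) ** 2, axis=1)
        better = sse_new < sse[active]
        improved_rel = (sse[active] - sse_new) > ftol * np.clip(sse[active], _EPS, None)
        p[active[better]] = p_new[better]
        sse[active[better]] = sse_new[better]
        lam[active[better]] /= 3.0
        lam[active[~better]] *= 5.0
        lam = np.clip(lam, 1e-9, 1e9)
        converged = (better & ~improved_rel) | (lam[active] > 1e8)
        active = active[~converged]
    return p, sse


def _init_params(k, s0, d0, evecs, rng, randomize=False):
    """Stack initial parameters for the k-stick model. evecs: (V, 3, 3)."""
    V = s0.shape[0]
    ftmpl = {1: [0.5], 2: [0.35, 0.25], 3: [0.30, 0.20, 0.12],
             4: [0.25, 0.18, 0.12, 0.08]}.get(k, [])
    fr = np.array(ftmpl)
    p = np.empty((V, 3 * k + 2))
    fball = 1.0 - fr.sum() if k else 1.0
    p[:, 0] = np.log(np.clip(s0 * fball, _EPS, None))
    for i in range(k):
        p[:, 1 + i] = np.log(np.clip(s0 * fr[i], _EPS, None))
    p[:, k + 1] = np.clip(np.log(np.clip(d0, 1e-6, None)), _LOGD_LO, _LOGD_HI)
    if k:
        vecs = np.empty((V, k, 3))
        for i in range(k):
            if i < 3:
                vecs[:, i] = evecs[:, :, 2 - i]
            else:
                w = rng.standard_normal((V, 3))
                vecs[:, i] = w / np.linalg.norm(w, axis=1, keepdims=True)
        if randomize:
            w = rng.standard_normal((V, k, 3))
            vecs = vecs + 0.8 * w
            vecs /= np.linalg.norm(vecs, axis=-1, keepdims=True)
        theta, phi = _vec_to_angles(vecs)
        p[:, k + 2 :: 2] = theta
        p[:, k + 3 :: 2] = phi
    return p


@dataclasses.dataclass
class FiberFit:
    """Ball-and-stick fit over the masked voxels (the multi-fiber analog
    of a BEDPOSTX output: dyads, fractions, dispersions)."""

    mask_idx: tuple[np.ndarray, ...]
    shape: tuple[int, int, int]
    s0: np.ndarray  # (V,)
    d: np.ndarray  # (V,)
    dyads: np.ndarray  # (V, 4, 3), zero rows where absent
    fractions: np.ndarray  # (V, 4), sorted descending, 0 where absent
    dispersion: np.ndarray  # (V, 4), NaN where absent or not bootstrapped
    n_supported: np.ndarray  # (V,) int, fractions >= support threshold
    model_order: np.ndarray  # (V,) int, BIC-chosen number of sticks
    support_threshold: float = SUPPORT_THRESHOLD

    @property
    def n_voxels(self) -> int:
        return self.s0.shape[0]

    def volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask_idx] = values
        return out


def fit_ball_and_stick(
    dwi: DWIVolume,
    mask: np.ndarray,
    max_sticks: int = 4,
    n_bootstrap: int = 50,
    seed: int = 0,
    support_threshold: float = SUPPORT_THRESHOLD,
    lm_iters: int = 40,
    boot_iters: int = 8,
    chunk: int = 4096,
) -> FiberFit:
    """Maximum-likelihood ball-and-stick fit with BIC model selection.

    For each voxel, models with 0..max_sticks sticks are fitted by
    batched Levenberg-Marquardt from tensor-derived starts (plus a
    perturbed restart for multi-stick models); the model order is chosen
    by BIC and sticks below the support threshold are not counted as
    dyads.  Residual-bootstrap refits give a per-dyad dispersion.
    """
    if not 1 <= max_sticks <= 4:
        raise ValueError("max_sticks must be in 1..4")
    n_params_max = 3 * max_sticks + 2
    if dwi.scheme.n < 2 * n_params_max:
        raise ValueError(
            f"scheme has {dwi.scheme.n} volumes; need >= {2 * n_params_max} "
            f"for a {max_sticks}-stick model"
        )
    idx = np.nonzero(mask)
    V = idx[0].shape[0]
    chunks = [np.arange(i, min(i + chunk, V)) for i in range(0, V, chunk)]
    outs = []
    for ci, sl in enumerate(chunks):
        sub_idx = tuple(a[sl] for a in idx)
        outs.append(
            _fit_chunk(
                dwi, sub_idx, max_sticks, n_bootstrap,
                np.random.default_rng([seed, ci]),
                support_threshold, lm_iters, boot_iters,
            )
        )
    cat = {key: np.concatenate([o[key] for o in outs]) for key in outs[0]}
    return FiberFit(
        mask_idx=idx, shape=dwi.shape, s0=cat["s0"], d=cat["d"],
        dyads=cat["dyads"], fractions=cat["fractions"],
        dispersion=cat["dispersion"], n_supported=cat["n_supported"],
        model_order=cat["model_order"], support_threshold=support_threshold,
    )


def _fit_chunk(dwi, idx, max_sticks, n_bootstrap, rng, support_threshold,
               lm_iters, boot_iters):
    bvals = dwi.scheme.bvalues
    gdirs = dwi.scheme.directions
    y = dwi.data[idx].astype(np.float64)  # (V, M)
    V, M = y.shape

    sub = DWIVolume(
        data=y.reshape(V, 1, 1, M), scheme=dwi.scheme,
        voxel_size=dwi.voxel_size, snr=dwi.snr,
    )
    tf = fit_tensor(sub, np.ones((V, 1, 1), dtype=bool))
    s0_init = np.clip(tf.s0, _EPS, None)
    d_init = np.clip(tf.md, 2e-4, 3e-3)

    results = {}
    sse_floor = 1e-12 * np.clip(np.sum(y**2, axis=1), _EPS, None)
    for k in range(0, max_sticks + 1):
        inits = [_init_params(k, s0_init, d_init, tf.evecs, rng)]
        if k >= 2:
            inits.append(_init_params(k, s0_init, d_init, tf.evecs, rng, randomize=True))
        best_p, best_sse = None, None
        for p0 in inits:
            p, sse = _lm_fit(y, bvals, gdirs, p0, k, n_iter=lm_iters)
            if best_p is None:
                best_p, best_sse = p, sse
            else:
                take = sse < best_sse
                best_p[take] = p[take]
                best_sse[take] = sse[take]
        P = 3 * k + 2
        bic = M * np.log(np.maximum(best_sse, sse_floor) / M) + P * np.log(M)
        results[k] = (best_p, best_sse, bic)

    bics = np.stack([results[k][2] for k in range(max_sticks + 1)], axis=1)
    model_order = np.argmin(bics, axis=1).astype(np.int16)

    s0 = np.empty(V)
    d = np.empty(V)
    dyads = np.zeros((V, 4, 3))
    fractions = np.zeros((V, 4))
    dispersion = np.full((V, 4), np.nan)
    n_supported = np.zeros(V, dtype=np.int16)

    for k in range(0, max_sticks + 1):
        sel = np.flatnonzero(model_order == k)
        if sel.size == 0:
            continue
        p = results[k][0][sel]
        A = np.exp(p[:, : k + 1])
        S0v = A.sum(axis=1)
        s0[sel] = S0v
        d[sel] = np.exp(p[:, k + 1])
        if k == 0:
            continue
        f = A[:, 1:] / S0v[:, None]  # (n, k)
        v = _angles_to_vec(p[:, k + 2 :: 2], p[:, k + 3 :: 2])  # (n, k, 3)
        order = np.argsort(-f, axis=1)
        f = np.take_along_axis(f, order, axis=1)
        v = np.take_along_axis(v, order[:, :, None], axis=1)
        fractions[sel, :k] = f
        dyads[sel, :k] = v
        n_supported[sel] = (f >= support_threshold).sum(axis=1)

        if n_bootstrap >= 2:
            disp = _bootstrap_dispersion(
                y[sel], bvals, gdirs, results[k][0][sel], k, v,
                n_bootstrap, rng, boot_iters,
            )
            dispersion[sel, :k] = disp

    return {
        "s0": s0, "d": d, "dyads": dyads, "fractions": fractions,
        "dispersion": dispersion, "n_supported": n_supported,
        "model_order": model_order,
    }


def _align_to_reference(ref: np.ndarray, rep: np.ndarray) -> np.ndarray:
    """Match replicate dyads to reference dyads by |dot| (greedy), sign-aligned.

    ref, rep: (V, k, 3).  Returns replicate vectors reordered to the
    reference ordering with signs flipped to agree.
    """
    V, k, _ = ref.shape
    D = np.einsum("vkd,vld->vkl", ref, rep)
    absD = np.abs(D.copy())
    out = np.empty_like(rep)
    for _ in range(k):
        flat = absD.reshape(V, -1)
        best = np.argmax(flat, axis=1)
        i, j = np.divmod(best, k)
        sign = np.sign(D[np.arange(V), i, j])
        sign[sign == 0] = 1.0
        out[np.arange(V), i] = rep[np.arange(V), j] * sign[:, None]
        absD[np.arange(V), i, :] = -1.0
        absD[np.arange(V), :, j] = -1.0
    return out


def _bootstrap_dispersion(y, bvals, gdirs, p_hat, k, ref_dyads_sorted, n_bootstrap,
                          rng, boot_iters):
    """Residual-bootstrap dispersion per dyad; returns (V, k) in [0, 1]."""
    V, M = y.shape
    S_hat, _ = _predict(p_hat, bvals, gdirs, k)
    resid = y - S_hat
    # reference in *fitted parameter* order for matching, then map to sorted order
    v_fit = _angles_to_vec(p_hat[:, k + 2 :: 2], p_hat[:, k + 3 :: 2])
    acc = np.zeros((V, k, 3))
    for _ in range(n_bootstrap):
        pick = rng.integers(0, M, size=(V, M))
        y_star = S_hat + np.take_along_axis(resid, pick, axis=1)
        p_star, _ = _lm_fit(y_star, bvals, gdirs, p_hat.copy(), k, n_iter=boot_iters)
        v_star = _angles_to_vec(p_star[:, k + 2 :: 2], p_star[:, k + 3 :: 2])
        acc += _align_to_reference(v_fit, v_star)
    R = np.linalg.norm(acc, axis=-1) / n_bootstrap  # (V, k) in fitted order
    disp_fit = 1.0 - np.clip(R, 0.0, 1.0)
    # reorder to fraction-descending order via |dot| matching with sorted dyads
    D = np.abs(np.einsum("vkd,vld->vkl", ref_dyads_sorted, v_fit))
    order = np.argmax(D, axis=2)  # for each sorted dyad, its fitted index
    return np.take_along_axis(disp_fit, order, axis=1)


def dyad_dispersion(replicate_dyads: np.ndarray) -> float:
    """Dispersion of a set of replicate dyads: 1 - ||mean of aligned vectors||.

    Replicates are antipodally symmetric, so each is first sign-aligned
    to the first principal direction of the set (the top eigenvector of
    sum v v^T); the result is 0 iff all replicates agree up to sign.
    """
    v = np.asarray(replicate_dyads, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("need >= 2 replicate 3-vectors")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < _EPS):
        raise ValueError("zero vectors are not valid dyads")
    v = v / norms[:, None]
    scatter = v.T @ v
    _, vecs = np.linalg.eigh(scatter)
    principal = vecs[:, -1]
    sign = np.sign(v @ principal)
    sign[sign == 0] = 1.0
    mean = np.mean(v * sign[:, None], axis=0)
    return float(1.0 - np.linalg.norm(mean))


@dataclasses.dataclass
class DyadCensus:
    """Per-region counts of voxels with 0-4 supported dyads."""

    table: pd.DataFrame  # columns: region, total, count_0..4, prop_0..4

    def proportions(self, region: str) -> np.ndarray:
        row = self.table[self.table["region"] == region]
        if row.empty:
            raise KeyError(f"region {region!r} absent from census")
        return row[[f"prop_{i}" for i in range(5)]].to_numpy().ravel()


def dyad_census(
    fit: FiberFit,
    labels: np.ndarray,
    region_names: dict[int, str] | None = None,
) -> DyadCensus:
    """Census of supported-dyad counts per region and globally.

    Regions with no in-mask voxels are absent from the table rather
    than reported as zeros.
    """
    if labels.shape != fit.shape:
        raise ValueError(f"labels shape {labels.shape} != fit grid {fit.shape}")
    lab = labels[fit.mask_idx]
    rows = []

    def add_row(name: str, counts_src: np.ndarray) -> None:
        total = counts_src.shape[0]
        counts = [int(np.sum(counts_src == i)) for i in range(5)]
        row = {"region": name, "total": total}
        row.update({f"count_{i}": c for i, c in enumerate(counts)})
        row.update({f"prop_{i}": c / total for i, c in enumerate(counts)})
        rows.append(row)

    add_row("global", fit.n_supported)
    for rid in sorted(np.unique(lab)):
        if rid == 0:
            continue
        name = region_names.get(int(rid), str(int(rid))) if region_names else str(int(rid))
        add_row(name, fit.n_supported[lab == rid])
    return DyadCensus(table=pd.DataFrame(rows))
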