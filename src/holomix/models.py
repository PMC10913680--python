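"""Sparse latent-variable solvers: PCA, sPCA, (s)PLS, (s)PLS-DA and the
multiblock discriminant model (DIABLO), plus class prediction.

All solvers share the same primitives: columns are centered and unit-scaled
(sample standard deviation, ddof=1) before fitting; sparsity is imposed by
soft-thresholding a weight vector at the magnitude of its (keep+1)-th
largest entry, leaving at most ``keep`` nonzeros; converged weight columns
are sign-fixed so their largest-magnitude entry is positive. Everything is
deterministic — there is no random number generation inside any solver.

The fitted object is a :class:`LatentModel` holding, per block, the
standardized training matrix, per-component scores, unit-norm (sparse)
weights and the regression loadings needed to project new samples through
the deflation sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import OmicsDataset, ValidationError

TOL = 1e-9
MAX_ITER = 500


class TunableFailure(RuntimeError):
    """A solver failure the tuning layer may repair by dropping
    near-zero-variance columns (see :func:`holomix.selection.nzv_repair`).

    ``datasets`` names the block(s) implicated in the failure.
    """

    def __init__(self, message: str, datasets: list[str] | None = None):
        super().__init__(message)
        self.datasets = list(datasets or [])


@dataclass
class BlockFit:
    """Per-block slice of a fitted latent model."""

    name: str
    feature_ids: list
    X: np.ndarray          # standardized training matrix, before deflation
    center: np.ndarray
    scale: np.ndarray
    scores: np.ndarray     # n x H
    weights: np.ndarray    # p x H, unit-norm, sparse under keep
    x_loadings: np.ndarray  # p x H regression loadings (deflation)
    keep: list = field(default_factory=list)

    def selected_features(self, ncomp: int | None = None) -> list:
        """Features with a nonzero weight on any of components 1..ncomp."""
        H = self.weights.shape[1] if ncomp is None else ncomp
        mask = (self.weights[:, :H] != 0).any(axis=1)
        return [f for f, m in zip(self.feature_ids, mask) if m]


@dataclass
class LatentModel:
    algorithm: str                 # pca|spca|pls|spls|plsda|splsda|diablo
    mode: str                      # regression|canonical|discriminant
    ncomp: int
    blocks: dict                   # name -> BlockFit
    sample_ids: list
    explained_variance: np.ndarray | None = None   # full spectrum (PCA family)
    class_labels: np.ndarray | None = None
    classes_: list | None = None
    dummy_Y: np.ndarray | None = None
    design: object | None = None   # DesignMatrix (diablo)
    y_block: str | None = None     # name of the outcome block (discriminant)
    y_loadings: np.ndarray | None = None  # q x H deflation loadings of Y

    @property
    def data_block_names(self) -> list:
        return [n for n in self.blocks if n != self.y_block]

    def block(self, name: str) -> BlockFit:
        if name not in self.blocks:
            raise KeyError(f"unknown block {name!r}; have {list(self.blocks)}")
        return self.blocks[name]


# ---------------------------------------------------------------- primitives

def center_scale(X: np.ndarray, center: bool = True, scale: bool = True,
                 block: str = "X"):
    """Standardize columns; constant columns under scaling raise
    :class:`TunableFailure` naming the block (the repair loop consumes it)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise TunableFailure(
                f"zero-variance column(s) {zero[:5].tolist()} in block "
                f"{block!r} cannot be unit-scaled", datasets=[block])
    else:
        sd = np.ones(X.shape[1])
    return (X - mu) / sd, mu, sd


def soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold `w` at its (keep+1)-th largest magnitude.

    Leaves at most ``keep`` nonzeros (exact magnitude ties at the cutoff
    shrink to zero); ties in the ranking keep the earlier index. Guards the
    degenerate all-tied case by retaining the first-ranked entry unshrunk.
    """
    p = w.size
    if keep >= p:
        return w.copy()
    if keep < 1:
        raise ValidationError(f"keep must be >= 1, got {keep}")
    absw = np.abs(w)
    order = np.lexsort((np.arange(p), -absw))
    active = order[:keep]
    lam = absw[order[keep]]
    out = np.zeros_like(w)
    out[active] = np.sign(w[active]) * (absw[active] - lam)
    if not out.any():
        out[order[0]] = w[order[0]]
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise TunableFailure("weight vector collapsed to zero during iteration")
    return v / n


def _sign_fix(weights: np.ndarray, *coupled: np.ndarray):
    """Flip a weight column (and anything coupled to it, e.g. its scores)
    so the largest-magnitude weight entry is positive."""
    j = int(np.argmax(np.abs(weights)))
    if weights[j] < 0:
        return (-weights, *(-c for c in coupled))
    return (weights, *coupled)


def _as_matrix(data, what: str = "X"):
    """Accept OmicsDataset / DataFrame / ndarray; return (array, feature ids, sample ids, name)."""
    if isinstance(data, OmicsDataset):
        return data.matrix(), data.feature_ids, data.sample_ids, data.name
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns), list(data.index), what
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{what} must be 2-D")
    return (arr, [f"{what}{j}" for j in range(arr.shape[1])],
            [f"s{i}" for i in range(arr.shape[0])], what)


def _svd_right(M: np.ndarray) -> np.ndarray:
    """Leading right singular vector, deterministic sign (largest entry > 0)."""
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    return _sign_fix(v)[0]


def _svd_left(M: np.ndarray) -> np.ndarray:
    u, _, _ = np.linalg.svd(M, full_matrices=False)
    return _sign_fix(u[:, 0])[0]


# ----------------------------------------------------------------- PCA/sPCA

def fit_pca(ds, ncomp: int, center: bool = True, scale: bool = True) -> LatentModel:
    """Principal component analysis by singular value decomposition.

    ``explained_variance`` holds the *full* spectrum over all
    min(n-1, p) components (shares of total variance, summing to 1);
    scores/loadings are stored for the requested ``ncomp`` only.
    """
    X, feats, samples, name = _as_matrix(ds)
    n, p = X.shape
    rank = min(n - 1, p)
    if not 1 <= ncomp <= rank:
        raise ValidationError(f"ncomp must be in [1, {rank}], got {ncomp}")
    try:
        Xs, mu, sd = center_scale(X, center, scale, block=name)
    except TunableFailure as exc:
        raise ValidationError(str(exc)) from exc
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    var = S[:rank] ** 2
    ev = var / var.sum()
    loadings = Vt[:ncomp].T.copy()
    scores = U[:, :ncomp] * S[:ncomp]
    for h in range(ncomp):
        loadings[:, h], scores[:, h] = _sign_fix(loadings[:, h], scores[:, h])
    blk = BlockFit(name=name, feature_ids=feats, X=Xs, center=mu, scale=sd,
                   scores=scores, weights=loadings, x_loadings=loadings.copy(),
                   keep=[p] * ncomp)
    return LatentModel(algorithm="pca", mode="regression", ncomp=ncomp,
                       blocks={name: blk}, sample_ids=samples,
                       explained_variance=ev)


def fit_spca(ds, ncomp: int, keep, center: bool = True, scale: bool = True,
             tol: float = TOL, max_iter: int = MAX_ITER) -> LatentModel:
    """Sparse PCA by iterative soft-thresholded rank-1 deflation.

    Per component the leading right singular vector of the current residual
    seeds an alternating update u <- Xv/|Xv|, w <- X'u, w soft-thresholded
    to ``keep[h]`` nonzeros and renormalized, until the loading change drops
    below `tol`. The residual is then deflated by t v' with t = Xv.
    """
    X, feats, samples, name = _as_matrix(ds)
    n, p = X.shape
    keep = _expand_keep(keep, ncomp, p)
    try:
        Xs, mu, sd = center_scale(X, center, scale, block=name)
    except TunableFailure as exc:
        raise ValidationError(str(exc)) from exc
    total_var = (Xs ** 2).sum()
    R = Xs.copy()
    W = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    ev = np.zeros(ncomp)
    for h in range(ncomp):
        v = _svd_right(R)
        for _ in range(max_iter):
            u = _unit(R @ v)
            w = soft_threshold_keep(R.T @ u, keep[h])
            v_new = _unit(w)
            if abs(v_new @ v) > 1 - 1e-15 or np.max(np.abs(v_new - np.sign(v_new @ v) * v)) < tol:
                v = v_new
                break
            v = v_new
        t = R @ v
        v, t = _sign_fix(v, t)
        W[:, h], T[:, h] = v, t
        ev[h] = (t @ t) / total_var if total_var > 0 else 0.0
        R = R - np.outer(t, v)
    blk = BlockFit(name=name, feature_ids=feats, X=Xs, center=mu, scale=sd,
                   scores=T, weights=W, x_loadings=W.copy(), keep=list(keep))
    return LatentModel(algorithm="spca", mode="regression", ncomp=ncomp,
                       blocks={name: blk}, sample_ids=samples,
                       explained_variance=ev)


def _expand_keep(keep, ncomp: int, p: int) -> list:
    if np.isscalar(keep):
        keep = [int(keep)] * ncomp
    keep = [int(k) for k in keep]
    if len(keep) != ncomp:
        raise ValidationError(f"need {ncomp} keep values, got {len(keep)}")
    for k in keep:
        if not 1 <= k <= p:
            raise ValidationError(f"keep value {k} outside [1, {p}]")
    return keep


# ----------------------------------------------------------------- (s)PLS

def dummy_code(labels) -> np.ndarray:
    """One-hot coding of class labels; column order = sorted labels."""
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    return np.array([[1.0 if l == c else 0.0 for c in classes] for l in labels])


def fit_spls(X, Y, ncomp: int, keepX=None, keepY=None,
             mode: str = "regression", center: bool = True, scale: bool = True,
             tol: float = TOL, max_iter: int = MAX_ITER,
             _algorithm: str | None = None) -> LatentModel:
    """Sparse partial least squares by NIPALS with soft-thresholding.

    Per component, the Y-weight is seeded from the leading right singular
    vector of the current X'Y, then the alternating updates

        a ∝ soft(X'u, keepX),  t = Xa;  b ∝ soft(Y't, keepY),  u = Yb

    run to convergence. Regression mode deflates both blocks on the X-score
    t (so swapping the blocks changes the result); canonical mode deflates
    Y on its own score u. Both blocks are standardized before fitting.
    """
    if mode not in ("regression", "canonical"):
        raise ValidationError(f"mode must be regression|canonical, got {mode!r}")
    Xm, xfeats, xsamples, xname = _as_matrix(X, "X")
    Ym, yfeats, ysamples, yname = _as_matrix(Y, "Y")
    if xname == yname:
        yname = xname + "_Y"
    if Xm.shape[0] != Ym.shape[0]:
        raise ValidationError("X and Y must share samples")
    if isinstance(X, OmicsDataset) and isinstance(Y, OmicsDataset):
        if X.sample_ids != Y.sample_ids:
            raise ValidationError("X and Y sample ids differ; harmonize first")
    n, p = Xm.shape
    q = Ym.shape[1]
    keepX = _expand_keep(keepX if keepX is not None else p, ncomp, p)
    keepY = _expand_keep(keepY if keepY is not None else q, ncomp, q)
    Xs, mux, sdx = center_scale(Xm, center, scale, block=xname)
    Ys, muy, sdy = center_scale(Ym, center, scale, block=yname)

    Xr, Yr = Xs.copy(), Ys.copy()
    A = np.zeros((p, ncomp)); B = np.zeros((q, ncomp))
    T = np.zeros((n, ncomp)); Uu = np.zeros((n, ncomp))
    Cx = np.zeros((p, ncomp)); Dy = np.zeros((q, ncomp))
    for h in range(ncomp):
        b = _svd_right(Xr.T @ Yr)
        u = Yr @ b
        a = np.zeros(p)
        for it in range(max_iter):
            a_new = _unit(soft_threshold_keep(Xr.T @ u, keepX[h]))
            t = Xr @ a_new
            b_new = _unit(soft_threshold_keep(Yr.T @ t, keepY[h]))
            u = Yr @ b_new
            delta = max(np.max(np.abs(a_new - np.sign(a_new @ a) * a)) if a.any() else np.inf,
                        np.max(np.abs(b_new - np.sign(b_new @ b) * b)))
            a, b = a_new, b_new
            if delta < tol:
                break
        else:
            raise TunableFailure(
                f"sPLS component {h + 1} did not converge in {max_iter} iterations",
                datasets=[xname, yname])
        t = Xr @ a
        u = Yr @ b
        a, t = _sign_fix(a, t)
        b, u = _sign_fix(b, u)
        tt = t @ t
        if tt == 0:
            raise TunableFailure(f"degenerate X-score at component {h + 1}",
                                 datasets=[xname])
        c = Xr.T @ t / tt
        Xr = Xr - np.outer(t, c)
        if mode == "regression":
            d = Yr.T @ t / tt
            Yr = Yr - np.outer(t, d)
        else:
            uu = u @ u
            if uu == 0:
                raise TunableFailure(f"degenerate Y-score at component {h + 1}",
                                     datasets=[yname])
            d = Yr.T @ u / uu
            Yr = Yr - np.outer(u, d)
        A[:, h], B[:, h], T[:, h], Uu[:, h] = a, b, t, u
        Cx[:, h], Dy[:, h] = c, d

    xblk = BlockFit(name=xname, feature_ids=xfeats, X=Xs, center=mux, scale=sdx,
                    scores=T, weights=A, x_loadings=Cx, keep=list(keepX))
    yblk = BlockFit(name=yname, feature_ids=yfeats, X=Ys, center=muy, scale=sdy,
                    scores=Uu, weights=B, x_loadings=Dy, keep=list(keepY))
    algo = _algorithm or ("spls" if (min(keepX) < p or min(keepY) < q) else "pls")
    return LatentModel(algorithm=algo, mode=mode, ncomp=ncomp,
                       blocks={xname: xblk, yname: yblk}, sample_ids=xsamples,
                       y_block=yname, y_loadings=Dy)


def fit_splsda(ds, labels, ncomp: int, keep=None, center: bool = True,
               scale: bool = True, **kw) -> LatentModel:
    """(Sparse) PLS discriminant analysis: regression-mode sPLS against the
    one-hot class matrix, with the class side never sparsified."""
    labels = np.asarray(labels, dtype=object)
    Ydum = dummy_code(labels)
    model = fit_spls(ds, Ydum, ncomp=ncomp, keepX=keep, keepY=None,
                     mode="regression", center=center, scale=scale,
                     _algorithm="splsda" if keep is not None else "plsda", **kw)
    model.mode = "discriminant"
    model.class_labels = labels
    model.classes_ = sorted(set(labels.tolist()))
    model.dummy_Y = Ydum
    return model


# ----------------------------------------------------------------- DIABLO

def fit_diablo(blocks: dict, labels, ncomp: int, design, keep=None,
               center: bool = True, scale: bool = True,
               tol: float = TOL, max_iter: int = MAX_ITER) -> LatentModel:
    """Supervised multiblock sparse PLS-DA.

    The one-hot class matrix joins as an extra block connected to every
    data block with weight 1; data-data connections carry the design-matrix
    weights. Per component, block coordinate ascent maximizes
    sum_{k<j} c_kj cov(X_k a_k, X_j a_j) with each data-block weight
    soft-thresholded to its keep count; each block is then deflated on its
    own score. The class block is never sparsified.
    """
    from .selection import DesignMatrix  # circular-free: selection imports models lazily
    names = list(blocks)
    if isinstance(design, (int, float)):
        design = DesignMatrix.uniform(names, float(design))
    if list(design.block_names) != names:
        design = design.reordered(names)
    labels = np.asarray(labels, dtype=object)
    Ydum = dummy_code(labels)
    K = Ydum.shape[1]

    mats, feats, samps, centers, scales = [], [], None, [], []
    for name in names:
        M, f, s, _ = _as_matrix(blocks[name], name)
        if samps is None:
            samps = s
        elif isinstance(blocks[name], OmicsDataset) and s != samps:
            raise ValidationError(f"block {name!r} has different samples")
        Ms, mu, sd = center_scale(M, center, scale, block=name)
        mats.append(Ms); feats.append(f); centers.append(mu); scales.append(sd)
    Ys, muy, sdy = center_scale(Ydum, center, scale, block="_outcome")
    mats.append(Ys); feats.append([f"class:{c}" for c in sorted(set(labels.tolist()))])
    centers.append(muy); scales.append(sdy)
    all_names = names + ["_outcome"]
    Bn = len(all_names)

    C = np.ones((Bn, Bn)) - np.eye(Bn)          # outcome tied to every block
    C[:len(names), :len(names)] = design.values  # data-data from the design

    keeps = []
    for k, name in enumerate(names):
        p = mats[k].shape[1]
        kv = p if keep is None else (keep[name] if isinstance(keep, dict) else keep[k])
        keeps.append(_expand_keep(kv, ncomp, p))
    keeps.append([K] * ncomp)  # outcome block dense

    n = mats[0].shape[0]
    R = [M.copy() for M in mats]
    W = [np.zeros((M.shape[1], ncomp)) for M in mats]
    T = [np.zeros((n, ncomp)) for _ in mats]
    CL = [np.zeros((M.shape[1], ncomp)) for M in mats]
    for h in range(ncomp):
        # a block whose residual has been exhausted (e.g. the rank-(K-1)
        # class block after K-1 components) sits out with zero weight
        active = [np.linalg.norm(R[k]) > 1e-9 for k in range(Bn)]
        if not any(active[:len(names)]):
            raise TunableFailure(
                f"all data blocks exhausted before component {h + 1}",
                datasets=list(names))
        a = []
        for k in range(Bn):
            if not active[k]:
                a.append(np.zeros(R[k].shape[1]))
                continue
            others = np.hstack([R[j] for j in range(Bn) if j != k])
            a.append(_svd_left(R[k].T @ others))
        t = [R[k] @ a[k] for k in range(Bn)]
        for it in range(max_iter):
            delta = 0.0
            for k in range(Bn):
                if not active[k]:
                    continue
                w = np.zeros(R[k].shape[1])
                for j in range(Bn):
                    if j != k and C[k, j] != 0:
                        w += C[k, j] * (R[k].T @ t[j])
                if np.linalg.norm(w) < 1e-300:
                    # no connected block carries signal for this one
                    active[k] = False
                    a[k] = np.zeros(R[k].shape[1])
                    t[k] = R[k] @ a[k]
                    continue
                if k < len(names):
                    w = soft_threshold_keep(w, keeps[k][h])
                a_new = _unit(w)
                delta = max(delta, np.max(np.abs(a_new - np.sign(a_new @ a[k]) * a[k]))
                            if a[k].any() else np.inf)
                a[k] = a_new
                t[k] = R[k] @ a[k]
            if delta < tol:
                break
        else:
            raise TunableFailure(
                f"DIABLO component {h + 1} did not converge in {max_iter} iterations",
                datasets=list(names))
        for k in range(Bn):
            if not active[k]:
                W[k][:, h] = a[k]
                continue
            a[k], t[k] = _sign_fix(a[k], t[k])
            tt = t[k] @ t[k]
            if tt == 0:
                raise TunableFailure(f"degenerate score in block {all_names[k]!r}",
                                     datasets=[all_names[k]] if k < len(names) else names)
            c = R[k].T @ t[k] / tt
            R[k] = R[k] - np.outer(t[k], c)
            W[k][:, h], T[k][:, h], CL[k][:, h] = a[k], t[k], c

    blockfits = {}
    for k, name in enumerate(all_names):
        blockfits[name] = BlockFit(name=name, feature_ids=feats[k], X=mats[k],
                                   center=centers[k], scale=scales[k],
                                   scores=T[k], weights=W[k], x_loadings=CL[k],
                                   keep=list(keeps[k]))
    model = LatentModel(algorithm="diablo", mode="discriminant", ncomp=ncomp,
                        blocks=blockfits, sample_ids=samps, design=design,
                        y_block="_outcome", y_loadings=CL[-1])
    model.class_labels = labels
    model.classes_ = sorted(set(labels.tolist()))
    model.dummy_Y = Ydum
    return model


# ------------------------------------------------------------- projection

def transform_block(model: LatentModel, block_name: str, X_new,
                    ncomp: int | None = None) -> np.ndarray:
    """Project new samples of one block to its component scores, replaying
    the training deflation sequence (valid for every algorithm here since
    each block is deflated on its own scores; regression-mode Y is the
    exception and is handled in :func:`predict_dummy`)."""
    blk = model.block(block_name)
    H = model.ncomp if ncomp is None else ncomp
    Xn = np.asarray(X_new, dtype=float)
    Xr = (Xn - blk.center) / blk.scale
    Tn = np.zeros((Xr.shape[0], H))
    for h in range(H):
        t = Xr @ blk.weights[:, h]
        Tn[:, h] = t
        Xr = Xr - np.outer(t, blk.x_loadings[:, h])
    return Tn


def transform_pair(model: LatentModel, X_new, Y_new,
                   ncomp: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project new (X, Y) sample pairs of a fitted (s)PLS model to their
    t- and u-scores, replaying the mode-specific deflation (regression mode
    deflates Y on the X-score, so the Y projection needs both matrices)."""
    xname, yname = model.data_block_names[0], model.y_block
    xblk, yblk = model.block(xname), model.block(yname)
    H = model.ncomp if ncomp is None else ncomp
    Xr = (np.asarray(X_new, dtype=float) - xblk.center) / xblk.scale
    Yr = (np.asarray(Y_new, dtype=float) - yblk.center) / yblk.scale
    Tn = np.zeros((Xr.shape[0], H))
    Un = np.zeros((Yr.shape[0], H))
    for h in range(H):
        t = Xr @ xblk.weights[:, h]
        u = Yr @ yblk.weights[:, h]
        Tn[:, h], Un[:, h] = t, u
        Xr = Xr - np.outer(t, xblk.x_loadings[:, h])
        if model.mode == "canonical":
            Yr = Yr - np.outer(u, yblk.x_loadings[:, h])
        else:
            Yr = Yr - np.outer(t, yblk.x_loadings[:, h])
    return Tn, Un


def predict_dummy(model: LatentModel, block_name: str, X_new,
                  ncomp: int | None = None) -> np.ndarray:
    """Predicted (unscaled) class-indicator responses for new samples of one
    block, via least squares of the standardized dummy matrix on the
    training scores."""
    if model.dummy_Y is None:
        raise ValidationError("not a discriminant model")
    H = model.ncomp if ncomp is None else ncomp
    Tn = transform_block(model, block_name, X_new, ncomp=H)
    blk = model.block(block_name)
    T = blk.scores[:, :H]
    yblk = model.block(model.y_block)
    Ys = yblk.X
    Bcoef, *_ = np.linalg.lstsq(T, Ys, rcond=None)
    return Tn @ Bcoef * yblk.scale + yblk.center


def _class_centroids(T: np.ndarray, labels, classes) -> np.ndarray:
    return np.vstack([T[np.asarray(labels) == c].mean(axis=0) for c in classes])


def _predict_one_block(model, block_name, X_new, distance, ncomp):
    classes = model.classes_
    if distance == "max":
        pred = predict_dummy(model, block_name, X_new, ncomp=ncomp)
        return np.array([classes[j] for j in np.argmax(pred, axis=1)], dtype=object)
    H = model.ncomp if ncomp is None else ncomp
    Tn = transform_block(model, block_name, X_new, ncomp=H)
    T = model.block(block_name).scores[:, :H]
    cent = _class_centroids(T, model.class_labels, classes)
    if distance == "centroids":
        d2 = ((Tn[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
    elif distance == "mahalanobis":
        resid = T - cent[[classes.index(c) for c in model.class_labels], :]
        dof = max(T.shape[0] - len(classes), 1)
        S = resid.T @ resid / dof + 1e-12 * np.eye(H)
        Sinv = np.linalg.inv(S)
        diff = Tn[:, None, :] - cent[None, :, :]
        d2 = np.einsum("nkh,hg,nkg->nk", diff, Sinv, diff)
    else:
        raise ValidationError(f"distance {distance!r} not implemented")
    return np.array([classes[j] for j in np.argmin(d2, axis=1)], dtype=object)


def predict_classes(model: LatentModel, new_blocks, distance: str = "centroids",
                    ncomp: int | None = None) -> np.ndarray:
    """Predict class labels for new samples.

    ``new_blocks`` is a single matrix/dataset for single-block discriminant
    models, or a name -> matrix mapping for DIABLO. DIABLO combines
    per-block predictions by majority vote; ties go to the block whose
    component-1 scores correlate best with the class indicators.
    """
    if model.mode != "discriminant":
        raise ValidationError("predict_classes needs a discriminant model")
    if model.algorithm != "diablo":
        name = model.data_block_names[0]
        X_new = new_blocks[name] if isinstance(new_blocks, dict) else new_blocks
        X_new, *_ = _as_matrix(X_new, name)
        return _predict_one_block(model, name, X_new, distance, ncomp)
    if not isinstance(new_blocks, dict):
        raise ValidationError("DIABLO prediction needs a name -> matrix mapping")
    names = [n for n in model.data_block_names if n in new_blocks]
    if not names:
        raise ValidationError("no known blocks supplied")
    preds, strengths = [], []
    for name in names:
        X_new, *_ = _as_matrix(new_blocks[name], name)
        preds.append(_predict_one_block(model, name, X_new, distance, ncomp))
        t1 = model.block(name).scores[:, 0]
        Yd = model.dummy_Y
        cors = [abs(np.corrcoef(t1, Yd[:, k])[0, 1]) for k in range(Yd.shape[1])]
        strengths.append(max(cors))
    block_rank = np.argsort([-s for s in strengths], kind="stable")
    n_new = len(preds[0])
    out = np.empty(n_new, dtype=object)
    for i in range(n_new):
        votes = {}
        for pr in preds:
            votes[pr[i]] = votes.get(pr[i], 0) + 1
        top = max(votes.values())
        tied = [c for c, v in votes.items() if v == top]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            for k in block_rank:  # best-correlated block breaks the tie
                if preds[k][i] in tied:
                    out[i] = preds[k][i]
                    break
    return out
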