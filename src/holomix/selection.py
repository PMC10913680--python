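"""Cross-validation machinery and the automated selection rules.

Component counts are chosen by three rules, one per analysis family:

* PCA: smallest number of components reaching 80 % cumulative explained
  variance;
* (s)PLS: the last component whose cross-validated total Q² (1 - PRESS/RSS,
  pooled over response columns) exceeds 0.0975 (= 1 - 0.95²);
* (s)PLS-DA and the multiblock model: lowest cross-validated balanced error
  rate (BER) under the centroids distance.

Feature counts (keepX) are tuned per component on a grid: by CV BER for the
discriminant models, and by correlation between predicted and fitted
component scores for pairwise sPLS.

CV solver failures caused by near-zero-variance columns are repaired
automatically: the implicated block's lowest-uniqueness columns are removed
and the computation restarts (:func:`nzv_repair`), mirroring the silent
repair loop of the GUI workflow this library reimplements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import OmicsDataset, ValidationError
from . import models as M
from .models import (LatentModel, TunableFailure, fit_spls, fit_splsda,
                     fit_diablo, dummy_code)

Q2_THRESHOLD = 0.0975
VARIANCE_THRESHOLD = 0.80

#: Default keepX candidates; truncated at each block's feature count.
DEFAULT_KEEP_GRID = tuple(range(1, 11)) + (15, 20, 25, 30, 40, 50)


@dataclass
class DesignMatrix:
    """Symmetric block-connection weights in [0, 1] with a zero diagonal."""

    block_names: list
    values: np.ndarray
    raw_minimum: float | None = None
    pairwise_correlations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        b = len(self.block_names)
        if self.values.shape != (b, b):
            raise ValidationError("design matrix shape does not match block count")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("design matrix must be symmetric")
        if np.diag(self.values).any():
            raise ValidationError("design matrix diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("design weights must lie in [0, 1]")

    @classmethod
    def uniform(cls, block_names, value: float) -> "DesignMatrix":
        b = len(block_names)
        return cls(list(block_names), value * (np.ones((b, b)) - np.eye(b)))

    def reordered(self, names) -> "DesignMatrix":
        idx = [self.block_names.index(n) for n in names]
        return DesignMatrix(list(names), self.values[np.ix_(idx, idx)],
                            raw_minimum=self.raw_minimum,
                            pairwise_correlations=self.pairwise_correlations)


@dataclass
class TuneResult:
    """Outcome of a tuning run: selections, CV surfaces and the repair log."""

    selected_ncomp: int
    selected_keep: dict          # dataset name -> list of keep per component
    criterion_surface: dict      # grid point -> mean criterion value
    criterion: str               # ber | q2 | score_correlation
    folds: int
    repeats: int
    seed: int
    repair_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"selected_ncomp": self.selected_ncomp,
                "selected_keep": {k: list(v) for k, v in self.selected_keep.items()},
                "criterion": self.criterion,
                "criterion_surface": {str(k): v for k, v in self.criterion_surface.items()},
                "folds": self.folds, "repeats": self.repeats, "seed": self.seed,
                "repair_log": list(self.repair_log)}


class RepairAborted(RuntimeError):
    """The near-zero-variance repair loop shrank a dataset below its floor."""

    def __init__(self, message: str, repair_log: list):
        super().__init__(message)
        self.repair_log = repair_log


# -------------------------------------------------------------------- folds

def stratified_folds(labels, folds: int, repeats: int = 1, seed: int = 0):
    """Seeded, class-balanced fold assignments.

    Per repeat, each class's samples are shuffled and dealt round-robin to
    the folds, so class proportions stay balanced. Returns an array of shape
    (repeats, n) of fold indices in [0, folds).
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    classes, counts = np.unique(labels.astype(str), return_counts=True)
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    if folds > counts.min():
        small = classes[np.argmin(counts)]
        raise ValidationError(
            f"folds={folds} exceeds the smallest class size "
            f"({small!r} has {counts.min()} samples)")
    rng = np.random.default_rng(seed)
    out = np.zeros((repeats, n), dtype=int)
    for r in range(repeats):
        for c in classes:
            idx = np.flatnonzero(labels.astype(str) == c)
            rng.shuffle(idx)
            for pos, i in enumerate(idx):
                out[r, i] = pos % folds
    return out


def plain_folds(n: int, folds: int, repeats: int = 1, seed: int = 0):
    """Seeded unstratified folds for label-free (pairwise) tuning."""
    if folds < 2 or folds > n:
        raise ValidationError(f"folds={folds} invalid for n={n}")
    rng = np.random.default_rng(seed)
    out = np.zeros((repeats, n), dtype=int)
    for r in range(repeats):
        idx = rng.permutation(n)
        for pos, i in enumerate(idx):
            out[r, i] = pos % folds
    return out


def ber(true, predicted) -> float:
    """Balanced error rate: mean over classes of the per-class error rate."""
    true = np.asarray(true, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(true) != len(predicted):
        raise ValidationError("length mismatch")
    rates = []
    true_classes = set(true.tolist())
    absent = sorted(set(predicted.tolist()) - true_classes)
    if absent:
        raise ValidationError(
            f"predicted class(es) {absent} have no members in the true "
            "labels; per-class error rates are undefined")
    for c in sorted(true_classes):
        mask = true == c
        rates.append(float((predicted[mask] != c).mean()))
    return float(np.mean(rates))


def uniqueness_percent(column) -> float:
    """100 x (number of distinct values) / n for one feature column."""
    x = np.asarray(column)
    if x.size == 0:
        raise ValidationError("empty column")
    return 100.0 * len(np.unique(x)) / x.size


def floor_tenth(x: float) -> float:
    """Largest multiple of 0.1 at or below `x` (0.87 -> 0.8)."""
    if not 0 <= x <= 1:
        raise ValidationError(f"expected a value in [0, 1], got {x}")
    return math.floor(round(x * 10, 9)) / 10


# ------------------------------------------------------- component selection

def select_ncomp_variance(model: LatentModel,
                          threshold: float = VARIANCE_THRESHOLD) -> int:
    """Smallest component count reaching `threshold` cumulative explained
    variance of a PCA fit (which stores its full variance spectrum)."""
    ev = np.asarray(model.explained_variance, dtype=float)
    cum = np.cumsum(ev)
    idx = np.flatnonzero(cum >= threshold - 1e-12)
    return int(idx[0]) + 1 if idx.size else len(ev)


def select_ncomp_q2(q2, threshold: float = Q2_THRESHOLD) -> int:
    """Last component with total Q² above `threshold`; 1 if none passes."""
    q2 = np.asarray(q2, dtype=float)
    if q2.size == 0:
        raise ValidationError("empty Q² list")
    passing = np.flatnonzero(q2 > threshold)
    return int(passing[-1]) + 1 if passing.size else 1


def q2_scores(X, Y, ncomp: int, folds: int = 5, repeats: int = 10,
              seed: int = 0, mode: str = "regression") -> np.ndarray:
    """Cross-validated total Q² per component of a dense PLS fit.

    For component h, the full-data model is deflated through h-1 components;
    each CV fold refits a single dense component on the training rows of the
    deflated matrices and predicts the held-out Y residuals from the X
    score. Q²_h = 1 - PRESS_h / RSS_{h-1}, pooled over all Y columns, then
    averaged over repeats.
    """
    Xm, _, _, xname = M._as_matrix(X, "X")
    Ym, _, _, yname = M._as_matrix(Y, "Y")
    n = Xm.shape[0]
    Xs, *_ = M.center_scale(Xm, block=xname)
    Ys, *_ = M.center_scale(Ym, block=yname)
    assign = plain_folds(n, folds, repeats, seed)
    Xh, Yh = Xs.copy(), Ys.copy()
    q2 = np.zeros((repeats, ncomp))
    for h in range(ncomp):
        rss = float((Yh ** 2).sum())
        if rss <= 0:
            q2[:, h:] = -np.inf
            break
        for r in range(repeats):
            press = 0.0
            for f in range(folds):
                te = assign[r] == f
                tr = ~te
                b = M._svd_right(Xh[tr].T @ Yh[tr])
                u = Yh[tr] @ b
                for _ in range(M.MAX_ITER):
                    a = M._unit(Xh[tr].T @ u)
                    t = Xh[tr] @ a
                    b_new = M._unit(Yh[tr].T @ t)
                    u = Yh[tr] @ b_new
                    if np.max(np.abs(b_new - np.sign(b_new @ b) * b)) < M.TOL:
                        b = b_new
                        break
                    b = b_new
                t_tr = Xh[tr] @ a
                tt = float(t_tr @ t_tr)
                if tt == 0:
                    raise TunableFailure("degenerate CV component in Q²",
                                         datasets=[xname, yname])
                d = Yh[tr].T @ t_tr / tt
                t_te = Xh[te] @ a
                press += float(((Yh[te] - np.outer(t_te, d)) ** 2).sum())
            q2[r, h] = 1.0 - press / rss
        # full-data deflation to the next component
        b = M._svd_right(Xh.T @ Yh)
        u = Yh @ b
        for _ in range(M.MAX_ITER):
            a = M._unit(Xh.T @ u)
            t = Xh @ a
            b_new = M._unit(Yh.T @ t)
            u = Yh @ b_new
            if np.max(np.abs(b_new - np.sign(b_new @ b) * b)) < M.TOL:
                b = b_new
                break
            b = b_new
        t = Xh @ a
        tt = float(t @ t)
        Xh = Xh - np.outer(t, Xh.T @ t / tt)
        if mode == "canonical":
            u = Yh @ b
            uu = float(u @ u)
            Yh = Yh - np.outer(u, Yh.T @ u / uu)
        else:
            Yh = Yh - np.outer(t, Yh.T @ t / tt)
    return q2.mean(axis=0)


# --------------------------------------------------------------- nzv repair

def nzv_repair(task, datasets: dict, min_features: int = 2):
    """Run `task(datasets)` under the near-zero-variance repair loop.

    On a :class:`TunableFailure`, the uniqueness percentage (distinct values
    / n) of every column of the implicated dataset(s) is computed; the
    dataset holding the global minimum loses *all* columns attaining that
    minimum and the task restarts. Aborts with :class:`RepairAborted` once
    any repaired dataset would drop below `min_features` columns.
    Non-tunable exceptions propagate unchanged.
    """
    datasets = dict(datasets)
    log: list = []
    iteration = 0
    while True:
        try:
            return task(datasets), log
        except TunableFailure as exc:
            iteration += 1
            implicated = [n for n in (exc.datasets or list(datasets))
                          if n in datasets]
            if not implicated:
                implicated = list(datasets)
            best_name, best_val = None, np.inf
            uniq_cache = {}
            for name in implicated:
                mat = datasets[name].matrix()
                uniq = np.array([uniqueness_percent(mat[:, j])
                                 for j in range(mat.shape[1])])
                uniq_cache[name] = uniq
                if uniq.min() < best_val:
                    best_val = float(uniq.min())
                    best_name = name
            ds = datasets[best_name]
            uniq = uniq_cache[best_name]
            drop = [ds.feature_ids[j] for j in np.flatnonzero(uniq == best_val)]
            log.append({"iteration": iteration, "dataset": best_name,
                        "removed_feature_ids": drop, "uniqueness_percent": best_val})
            remaining = ds.n_features - len(drop)
            if remaining < min_features:
                raise RepairAborted(
                    f"repair would leave dataset {best_name!r} with "
                    f"{remaining} < {min_features} features", log) from exc
            keep = [f for f in ds.feature_ids if f not in set(drop)]
            datasets[best_name] = ds.with_values(
                ds.values[keep], operation="nzv_repair",
                removed=len(drop), uniqueness_percent=best_val)


# ------------------------------------------------------------------- tuning

def _truncate_grid(grid, p: int) -> list:
    vals = sorted({int(g) for g in grid if 1 <= int(g) <= p})
    if not vals:
        vals = [min(p, 1)]
    return vals


def cv_ber_splsda(ds: OmicsDataset, labels, keeps, folds, repeats, seed,
                   distance: str) -> float:
    """Mean CV balanced error rate of an sPLS-DA at the given keep vector."""
    labels = np.asarray(labels, dtype=object)
    X = ds.matrix()
    assign = stratified_folds(labels, folds, repeats, seed)
    h = len(keeps)
    bers = []
    for r in range(repeats):
        pred = np.empty(len(labels), dtype=object)
        for f in range(folds):
            te = assign[r] == f
            tr = ~te
            model = fit_splsda(X[tr], labels[tr], ncomp=h, keep=list(keeps))
            pred[te] = M.predict_classes(model, X[te], distance=distance)
        bers.append(ber(labels, pred))
    return float(np.mean(bers))


def tune_splsda(ds: OmicsDataset, labels, ncomp_max: int,
                grid=DEFAULT_KEEP_GRID, folds: int | None = None,
                repeats: int = 10, seed: int = 0,
                distance: str = "centroids") -> TuneResult:
    """Sequential per-component keepX tuning of sPLS-DA by CV balanced
    error rate; the retained component count is the one whose cumulative
    model attains the lowest mean BER (ties: fewer components / smaller
    keep)."""
    labels = np.asarray(labels, dtype=object)
    folds = _default_folds(labels, folds)
    grid = _truncate_grid(grid, ds.n_features)
    keeps: list[int] = []
    surface: dict = {}
    best_per_ncomp = []
    for h in range(1, ncomp_max + 1):
        best_keep, best_ber = None, np.inf
        for g in grid:
            val = cv_ber_splsda(ds, labels, keeps + [g], folds, repeats, seed,
                                 distance)
            surface[(h, g)] = val
            if val < best_ber - 1e-12:
                best_keep, best_ber = g, val
        keeps.append(best_keep)
        best_per_ncomp.append(best_ber)
    selected_ncomp = int(np.argmin(np.round(best_per_ncomp, 12))) + 1
    return TuneResult(selected_ncomp=selected_ncomp,
                      selected_keep={ds.name: keeps},
                      criterion_surface=surface, criterion="ber",
                      folds=folds, repeats=repeats, seed=seed)


def _default_folds(labels, folds):
    if folds is not None:
        return folds
    _, counts = np.unique(np.asarray(labels, dtype=object).astype(str),
                          return_counts=True)
    return int(min(5, counts.min()))


def tune_spls_keep(X: OmicsDataset, Y: OmicsDataset, ncomp: int,
                   gridX=DEFAULT_KEEP_GRID, gridY=DEFAULT_KEEP_GRID,
                   folds: int = 5, repeats: int = 10, seed: int = 0,
                   mode: str = "regression") -> TuneResult:
    """Per-component (keepX, keepY) tuning of pairwise sPLS.

    Candidate pairs are scored by the correlation between CV-predicted
    held-out component scores and the scores of the full-data fit at the
    same keeps (mean of |cor| over the t and u sides and over repeats);
    the maximizing pair wins, ties going to smaller keeps.
    """
    Xm, Ym = X.matrix(), Y.matrix()
    n = Xm.shape[0]
    gridX = _truncate_grid(gridX, X.n_features)
    gridY = _truncate_grid(gridY, Y.n_features)
    assign = plain_folds(n, folds, repeats, seed)
    keepsX: list[int] = []
    keepsY: list[int] = []
    surface: dict = {}
    for h in range(1, ncomp + 1):
        best, best_val = None, -np.inf
        for gx, gy in itertools.product(gridX, gridY):
            kx, ky = keepsX + [gx], keepsY + [gy]
            full = fit_spls(X, Y, ncomp=h, keepX=kx, keepY=ky, mode=mode)
            xname = full.data_block_names[0]
            t_full = full.block(xname).scores[:, h - 1]
            u_full = full.block(full.y_block).scores[:, h - 1]
            vals = []
            for r in range(repeats):
                t_pred = np.zeros(n)
                u_pred = np.zeros(n)
                for f in range(folds):
                    te = assign[r] == f
                    tr = ~te
                    m = fit_spls(Xm[tr], Ym[tr], ncomp=h, keepX=kx, keepY=ky,
                                 mode=mode)
                    Tn, Un = M.transform_pair(m, Xm[te], Ym[te])
                    t_pred[te] = Tn[:, h - 1]
                    u_pred[te] = Un[:, h - 1]
                vals.append((abs(_safe_cor(t_pred, t_full))
                             + abs(_safe_cor(u_pred, u_full))) / 2)
            score = float(np.mean(vals))
            surface[(h, gx, gy)] = score
            if score > best_val + 1e-12:
                best, best_val = (gx, gy), score
        keepsX.append(best[0])
        keepsY.append(best[1])
    return TuneResult(selected_ncomp=ncomp,
                      selected_keep={X.name: keepsX, Y.name: keepsY},
                      criterion_surface=surface, criterion="score_correlation",
                      folds=folds, repeats=repeats, seed=seed)


def _safe_cor(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def tune_spca_keep(ds: OmicsDataset, ncomp: int, grid=DEFAULT_KEEP_GRID,
                   folds: int = 5, repeats: int = 10, seed: int = 0) -> TuneResult:
    """Per-component keep tuning for sPCA by the same CV score-correlation
    criterion as pairwise sPLS: held-out samples are projected with the
    training fit and correlated against the full-data component scores."""
    Xm = ds.matrix()
    n = Xm.shape[0]
    grid = _truncate_grid(grid, ds.n_features)
    assign = plain_folds(n, folds, repeats, seed)
    keeps: list[int] = []
    surface: dict = {}
    for h in range(1, ncomp + 1):
        best, best_val = None, -np.inf
        for g in grid:
            kv = keeps + [g]
            full = M.fit_spca(ds, ncomp=h, keep=kv)
            t_full = full.block(ds.name).scores[:, h - 1]
            vals = []
            for r in range(repeats):
                t_pred = np.zeros(n)
                for f in range(folds):
                    te = assign[r] == f
                    m = M.fit_spca(Xm[~te], ncomp=h, keep=kv)
                    blk = m.block(m.data_block_names[0])
                    Xr = (Xm[te] - blk.center) / blk.scale
                    for j in range(h):
                        t = Xr @ blk.weights[:, j]
                        if j == h - 1:
                            t_pred[te] = t
                        Xr = Xr - np.outer(t, blk.weights[:, j])
                vals.append(abs(_safe_cor(t_pred, t_full)))
            score = float(np.mean(vals))
            surface[(h, g)] = score
            if score > best_val + 1e-12:
                best, best_val = g, score
        keeps.append(best)
    return TuneResult(selected_ncomp=ncomp, selected_keep={ds.name: keeps},
                      criterion_surface=surface, criterion="score_correlation",
                      folds=folds, repeats=repeats, seed=seed)


# ------------------------------------------------------------------- design

def data_driven_design(blocks: dict, ncomp: int = 1, floor: bool = True
                       ) -> DesignMatrix:
    """Data-driven design matrix for the multiblock model.

    Every block pair is fitted with dense canonical-mode PLS (1 component)
    and the absolute score correlation |cor(t1, u1)| recorded; the minimum
    over pairs — optionally floored to the nearest tenth below — fills every
    off-diagonal cell.
    """
    names = list(blocks)
    if len(names) < 2:
        raise ValidationError("need at least two blocks for a design matrix")
    cors = {}
    for a, b in itertools.combinations(names, 2):
        m = fit_spls(blocks[a], blocks[b], ncomp=ncomp, mode="canonical")
        t = m.block(m.data_block_names[0]).scores[:, 0]
        u = m.block(m.y_block).scores[:, 0]
        cors[(a, b)] = abs(_safe_cor(t, u))
    raw = min(cors.values())
    value = floor_tenth(raw) if floor else raw
    B = len(names)
    return DesignMatrix(names, value * (np.ones((B, B)) - np.eye(B)),
                        raw_minimum=raw,
                        pairwise_correlations={f"{a}~{b}": v
                                               for (a, b), v in cors.items()})


# ------------------------------------------------------------------- DIABLO

def cv_ber_diablo(blocks: dict, labels, keeps: dict, ncomp, design,
                   folds, repeats, seed, distance: str = "centroids") -> float:
    labels = np.asarray(labels, dtype=object)
    mats = {n: b.matrix() for n, b in blocks.items()}
    assign = stratified_folds(labels, folds, repeats, seed)
    bers = []
    for r in range(repeats):
        pred = np.empty(len(labels), dtype=object)
        for f in range(folds):
            te = assign[r] == f
            tr = ~te
            model = fit_diablo({n: mats[n][tr] for n in blocks}, labels[tr],
                               ncomp=ncomp, design=design,
                               keep={n: keeps[n][:ncomp] for n in blocks})
            pred[te] = M.predict_classes(model, {n: mats[n][te] for n in blocks},
                                         distance=distance)
        bers.append(ber(labels, pred))
    return float(np.mean(bers))


def tune_diablo(blocks: dict, labels, ncomp_max: int, grids=None,
                folds: int | None = None, repeats: int = 10, seed: int = 0,
                design: DesignMatrix | None = None,
                distance: str = "centroids") -> TuneResult:
    """Two-stage tuning of the multiblock discriminant model.

    Stage 1 picks the component count: dense fits up to `ncomp_max` under
    CV, lowest overall centroids-distance BER wins (ties: fewer components).
    Stage 2 tunes per-block keep counts per component, blocks scanned
    sequentially with the others held at their current best, again by CV
    BER. Solver failures are repaired via :func:`nzv_repair` and the repair
    log is carried in the result.
    """
    labels = np.asarray(labels, dtype=object)
    folds = _default_folds(labels, folds)
    names = list(blocks)
    if design is None:
        design = data_driven_design(blocks)
    if grids is None:
        grids = {n: DEFAULT_KEEP_GRID for n in names}
    repair_log: list = []
    surface: dict = {}

    dense = {n: [blocks[n].n_features] * ncomp_max for n in names}

    def stage1(dss):
        per_ncomp = []
        for h in range(1, ncomp_max + 1):
            val = cv_ber_diablo(dss, labels, dense, h, design, folds, repeats,
                                 seed, distance)
            surface[("ncomp", h)] = val
            per_ncomp.append(val)
        return int(np.argmin(np.round(per_ncomp, 12))) + 1

    ncomp, log1 = nzv_repair(stage1, blocks)
    repair_log.extend(log1)

    def stage2(dss):
        keeps = {n: [dss[n].n_features] * ncomp for n in names}
        for h in range(ncomp):
            for n in names:
                best, best_ber = None, np.inf
                for g in _truncate_grid(grids[n], dss[n].n_features):
                    trial = {m: list(keeps[m]) for m in names}
                    trial[n][h] = g
                    val = cv_ber_diablo(dss, labels, trial, h + 1, design,
                                         folds, repeats, seed, distance)
                    surface[(h + 1, n, g)] = val
                    if val < best_ber - 1e-12:
                        best, best_ber = g, val
                keeps[n][h] = best
        return keeps

    keeps, log2 = nzv_repair(stage2, blocks)
    repair_log.extend(log2)
    return TuneResult(selected_ncomp=ncomp, selected_keep=keeps,
                      criterion_surface=surface, criterion="ber",
                      folds=folds, repeats=repeats, seed=seed,
                      repair_log=repair_log)


def reduce_dataset(ds: OmicsDataset, model: LatentModel,
                   tune: TuneResult | None = None,
                   block: str | None = None) -> OmicsDataset:
    """Restrict `ds` to the features with a nonzero loading on any retained
    component of the fitted sparse model; column order is preserved."""
    name = block or (ds.name if ds.name in model.blocks
                     else model.data_block_names[0])
    ncomp = tune.selected_ncomp if tune is not None else model.ncomp
    selected = model.block(name).selected_features(ncomp=ncomp)
    if not selected:
        raise ValidationError("no feature carries a nonzero loading")
    return ds.subset_features(selected, operation="reduce_dataset",
                              n_selected=len(selected), ncomp=ncomp)
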