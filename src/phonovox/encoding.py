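"""Banded (grouped) ridge voxelwise encoding models.

Each feature-space block b gets its own Tikhonov penalty lambda_b, and a
fixed temporal prior rescales the columns of each delay so that weights at
delays far from the hemodynamic peak are shrunk harder.  The whole model is
equivalent to ordinary ridge regression with unit penalty on the rescaled
design

    X~[:, c] = X[:, c] * prior.scale[delay(c)] / sqrt(lambda_block(c)),

solved in the primal when columns <= rows and in the dual (kernel) form
otherwise.  Cross-validation selects the per-voxel lambda vector on a
Cartesian grid, maximizing held-out R^2 over contiguous time folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special

from .preprocess import BoldRun, zscore_per_story
from .stimulus_features import DelayedDesign

# ---------------------------------------------------------------------------
# Temporal (HRF) prior
# ---------------------------------------------------------------------------


def double_gamma_hrf(t: np.ndarray, peak_shape: float = 6.0,
                     under_shape: float = 16.0, scale: float = 1.0,
                     under_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~5 s, undershoot ~15 s)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale

    def gamma_pdf(x, a):
        return np.exp((a - 1) * np.log(x) - x - special.gammaln(a))

    out[pos] = gamma_pdf(tp, peak_shape) - under_ratio * gamma_pdf(tp, under_shape)
    return out


@dataclass
class TemporalPrior:
    """Per-delay shrinkage scale applied as fixed column rescaling."""

    delays: tuple[float, ...]
    scale: np.ndarray

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=float)
        if len(self.scale) != len(self.delays):
            raise ValueError("one scale per delay required")
        if np.any(self.scale <= 0) or not np.all(np.isfinite(self.scale)):
            raise ValueError("prior scales must be positive and finite")


def hrf_prior(delays, kind: str = "hrf") -> TemporalPrior:
    """Temporal prior over the FIR delays.

    ``kind='hrf'`` sets the scale proportional to the canonical double-gamma
    HRF at each delay (normalized to max 1, floored at a small positive
    value); ``kind='identity'`` gives equal weight to all delays.
    """
    delays = tuple(float(d) for d in delays)
    if any(d < 0 for d in delays):
        raise ValueError("delays must be non-negative")
    if kind == "identity":
        return TemporalPrior(delays=delays, scale=np.ones(len(delays)))
    if kind != "hrf":
        raise ValueError(f"unknown prior kind {kind!r}")
    h = np.abs(double_gamma_hrf(np.asarray(delays)))
    peak = h.max()
    if peak <= 0:       # degenerate delays (e.g. all at 0): flat prior
        return TemporalPrior(delays=delays, scale=np.ones(len(delays)))
    h = np.maximum(h / peak, 1e-3)
    return TemporalPrior(delays=delays, scale=h)


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_MIN = 1e-1
DEFAULT_LAMBDA_MAX = 1e5
DEFAULT_GRID_SIZE = 10


def default_lambda_grid(n_values: int = DEFAULT_GRID_SIZE,
                        lo: float = DEFAULT_LAMBDA_MIN,
                        hi: float = DEFAULT_LAMBDA_MAX) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n_values)


@dataclass
class HyperGrid:
    """Per-block candidate lambda lists; the search grid is their product."""

    per_block: list[np.ndarray]

    def __post_init__(self):
        self.per_block = [np.sort(np.asarray(v, dtype=float))
                          for v in self.per_block]
        for v in self.per_block:
            if len(v) == 0:
                raise ValueError("empty lambda list for a block")
            if np.any(v <= 0):
                raise ValueError("lambdas must be positive")

    @classmethod
    def default(cls, n_blocks: int,
                n_values: int = DEFAULT_GRID_SIZE) -> "HyperGrid":
        return cls(per_block=[default_lambda_grid(n_values)
                              for _ in range(n_blocks)])

    def combos(self):
        """Ascending lexicographic iteration over lambda vectors."""
        return itertools.product(*self.per_block)

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.per_block]))


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------


@dataclass
class BandedModel:
    """Weights of a banded ridge fit.

    ``col_mean``/``col_scale`` record the training-set standardization of
    the design columns (regressors are z-scored before fitting, matching
    the z-scored BOLD targets); weights act on the standardized columns.
    """

    weights: np.ndarray               # (n_features, n_voxels)
    lambdas: np.ndarray               # (n_voxels, n_blocks)
    prior: TemporalPrior
    block_names: tuple[str, ...]
    delays: tuple[float, ...]
    col_mean: np.ndarray | None = None
    col_scale: np.ndarray | None = None

    def predict(self, design: DelayedDesign) -> np.ndarray:
        if design.block_names != self.block_names:
            raise ValueError(
                f"design blocks {design.block_names} do not match the "
                f"model's {self.block_names}")
        if design.n_features != self.weights.shape[0]:
            raise ValueError("design column count does not match weights")
        X = design.values
        if self.col_mean is not None:
            X = (X - self.col_mean) / self.col_scale
        return X @ self.weights

    def save(self, path) -> None:
        n = self.weights.shape[0]
        np.savez_compressed(
            path, weights=self.weights, lambdas=self.lambdas,
            prior_scale=self.prior.scale,
            delays=np.asarray(self.delays),
            block_names=np.asarray(self.block_names),
            col_mean=(self.col_mean if self.col_mean is not None
                      else np.zeros(n)),
            col_scale=(self.col_scale if self.col_scale is not None
                       else np.ones(n)))

    @classmethod
    def load(cls, path) -> "BandedModel":
        with np.load(path, allow_pickle=False) as z:
            delays = tuple(float(d) for d in z["delays"])
            return cls(
                weights=z["weights"], lambdas=z["lambdas"],
                prior=TemporalPrior(delays=delays, scale=z["prior_scale"]),
                block_names=tuple(str(n) for n in z["block_names"]),
                delays=delays, col_mean=z["col_mean"],
                col_scale=z["col_scale"])


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray]:
    """Z-score design columns; constant columns become zeros (scale 1).

    Scales are floored relative to the largest column scale: a sparse
    indicator column whose events sit just outside the scored rows can
    have a vanishing-but-nonzero std, and dividing by it would blow up
    out-of-sample values by orders of magnitude.
    """
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    top = scale.max() if scale.size else 1.0
    floor = max(1e-6 * top, 1e-300)
    scale = np.where(scale < floor, 1.0, scale)
    return (X - mean) / scale, mean, scale


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def _column_scales(design: DelayedDesign, lambdas: np.ndarray,
                   prior: TemporalPrior) -> np.ndarray:
    """Per-column rescaling prior.scale[delay] / sqrt(lambda_block)."""
    lam = np.asarray(lambdas, dtype=float)
    return prior.scale[design.col_delay] / np.sqrt(lam[design.col_block])


def _solve_unit_ridge(Xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Weights of ridge with unit penalty on a pre-scaled design.

    Uses the primal normal equations when columns <= rows and the dual
    (kernel) solution otherwise; both give identical predictions.
    """
    n, p = Xs.shape
    if p <= n:
        A = Xs.T @ Xs
        A[np.diag_indices_from(A)] += 1.0
        return linalg.solve(A, Xs.T @ Y, assume_a="pos")
    K = Xs @ Xs.T
    K[np.diag_indices_from(K)] += 1.0
    alpha = linalg.solve(K, Y, assume_a="pos")
    return Xs.T @ alpha


def fit_banded(design: DelayedDesign, Y, lambdas,
               prior: TemporalPrior | None = None,
               standardize: bool = True) -> BandedModel:
    """Fit the banded ridge model with fixed per-block penalties.

    ``lambdas`` is one lambda per block, a dict keyed by block name, or a
    (n_voxels, n_blocks) array for voxel-specific penalties (voxels sharing
    a lambda vector are solved together).  By default the design columns
    are z-scored on the training data (like the BOLD targets) before the
    penalty scaling; ``standardize=False`` fits the raw columns, which is
    the textbook-ridge reduction.
    """
    Yv = Y.values if isinstance(Y, BoldRun) else np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    if Yv.shape[0] != design.n_timepoints:
        raise ValueError("design rows and BOLD rows differ")
    if not np.all(np.isfinite(design.values)) or not np.all(np.isfinite(Yv)):
        raise ValueError("non-finite inputs")
    n_blocks = len(design.block_names)
    if prior is None:
        prior = hrf_prior(design.delays) if design.delays else TemporalPrior(
            delays=design.delays, scale=np.ones(0))
    if isinstance(lambdas, dict):
        lambdas = np.array([lambdas[n] for n in design.block_names])
    lam = np.asarray(lambdas, dtype=float)
    nv = Yv.shape[1]
    if lam.ndim == 1:
        lam = np.broadcast_to(lam, (nv, n_blocks)).copy()
    if lam.shape != (nv, n_blocks):
        raise ValueError(f"lambdas shape {lam.shape} != ({nv}, {n_blocks})")
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("lambdas must be positive and finite")

    if standardize:
        X, col_mean, col_scale = _standardize_columns(design.values)
    else:
        X, col_mean, col_scale = design.values, None, None

    weights = np.zeros((design.n_features, nv))
    uniq, inverse = np.unique(lam, axis=0, return_inverse=True)
    inverse = np.ravel(inverse)
    for g, lam_vec in enumerate(uniq):
        cols = np.flatnonzero(inverse == g)
        s = _column_scales(design, lam_vec, prior)
        w_tilde = _solve_unit_ridge(X * s, Yv[:, cols])
        weights[:, cols] = s[:, None] * w_tilde
    return BandedModel(weights=weights, lambdas=lam, prior=prior,
                       block_names=design.block_names, delays=design.delays,
                       col_mean=col_mean, col_scale=col_scale)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def r2_columns(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Column-wise coefficient of determination 1 - SSE/SST.

    SST uses the scored rows' own variance, so a constant prediction at the
    mean scores exactly 0.  Constant targets score 0 by convention.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between targets and predictions")
    resid = y_true - y_pred
    sse = np.einsum("ij,ij->j", resid, resid)
    centered = y_true - y_true.mean(axis=0)
    sst = np.einsum("ij,ij->j", centered, centered)
    out = np.zeros(y_true.shape[1])
    ok = sst > 0
    out[ok] = 1.0 - sse[ok] / sst[ok]
    return out


def score_validation(model: BandedModel, design_val: DelayedDesign,
                     Y_val) -> np.ndarray:
    """Held-out R^2 between model predictions and observed responses."""
    Yv = Y_val.values if isinstance(Y_val, BoldRun) else np.asarray(Y_val)
    return r2_columns(Yv, model.predict(design_val))


def residualize(Y: BoldRun, baseline_model: BandedModel,
                baseline_design: DelayedDesign) -> BoldRun:
    """Z-score the run and subtract the baseline model's prediction."""
    z = zscore_per_story([Y])[0]
    pred = baseline_model.predict(baseline_design)
    if pred.shape != z.values.shape:
        raise ValueError("baseline prediction shape does not match the run")
    return BoldRun(values=z.values - pred, tr=Y.tr, story_id=Y.story_id)


# ---------------------------------------------------------------------------
# Cross-validated hyperparameter search
# ---------------------------------------------------------------------------


def contiguous_folds(nt: int, folds: int) -> list[np.ndarray]:
    """Contiguous-in-time validation folds (respects BOLD autocorrelation)."""
    if nt < folds:
        raise ValueError(f"{nt} timepoints cannot make {folds} folds")
    bounds = np.linspace(0, nt, folds + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def cv_search(design: DelayedDesign, Y, grid: HyperGrid | None = None,
              folds: int = 10, prior: TemporalPrior | None = None):
    """Select per-voxel lambda vectors by contiguous-fold cross-validation.

    Returns ``(best_lambdas, cv_scores)`` where ``best_lambdas`` is
    (n_voxels, n_blocks) and ``cv_scores`` the per-voxel mean held-out R^2
    at the selected grid point.  Exact ties go to the lexicographically
    larger lambda vector (more shrinkage).

    The search runs in the dual: per fold, the per-block kernels
    ``K_b = X_b S_b^2 X_b^T`` are precomputed once, and each grid point only
    re-solves ``(sum_b K_b / lambda_b + I) alpha = y``.
    """
    Yv = Y.values if isinstance(Y, BoldRun) else np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n_blocks = len(design.block_names)
    if n_blocks == 0:
        raise ValueError("design has no blocks")
    if grid is None:
        grid = HyperGrid.default(n_blocks)
    if len(grid.per_block) != n_blocks:
        raise ValueError("grid must list lambdas for every block")
    if prior is None:
        prior = hrf_prior(design.delays)

    nt, nv = Yv.shape
    fold_idx = contiguous_folds(nt, folds)
    # standardize on the whole design (stimulus statistics only — no target
    # information): per-fold statistics explode for sparse indicator
    # columns whose few events happen to fall in the held-out rows
    Xs, _, _ = _standardize_columns(design.values)
    Xs = Xs * prior.scale[design.col_delay]

    fold_data = []
    for te in fold_idx:
        tr_mask = np.ones(nt, dtype=bool)
        tr_mask[te] = False
        tr = np.flatnonzero(tr_mask)
        K_blocks, M_blocks = [], []
        for b in range(n_blocks):
            cols = np.flatnonzero(design.col_block == b)
            Xtr = Xs[np.ix_(tr, cols)]
            K_blocks.append(Xtr @ Xtr.T)
            M_blocks.append(Xs[np.ix_(te, cols)] @ Xtr.T)
        fold_data.append((tr, te, K_blocks, M_blocks))

    n_combos = grid.size
    mean_r2 = np.zeros((n_combos, nv))
    for ci, lam in enumerate(grid.combos()):
        lam = np.asarray(lam)
        for tr, te, K_blocks, M_blocks in fold_data:
            K = sum(Kb / lb for Kb, lb in zip(K_blocks, lam))
            K[np.diag_indices_from(K)] += 1.0
            alpha = linalg.solve(K, Yv[tr], assume_a="pos")
            pred = sum(Mb / lb for Mb, lb in zip(M_blocks, lam)) @ alpha
            mean_r2[ci] += r2_columns(Yv[te], pred)
    mean_r2 /= len(fold_data)

    combo_list = np.array(list(grid.combos()))
    # ascending lexicographic order; >= keeps the later (larger) combo on ties
    best_idx = np.zeros(nv, dtype=int)
    best_score = mean_r2[0].copy()
    for ci in range(1, n_combos):
        better = mean_r2[ci] >= best_score
        best_idx[better] = ci
        best_score[better] = mean_r2[ci][better]
    return combo_list[best_idx], best_score


# ---------------------------------------------------------------------------
# Single-block fast path (shared eigendecomposition over lambdas and voxels)
# ---------------------------------------------------------------------------


def _eig_ridge_predictions(X_tr: np.ndarray, Y_tr: np.ndarray,
                           X_te: np.ndarray,
                           lambdas: np.ndarray) -> np.ndarray:
    """Test-set ridge predictions for every lambda, via one eigendecomposition.

    Returns an array of shape (n_lambdas, n_test, n_voxels).  Chooses the
    primal or dual eigenbasis according to the smaller of rows/columns.
    """
    n, p = X_tr.shape
    lambdas = np.asarray(lambdas, dtype=float)
    if p <= n:
        G = X_tr.T @ X_tr
        evals, V = linalg.eigh(G)
        B = V.T @ (X_tr.T @ Y_tr)          # (p, nv)
        XteV = X_te @ V                     # (n_te, p)
        preds = np.empty((len(lambdas), X_te.shape[0], Y_tr.shape[1]))
        for i, lam in enumerate(lambdas):
            preds[i] = XteV @ (B / (evals[:, None] + lam))
        return preds
    K = X_tr @ X_tr.T
    evals, Q = linalg.eigh(K)
    B = Q.T @ Y_tr                          # (n, nv)
    M = X_te @ X_tr.T                       # (n_te, n)
    MQ = M @ Q
    preds = np.empty((len(lambdas), X_te.shape[0], Y_tr.shape[1]))
    for i, lam in enumerate(lambdas):
        preds[i] = MQ @ (B / (evals[:, None] + lam))
    return preds


def _eig_ridge_weights(X_tr: np.ndarray, Y_tr: np.ndarray,
                       lambdas: np.ndarray) -> np.ndarray:
    """Ridge weights for every lambda via one eigendecomposition.

    Returns (n_lambdas, p, n_voxels); weights act on the given (already
    scaled) design.
    """
    n, p = X_tr.shape
    lambdas = np.asarray(lambdas, dtype=float)
    out = np.empty((len(lambdas), p, Y_tr.shape[1]))
    if p <= n:
        evals, V = linalg.eigh(X_tr.T @ X_tr)
        B = V.T @ (X_tr.T @ Y_tr)
        for i, lam in enumerate(lambdas):
            out[i] = V @ (B / (evals[:, None] + lam))
        return out
    evals, Q = linalg.eigh(X_tr @ X_tr.T)
    B = Q.T @ Y_tr
    for i, lam in enumerate(lambdas):
        out[i] = X_tr.T @ (Q @ (B / (evals[:, None] + lam)))
    return out


def single_block_cv_fit(design: DelayedDesign, Y_train,
                        design_val: DelayedDesign, Y_val=None,
                        lambdas: np.ndarray | None = None,
                        folds: int = 10,
                        prior: TemporalPrior | None = None,
                        return_weights: bool = False,
                        standardize: bool = True):
    """CV lambda selection, refit, and validation prediction for one block.

    Shares each fold's eigendecomposition across all candidate lambdas and
    all voxels, which makes large simulation sweeps tractable.  Returns
    ``(best_lambda per voxel, val_pred, val_r2 or None)`` and, with
    ``return_weights``, appends the refit weights (n_features, n_voxels)
    in original design coordinates.
    """
    if len(design.block_names) != 1:
        raise ValueError("single_block_cv_fit requires exactly one block")
    Ytr = Y_train.values if isinstance(Y_train, BoldRun) else np.asarray(Y_train)
    if Ytr.ndim == 1:
        Ytr = Ytr[:, None]
    if lambdas is None:
        lambdas = default_lambda_grid()
    if prior is None:
        prior = hrf_prior(design.delays)
    pscale = prior.scale[design.col_delay]

    nt, nv = Ytr.shape
    if standardize:
        # column statistics come from the whole training design (stimulus
        # statistics only), which keeps sparse indicator columns stable
        # across the inner folds; callers whose validation rows come from
        # the same stream should standardize the full design once and
        # pass standardize=False
        Xp, col_mean, col_scale = _standardize_columns(design.values)
        Xp = Xp * pscale
        Xp_val = ((design_val.values - col_mean) / col_scale) * pscale
    else:
        Xp = design.values * pscale
        Xp_val = design_val.values * pscale

    cv_r2 = np.zeros((len(lambdas), nv))
    for te in contiguous_folds(nt, folds):
        tr_mask = np.ones(nt, dtype=bool)
        tr_mask[te] = False
        preds = _eig_ridge_predictions(Xp[tr_mask], Ytr[tr_mask], Xp[te],
                                       lambdas)
        for i in range(len(lambdas)):
            cv_r2[i] += r2_columns(Ytr[te], preds[i])
    cv_r2 /= folds

    best = np.zeros(nv, dtype=int)
    best_score = cv_r2[0].copy()
    for i in range(1, len(lambdas)):   # ascending; ties -> larger lambda
        hit = cv_r2[i] >= best_score
        best[hit] = i
        best_score[hit] = cv_r2[i][hit]

    all_preds = _eig_ridge_predictions(Xp, Ytr, Xp_val, lambdas)
    val_pred = np.empty((Xp_val.shape[0], nv))
    for i in range(len(lambdas)):
        sel = best == i
        if np.any(sel):
            val_pred[:, sel] = all_preds[i][:, sel]
    best_lambda = np.asarray(lambdas)[best]
    if Y_val is None:
        val_r2 = None
    else:
        Yva = Y_val.values if isinstance(Y_val, BoldRun) else np.asarray(Y_val)
        if Yva.ndim == 1:
            Yva = Yva[:, None]
        val_r2 = r2_columns(Yva, val_pred)
    if not return_weights:
        return best_lambda, val_pred, val_r2
    w_all = _eig_ridge_weights(Xp, Ytr, lambdas)
    weights = np.empty((design.n_features, nv))
    for i in range(len(lambdas)):
        sel = best == i
        if np.any(sel):
            weights[:, sel] = w_all[i][:, sel]
    # weights act on the z-scored design columns
    weights *= pscale[:, None]
    return best_lambda, val_pred, val_r2, weights


def nested_single_block_r2(design: DelayedDesign, Y,
                           lambdas: np.ndarray | None = None,
                           outer_folds: int = 5, inner_folds: int = 5,
                           prior: TemporalPrior | None = None) -> np.ndarray:
    """Nested-CV held-out R^2 for a single-block model.

    Every contiguous outer fold is predicted by a model whose lambda was
    selected by inner cross-validation on the remaining rows, so the
    reported R^2 (computed once over the reassembled out-of-fold
    predictions) carries no hyperparameter-selection optimism.
    """
    Yv = Y.values if isinstance(Y, BoldRun) else np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    nt = Yv.shape[0]
    # standardize over the whole stream once (stimulus statistics only);
    # per-split statistics destabilize sparse indicator columns
    Xs, _, _ = _standardize_columns(design.values)
    design = DelayedDesign(values=Xs, delays=design.delays,
                           block_names=design.block_names,
                           block_slices=design.block_slices,
                           col_block=design.col_block,
                           col_delay=design.col_delay, tr=design.tr)
    pred = np.empty_like(Yv)
    for te in contiguous_folds(nt, outer_folds):
        tr_mask = np.ones(nt, dtype=bool)
        tr_mask[te] = False
        d_tr = _row_subset(design, tr_mask)
        d_te = _row_subset(design, te)
        _, p, _ = single_block_cv_fit(d_tr, Yv[tr_mask], d_te, None,
                                      lambdas=lambdas, folds=inner_folds,
                                      prior=prior, standardize=False)
        pred[te] = p
    return r2_columns(Yv, pred)


def _row_subset(design: DelayedDesign, rows) -> DelayedDesign:
    return DelayedDesign(values=design.values[rows], delays=design.delays,
                         block_names=design.block_names,
                         block_slices=design.block_slices,
                         col_block=design.col_block,
                         col_delay=design.col_delay, tr=design.tr)
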