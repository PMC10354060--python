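"""Statistical inference for voxelwise model comparisons.

Significance of held-out prediction performance is assessed with a
permutation test that preserves each feature space's autocorrelation
(block-wise circular time shifts), corrected with Benjamini-Hochberg FDR.
Group-level effect sizes use a balanced random-intercept decomposition
(subject as the random factor) and the d-prime / logit algebra defined on
its components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .encoding import (BandedModel, TemporalPrior, fit_banded,
                       score_validation)
from .preprocess import BoldRun
from .stimulus_features import DelayedDesign

# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Observed scores, their null samples and the resulting p-values."""

    observed: np.ndarray          # (n_voxels,)
    null: np.ndarray              # (n_perm, n_voxels)
    pvalues: np.ndarray
    scheme: str
    seed: int


def _shift_blocks(design: DelayedDesign, rng: np.random.Generator,
                  scheme: str, min_shift: int) -> DelayedDesign:
    """Independently permute the rows of each feature-space block."""
    values = design.values.copy()
    nt = design.n_timepoints
    for name in design.block_names:
        sl = design.block_slices[name]
        if scheme == "circular":
            hi = nt - min_shift
            if hi <= min_shift:
                raise ValueError(
                    f"{nt} rows too short for circular shifts of at least "
                    f"{min_shift}")
            off = int(rng.integers(min_shift, hi + 1))
            values[:, sl] = np.roll(design.values[:, sl], off, axis=0)
        elif scheme == "iid":
            perm = rng.permutation(nt)
            values[:, sl] = design.values[perm, sl]
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
    return DelayedDesign(values=values, delays=design.delays,
                         block_names=design.block_names,
                         block_slices=design.block_slices,
                         col_block=design.col_block,
                         col_delay=design.col_delay, tr=design.tr)


def permutation_pvalues(design_train: DelayedDesign, Y_train,
                        design_val: DelayedDesign, Y_val,
                        lambdas: np.ndarray, n_perm: int = 1000,
                        seed: int = 0, scheme: str = "circular",
                        min_shift: int = 20,
                        prior: TemporalPrior | None = None
                        ) -> PermutationNull:
    """Permutation p-values for held-out R^2 at fixed hyperparameters.

    Each permutation applies an independent circular time shift (default;
    at least ``min_shift`` TRs, preserving within-block autocorrelation) or
    an i.i.d. row shuffle to every feature-space block of the training and
    validation designs, refits with the real fit's lambdas, and scores the
    validation set.  p-values use the add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    model = fit_banded(design_train, Y_train, lambdas, prior=prior)
    observed = score_validation(model, design_val, Y_val)

    null = np.empty((n_perm, observed.shape[0]))
    for i in range(n_perm):
        d_tr = _shift_blocks(design_train, rng, scheme, min_shift)
        d_va = _shift_blocks(design_val, rng, scheme,
                             min(min_shift, max(design_val.n_timepoints // 4,
                                                1)))
        m = fit_banded(d_tr, Y_train, lambdas, prior=prior)
        null[i] = score_validation(m, d_va, Y_val)
    pvalues = (1.0 + np.sum(null >= observed[None, :], axis=0)) / (n_perm + 1.0)
    return PermutationNull(observed=observed, null=null, pvalues=pvalues,
                           scheme=scheme, seed=seed)


def fdr_bh(pvalues: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# Random-intercept aggregation (balanced closed form)
# ---------------------------------------------------------------------------


@dataclass
class RandomInterceptFit:
    """Closed-form variance components of a subject random-intercept model."""

    condition_means: dict
    sigma_sub: float
    se_condition_means: dict
    sigma_within: float
    n_groups: int


def random_intercept_components(values: np.ndarray, groups: np.ndarray,
                                conditions: np.ndarray | None = None
                                ) -> RandomInterceptFit:
    """Method-of-moments estimates for a subject random-intercept model.

    With one condition this is the balanced one-way random-effects
    decomposition: ``sigma_sub^2 = (MSB - MSW) / n0`` (floored at 0), where
    n0 is the effective per-group size.  With a ``conditions`` label per
    observation, per-(group, condition) cell means enter a balanced two-way
    decomposition whose subject main effect gives sigma_sub and whose
    residual gives the standard errors of condition means and differences.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ug = np.unique(groups)
    if len(ug) < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    if conditions is None:
        gm = np.array([values[groups == g].mean() for g in ug])
        ns = np.array([np.sum(groups == g) for g in ug])
        N, G = len(values), len(ug)
        grand = gm.mean()
        msb = float(np.sum(ns * (np.array([values[groups == g].mean()
                                           for g in ug]) -
                                 values.mean()) ** 2) / (G - 1))
        ssw = sum(float(np.sum((values[groups == g] -
                                values[groups == g].mean()) ** 2))
                  for g in ug)
        msw = ssw / max(N - G, 1)
        n0 = (N - np.sum(ns ** 2) / N) / (G - 1)
        var_sub = max((msb - msw) / n0, 0.0)
        se_mean = float(np.sqrt(msb / (G * n0)))
        return RandomInterceptFit(
            condition_means={"all": float(grand)},
            sigma_sub=float(np.sqrt(var_sub)),
            se_condition_means={"all": se_mean},
            sigma_within=float(np.sqrt(msw)), n_groups=G)

    conditions = np.asarray(conditions)
    uc = np.unique(conditions)
    C, G = len(uc), len(ug)
    if C < 2:
        raise ValueError("conditions must have at least 2 levels")
    cell = np.full((G, C), np.nan)
    for i, g in enumerate(ug):
        for j, c in enumerate(uc):
            sel = (groups == g) & (conditions == c)
            if not np.any(sel):
                raise ValueError(f"empty cell (group {g!r}, condition {c!r})")
            cell[i, j] = values[sel].mean()
    subj_means = cell.mean(axis=1)
    cond_means = cell.mean(axis=0)
    grand = cell.mean()
    resid = cell - subj_means[:, None] - cond_means[None, :] + grand
    ms_err = float(np.sum(resid ** 2) / ((G - 1) * (C - 1)))
    var_subj_means = float(np.sum((subj_means - grand) ** 2) / (G - 1))
    var_sub = max(var_subj_means - ms_err / C, 0.0)
    se_cond = float(np.sqrt(ms_err / G))
    return RandomInterceptFit(
        condition_means={c: float(m) for c, m in zip(uc, cond_means)},
        sigma_sub=float(np.sqrt(var_sub)),
        se_condition_means={c: se_cond for c in uc},
        sigma_within=float(np.sqrt(ms_err)), n_groups=G)


def se_condition_difference(fit: RandomInterceptFit) -> float:
    """Standard error of a difference of two condition means (paired design)."""
    return float(np.sqrt(2.0) * fit.sigma_within / np.sqrt(fit.n_groups))


# ---------------------------------------------------------------------------
# Effect-size algebra
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-12


def dprime(mu_a: float, mu_b: float, sigma_sub: float) -> float:
    """Standardized mean difference (mu_a - mu_b) / sigma_sub."""
    if sigma_sub <= 0:
        raise ValueError("sigma_sub must be positive")
    return (mu_a - mu_b) / max(sigma_sub, _SIGMA_FLOOR)


def se_dprime(se_diff: float, sigma_sub: float) -> float:
    """Standard error of d-prime from the SE of the mean difference."""
    if sigma_sub <= 0:
        raise ValueError("sigma_sub must be positive")
    return se_diff / max(sigma_sub, _SIGMA_FLOOR)


def dprime_phn(d_di_tri: float, d_sin_di: float) -> float:
    """Average diphone-dominance d-prime, correcting the sign inversion."""
    return (d_di_tri - d_sin_di) / 2.0


def se_dprime_phn(se_di_tri: float, se_sin_di: float) -> float:
    return float(np.sqrt(se_di_tri ** 2 + se_sin_di ** 2) / 2.0)


def label_logit(p_s: float, p_reference: float | None = None) -> float:
    """Log-odds of a voxel label.

    Two-way form ``log(p_s / (1 - p_s))``; with a reference probability the
    multinomial form ``-log(p_s / p_ref)`` (negative logits relative to the
    reference label).
    """
    if not 0.0 < p_s < 1.0:
        raise ValueError("p_s must be strictly inside (0, 1)")
    if p_reference is None:
        return float(np.log(p_s / (1.0 - p_s)))
    if p_reference <= 0:
        raise ValueError("reference probability must be positive")
    return float(-np.log(p_s / p_reference))


# ---------------------------------------------------------------------------
# Winner-take-all labeling
# ---------------------------------------------------------------------------


@dataclass
class LabelTable:
    """Per-voxel winning feature space among significant voxels."""

    labels: np.ndarray            # object array, None where not significant
    counts: dict
    order: tuple[str, ...]


def winner_take_all(partition_values: dict[str, np.ndarray],
                    mask: np.ndarray,
                    order: tuple[str, ...] = ("phoneme", "diphone",
                                              "triphone")) -> LabelTable:
    """Label each significant voxel with its best feature space.

    The winner is the argmax of the provided per-voxel values (typically
    unique partitions); exact ties are broken toward the earliest name in
    ``order``.  Non-significant voxels stay unlabeled.
    """
    names = [n for n in order if n in partition_values]
    names += [n for n in partition_values if n not in names]
    stacked = np.stack([np.asarray(partition_values[n], dtype=float)
                        for n in names])
    mask = np.asarray(mask, dtype=bool)
    if stacked.shape[1] != mask.shape[0]:
        raise ValueError("partition values and mask are misaligned")
    best = np.argmax(stacked, axis=0)   # first occurrence wins ties
    labels = np.array([None] * mask.shape[0], dtype=object)
    labels[mask] = np.asarray(names, dtype=object)[best[mask]]
    counts = {n: int(np.sum(labels == n)) for n in names}
    return LabelTable(labels=labels, counts=counts, order=tuple(names))
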