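"""Variance partitioning across feature spaces.

The unique and shared variance explained by up to three feature spaces is
obtained by inclusion-exclusion over nested banded-ridge fits that reuse the
joint model's per-block shrinkage, so every sub-model sees the same
effective feature subspace.  A separate analysis splits the diphone block's
prediction into the contributions of three word-relative diphone categories
(short words, word beginnings, residues).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .encoding import (BandedModel, TemporalPrior, fit_banded, r2_columns,
                       score_validation)
from .preprocess import BoldRun
from .stimulus_features import (DelayedDesign, NGramInventory,
                                ROLE_RESIDUE, ROLE_WHOLE_WORD,
                                ROLE_WORD_BEGINNING, StimulusAnnotation,
                                event_indicator_features, extract_ngrams,
                                stack_delays)

# diphone categories (word-relative roles of the token)
CAT_SHORT_WORD = "short_word"
CAT_WORD_BEGINNING = "word_beginning"
CAT_RESIDUE = "residue"
CATEGORIES = (CAT_SHORT_WORD, CAT_WORD_BEGINNING, CAT_RESIDUE)

_ROLE_TO_CAT = {
    ROLE_WHOLE_WORD: CAT_SHORT_WORD,
    ROLE_WORD_BEGINNING: CAT_WORD_BEGINNING,
    ROLE_RESIDUE: CAT_RESIDUE,
}


# ---------------------------------------------------------------------------
# Nested model scores
# ---------------------------------------------------------------------------


def _as_values(Y):
    v = Y.values if isinstance(Y, BoldRun) else np.asarray(Y, dtype=float)
    return v[:, None] if v.ndim == 1 else v


def all_nonempty_subsets(names) -> list[tuple[str, ...]]:
    names = tuple(names)
    out = []
    for r in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, r))
    return out


def nested_scores(design_train: DelayedDesign, Y_train,
                  design_val: DelayedDesign, Y_val,
                  lambdas: np.ndarray, subsets=None,
                  prior: TemporalPrior | None = None
                  ) -> dict[tuple[str, ...], np.ndarray]:
    """Validation R^2 of every nested sub-model at the joint model's lambdas.

    ``lambdas`` is the (n_voxels, n_blocks) selection from the joint fit
    (or one lambda per block); each subset model is refit using the joint
    lambdas of its blocks only.  The empty subset scores the zero predictor.
    """
    names = design_train.block_names
    if subsets is None:
        subsets = all_nonempty_subsets(names)
    lam = np.asarray(lambdas, dtype=float)
    Ytr, Yva = _as_values(Y_train), _as_values(Y_val)
    if lam.ndim == 1:
        lam = np.broadcast_to(lam, (Ytr.shape[1], len(names))).copy()

    scores: dict[tuple[str, ...], np.ndarray] = {}
    for subset in subsets:
        subset = tuple(subset)
        unknown = set(subset) - set(names)
        if unknown:
            raise KeyError(f"unknown block(s) in subset: {sorted(unknown)}")
        key = tuple(n for n in names if n in subset)
        if not key:
            scores[()] = r2_columns(Yva, np.zeros_like(Yva))
            continue
        cols = [names.index(n) for n in key]
        model = fit_banded(design_train.subset(key), Ytr, lam[:, cols],
                           prior=prior)
        scores[key] = score_validation(model, design_val.subset(key), Yva)
    return scores


# ---------------------------------------------------------------------------
# Inclusion-exclusion partitioning
# ---------------------------------------------------------------------------


@dataclass
class PartitionTable:
    """Per-voxel variance partitions over 2 or 3 feature sets."""

    set_names: tuple[str, ...]
    raw: dict[tuple[str, ...], np.ndarray]
    full_r2: np.ndarray
    corrected: dict[tuple[str, ...], np.ndarray] | None = None
    clipped_magnitude: np.ndarray | None = None

    def partition_sum(self) -> np.ndarray:
        return np.sum(list(self.raw.values()), axis=0)


def variance_partition(scores: dict[tuple[str, ...], np.ndarray]
                       ) -> PartitionTable:
    """Decompose the full model's R^2 into unique and shared partitions.

    For three sets A, B, C the seven partitions follow commonality analysis:
    ``unique(A) = R(ABC) - R(BC)``,
    ``shared(AB) = R(AC) + R(BC) - R(C) - R(ABC)``, and the triple-shared
    term from the full inclusion-exclusion identity; they sum to R(ABC)
    exactly.  Two-set input yields the three analogous partitions.
    """
    keys = [k for k in scores if k]
    names = tuple(sorted(set().union(*keys)))
    n = len(names)
    if n not in (2, 3):
        raise ValueError(f"partitioning supports 2 or 3 sets, got {n}")

    def sc(subset):
        key = tuple(x for x in names if x in subset)
        # scores may be keyed in a block order differing from sorted order
        for k, v in scores.items():
            if set(k) == set(key):
                return np.asarray(v, dtype=float)
        raise KeyError(f"missing score for subset {key}")

    parts: dict[tuple[str, ...], np.ndarray] = {}
    if n == 2:
        a, b = names
        full = sc((a, b))
        parts[(a,)] = full - sc((b,))
        parts[(b,)] = full - sc((a,))
        parts[(a, b)] = sc((a,)) + sc((b,)) - full
    else:
        a, b, c = names
        full = sc((a, b, c))
        parts[(a,)] = full - sc((b, c))
        parts[(b,)] = full - sc((a, c))
        parts[(c,)] = full - sc((a, b))
        parts[(a, b)] = sc((a, c)) + sc((b, c)) - sc((c,)) - full
        parts[(a, c)] = sc((a, b)) + sc((b, c)) - sc((b,)) - full
        parts[(b, c)] = sc((a, b)) + sc((a, c)) - sc((a,)) - full
        parts[(a, b, c)] = (sc((a,)) + sc((b,)) + sc((c,))
                            - sc((a, b)) - sc((a, c)) - sc((b, c)) + full)
    return PartitionTable(set_names=names, raw=parts, full_r2=full)


def correct_partitions(table: PartitionTable) -> PartitionTable:
    """Clip negative partitions to zero, keeping raw values for audit."""
    corrected = {}
    clipped = np.zeros_like(table.full_r2)
    for key, val in table.raw.items():
        neg = np.minimum(val, 0.0)
        clipped += -neg
        corrected[key] = np.maximum(val, 0.0)
    return PartitionTable(set_names=table.set_names, raw=table.raw,
                          full_r2=table.full_r2, corrected=corrected,
                          clipped_magnitude=clipped)


# ---------------------------------------------------------------------------
# Diphone categories
# ---------------------------------------------------------------------------


@dataclass
class DiphoneCategoryMap:
    """Token-level diphone categorization with occurrence proportions."""

    token_counts: dict[str, int]
    proportions: dict[str, float]
    type_fractions: dict[str, dict[str, float]] = field(default_factory=dict)


def categorize_diphones(annotation: StimulusAnnotation,
                        include_single_phoneme_words: bool = False
                        ) -> DiphoneCategoryMap:
    """Assign each diphone token a category from its word-relative role.

    A token is ``short_word`` if it spans an entire two-phoneme word,
    ``word_beginning`` if it starts a longer word, and ``residue``
    otherwise.  ``include_single_phoneme_words`` additionally counts
    one-phoneme words as short-word tokens (their label is the bare
    phoneme).
    """
    token_counts = {c: 0 for c in CATEGORIES}
    per_type: dict[str, dict[str, int]] = {}
    for tok in extract_ngrams(annotation, 2):
        cat = _ROLE_TO_CAT[tok.role]
        token_counts[cat] += 1
        per_type.setdefault(tok.label, {c: 0 for c in CATEGORIES})[cat] += 1
    if include_single_phoneme_words:
        for word, phonemes in annotation.words:
            if len(phonemes) == 1:
                token_counts[CAT_SHORT_WORD] += 1
                per_type.setdefault(
                    phonemes[0], {c: 0 for c in CATEGORIES}
                )[CAT_SHORT_WORD] += 1
    total = sum(token_counts.values())
    proportions = {c: (token_counts[c] / total if total else 0.0)
                   for c in CATEGORIES}
    type_fractions = {}
    for label, counts in per_type.items():
        t = sum(counts.values())
        type_fractions[label] = {c: counts[c] / t for c in CATEGORIES}
    return DiphoneCategoryMap(token_counts=token_counts,
                              proportions=proportions,
                              type_fractions=type_fractions)


def diphone_category_designs(annotation: StimulusAnnotation,
                             inventory: NGramInventory,
                             delays, block_name: str = "diphone"
                             ) -> dict[str, DelayedDesign]:
    """Per-category diphone designs built from role-filtered tokens.

    Each category design has the full diphone column set but only that
    category's tokens contribute events, so the three designs sum exactly
    to the unrestricted diphone design (linearity of the indicator filter).
    """
    tokens = [t for t in extract_ngrams(annotation, 2)
              if t.label in inventory.index]
    designs = {}
    for cat in CATEGORIES:
        evs = [t for t in tokens if _ROLE_TO_CAT[t.role] == cat]
        space = event_indicator_features(evs, inventory, annotation,
                                         name=block_name)
        designs[cat] = stack_delays([space], delays)
    return designs


@dataclass
class CategoryContribution:
    """Per-voxel diphone-category contributions to explained variance."""

    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    masked_r2: dict[str, np.ndarray]
    proportions: dict[str, float]
    block_total: np.ndarray


def category_contribution(model: BandedModel, design: DelayedDesign,
                          category_designs: dict[str, DelayedDesign],
                          Y_res, categories: DiphoneCategoryMap,
                          diphone_block: str = "diphone"
                          ) -> CategoryContribution:
    """Split the diphone block's explained variance over token categories.

    The diphone prediction decomposes linearly over the per-category designs
    (each token belongs to exactly one category).  The raw contribution of
    category c with partial prediction P_c and total diphone prediction
    P = sum_c P_c is the additive explained-variance share

        contribution_c = (2 <Y, P_c> - <P_c, P>) / SST,

    which sums over categories exactly to the analogous share of P.  The
    plain R^2 of each masked prediction is reported alongside, and
    normalized contributions divide by each category's token-occurrence
    proportion (NaN where a category never occurs).
    """
    if diphone_block not in model.block_names:
        raise ValueError(f"model has no block {diphone_block!r}")
    Yv = _as_values(Y_res)
    sl = design.block_slices[diphone_block]
    w_di = model.weights[sl]

    preds = {}
    for cat, cdesign in category_designs.items():
        if cdesign.n_features != (sl.stop - sl.start):
            raise ValueError(
                f"category design {cat!r} has {cdesign.n_features} columns, "
                f"expected {sl.stop - sl.start}")
        preds[cat] = cdesign.values @ w_di
    total = np.sum(list(preds.values()), axis=0)

    Yc = Yv - Yv.mean(axis=0)
    sst = np.einsum("ij,ij->j", Yc, Yc)
    sst = np.where(sst > 0, sst, 1.0)

    raw, masked, normalized = {}, {}, {}
    for cat, P in preds.items():
        raw[cat] = (2.0 * np.einsum("ij,ij->j", Yc, P)
                    - np.einsum("ij,ij->j", P, total)) / sst
        masked[cat] = r2_columns(Yv, P)
        prop = categories.proportions.get(cat, 0.0)
        normalized[cat] = raw[cat] / prop if prop > 0 else np.full(
            raw[cat].shape, np.nan)
    block_total = (2.0 * np.einsum("ij,ij->j", Yc, total)
                   - np.einsum("ij,ij->j", total, total)) / sst
    return CategoryContribution(raw=raw, normalized=normalized,
                                masked_r2=masked,
                                proportions=dict(categories.proportions),
                                block_total=block_total)
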