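"""Variance partitioning and diphone-category contribution tests."""

import numpy as np
import pytest

import phonovox as pv
from phonovox.partitioning import (CAT_RESIDUE, CAT_SHORT_WORD,
                                   CAT_WORD_BEGINNING, all_nonempty_subsets)

from conftest import make_annotation

IDENTITY = pv.TemporalPrior(delays=(0.0,), scale=np.ones(1))


def make_blocks(rng, nt, sizes, orthogonal=False):
    if orthogonal:
        q, _ = np.linalg.qr(rng.standard_normal((nt, sum(sizes))))
        chunks = np.split(q, np.cumsum(sizes)[:-1], axis=1)
    else:
        chunks = [rng.standard_normal((nt, s)) for s in sizes]
    spaces = [
        pv.FeatureSpace(n, c, tuple(f"{n}{j}" for j in range(c.shape[1])),
                        tr=2.0)
        for n, c in zip("ABC", chunks)
    ]
    return pv.stack_delays(spaces, delays=(0.0,))


class TestNestedScores:
    def test_full_subset_matches_joint_fit(self, rng):
        nt = 120
        design = make_blocks(rng, nt, (3, 4))
        y = rng.standard_normal((nt, 2))
        lam = np.array([1.0, 5.0])
        scores = pv.nested_scores(design, y, design, y, lam,
                                  prior=IDENTITY)
        joint = pv.fit_banded(design, y, lam, prior=IDENTITY)
        assert np.allclose(scores[("A", "B")],
                           pv.score_validation(joint, design, y), atol=1e-10)

    def test_empty_subset_scores_zero_predictor(self, rng):
        nt = 80
        design = make_blocks(rng, nt, (3, 3))
        y = rng.standard_normal((nt, 2))
        y -= y.mean(axis=0)
        scores = pv.nested_scores(design, y, design, y,
                                  np.array([1.0, 1.0]), subsets=[()],
                                  prior=IDENTITY)
        assert np.allclose(scores[()], 0.0, atol=1e-12)

    def test_orthogonal_blocks_are_additive(self):
        """R^2(AB) ~ R^2(A) + R^2(B) when the blocks are orthogonal."""
        gaps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            nt = 500
            design = make_blocks(r, nt, (4, 4), orthogonal=True)
            w = r.standard_normal(design.n_features)
            s = design.values @ w
            s /= s.std()
            y = (s + r.standard_normal(nt))[:, None]
            lam = np.array([1e-3, 1e-3])
            sc = pv.nested_scores(design, y, design, y, lam, prior=IDENTITY)
            gaps.append(sc[("A", "B")][0] - sc[("A",)][0] - sc[("B",)][0])
        assert abs(np.mean(gaps)) < 0.02

    def test_unknown_block_rejected(self, rng):
        design = make_blocks(rng, 40, (2, 2))
        y = rng.standard_normal((40, 1))
        with pytest.raises(KeyError):
            pv.nested_scores(design, y, design, y, np.array([1.0, 1.0]),
                             subsets=[("Z",)])


class TestVariancePartition:
    def _random_scores(self, rng, names):
        return {s: rng.standard_normal(5)
                for s in all_nonempty_subsets(names)}

    def test_seven_partitions_sum_to_full_r2(self, rng):
        scores = self._random_scores(rng, "ABC")
        table = pv.variance_partition(scores)
        assert len(table.raw) == 7
        assert np.allclose(table.partition_sum(), scores[("A", "B", "C")],
                           atol=1e-10)

    def test_two_set_partitions_sum(self, rng):
        scores = self._random_scores(rng, "AB")
        table = pv.variance_partition(scores)
        assert len(table.raw) == 3
        assert np.allclose(table.partition_sum(), scores[("A", "B")],
                           atol=1e-12)

    def test_permutation_equivariance(self, rng):
        scores = self._random_scores(rng, "ABC")
        relabeled = {tuple("CAB"["ABC".index(x)] for x in k): v
                     for k, v in scores.items()}
        t1 = pv.variance_partition(scores)
        t2 = pv.variance_partition(relabeled)
        for key, val in t1.raw.items():
            mapped = tuple(sorted("CAB"["ABC".index(x)] for x in key))
            assert np.allclose(t2.raw[mapped], val, atol=1e-12)

    def test_duplicated_predictor_is_shared(self):
        """A duplicated as B: variance moves to the shared partition."""
        uniq_a, uniq_b, shared, ra = [], [], [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            nt = 400
            X = r.standard_normal((nt, 3))
            spaces = [pv.FeatureSpace("A", X, ("a0", "a1", "a2"), tr=2.0),
                      pv.FeatureSpace("B", X.copy(), ("b0", "b1", "b2"),
                                      tr=2.0)]
            design = pv.stack_delays(spaces, delays=(0.0,))
            w = r.standard_normal(3)
            s = X @ w
            s /= s.std()
            y = (s + r.standard_normal(nt))[:, None]
            sc = pv.nested_scores(design, y, design, y,
                                  np.array([1.0, 1.0]), prior=IDENTITY)
            t = pv.variance_partition(sc)
            uniq_a.append(t.raw[("A",)][0])
            uniq_b.append(t.raw[("B",)][0])
            shared.append(t.raw[("A", "B")][0])
            ra.append(sc[("A",)][0])
        assert abs(np.mean(uniq_a)) < 0.02
        assert abs(np.mean(uniq_b)) < 0.02
        assert abs(np.mean(shared) - np.mean(ra)) < 0.02

    def test_orthogonal_three_blocks_unique_only(self):
        uniques, shareds = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            nt = 600
            design = make_blocks(r, nt, (3, 3, 3), orthogonal=True)
            w = r.standard_normal(design.n_features)
            s = design.values @ w
            s /= s.std()
            y = (s + r.standard_normal(nt))[:, None]
            lam = np.array([1e-3] * 3)
            sc = pv.nested_scores(design, y, design, y, lam, prior=IDENTITY)
            t = pv.variance_partition(sc)
            for n in "ABC":
                uniques.append(t.raw[(n,)][0] - sc[(n,)][0])
            shareds.extend([t.raw[k][0] for k in t.raw if len(k) > 1])
        assert abs(np.mean(uniques)) < 0.03
        assert abs(np.mean(shareds)) < 0.03

    def test_missing_subset_rejected(self, rng):
        scores = self._random_scores(rng, "ABC")
        del scores[("A", "B")]
        with pytest.raises(KeyError):
            pv.variance_partition(scores)


class TestCorrectPartitions:
    def test_nonnegative_untouched(self, rng):
        scores = {s: np.abs(rng.standard_normal(4)) * 0
                  for s in all_nonempty_subsets("AB")}
        scores[("A", "B")] = np.array([1.0, 1.0, 1.0, 1.0])
        scores[("A",)] = np.array([0.4, 0.2, 0.9, 0.5])
        scores[("B",)] = np.array([0.6, 0.8, 0.2, 0.5])
        table = pv.correct_partitions(pv.variance_partition(scores))
        for k in table.raw:
            assert np.allclose(table.corrected[k],
                               np.maximum(table.raw[k], 0.0))

    def test_negative_partition_clipped_and_logged(self, rng):
        scores = {s: rng.standard_normal(50)
                  for s in all_nonempty_subsets("ABC")}
        table = pv.correct_partitions(pv.variance_partition(scores))
        for k in table.corrected:
            assert np.all(table.corrected[k] >= 0)
        expect = sum(np.maximum(-table.raw[k], 0.0) for k in table.raw)
        assert np.allclose(table.clipped_magnitude, expect, atol=1e-12)


class TestDiphoneCategories:
    WORDS = [("my", ("M", "AY")), ("and", ("AE", "N", "D")),
             ("undid", ("AH", "N", "D", "IH", "D")), ("a", ("AH",))]

    def test_token_roles_follow_taxonomy(self):
        ann = make_annotation(self.WORDS, tr=2.0)
        ann.duration = 20.0
        cats = pv.categorize_diphones(ann)
        # my -> short word; and -> beginning + residue;
        # undid -> beginning + 3 residues; "a" contributes nothing
        assert cats.token_counts[CAT_SHORT_WORD] == 1
        assert cats.token_counts[CAT_WORD_BEGINNING] == 2
        assert cats.token_counts[CAT_RESIDUE] == 4
        assert sum(cats.proportions.values()) == pytest.approx(1.0)
        assert cats.type_fractions["M.AY"][CAT_SHORT_WORD] == 1.0
        assert cats.type_fractions["AE.N"][CAT_WORD_BEGINNING] == 1.0
        assert cats.type_fractions["N.D"][CAT_RESIDUE] == 1.0

    def test_single_phoneme_words_option(self):
        ann = make_annotation(self.WORDS, tr=2.0)
        ann.duration = 20.0
        cats = pv.categorize_diphones(ann, include_single_phoneme_words=True)
        assert cats.token_counts[CAT_SHORT_WORD] == 2

    def test_category_designs_sum_to_full(self, annotation):
        inv = pv.NGramInventory.from_annotation(annotation, 2)
        designs = pv.diphone_category_designs(annotation, inv,
                                              delays=(2.0, 4.0))
        total = sum(d.values for d in designs.values())
        events = pv.extract_ngrams(annotation, 2)
        full = pv.stack_delays(
            [pv.event_indicator_features(events, inv, annotation,
                                         name="diphone")],
            delays=(2.0, 4.0))
        assert np.allclose(total, full.values, atol=1e-10)


class TestCategoryContribution:
    def _setup(self, annotation, rng):
        inv = pv.NGramInventory.from_annotation(annotation, 2)
        events = pv.extract_ngrams(annotation, 2)
        space = pv.event_indicator_features(events, inv, annotation,
                                            name="diphone")
        design = pv.stack_delays([space], delays=(2.0, 4.0))
        cat_designs = pv.diphone_category_designs(annotation, inv,
                                                  delays=(2.0, 4.0))
        cats = pv.categorize_diphones(annotation)
        return inv, design, cat_designs, cats

    def test_contributions_sum_to_block_total(self, annotation, rng):
        inv, design, cat_designs, cats = self._setup(annotation, rng)
        y = rng.standard_normal((design.n_timepoints, 3))
        y -= y.mean(axis=0)
        model = pv.fit_banded(design, y, np.array([10.0]))
        contrib = pv.category_contribution(model, design, cat_designs, y,
                                           cats)
        total = sum(contrib.raw.values())
        assert np.allclose(total, contrib.block_total, atol=1e-8)

    def test_zero_weights_zero_contributions(self, annotation, rng):
        inv, design, cat_designs, cats = self._setup(annotation, rng)
        y = rng.standard_normal((design.n_timepoints, 2))
        model = pv.fit_banded(design, np.zeros_like(y), np.array([1.0]))
        contrib = pv.category_contribution(model, design, cat_designs, y,
                                           cats)
        for v in contrib.raw.values():
            assert np.allclose(v, 0.0, atol=1e-12)

    def test_short_word_voxel_prefers_short_word_category(self, phonotactics):
        """Voxels driven only by whole-word diphones show the largest
        normalized short-word contribution."""
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            ann = pv.gen_stream(phonotactics, 150, seed=100 + seed)
            inv = pv.NGramInventory.from_annotation(ann, 2)
            cat_designs = pv.diphone_category_designs(ann, inv,
                                                      delays=(2.0, 4.0))
            cats = pv.categorize_diphones(ann)
            events = pv.extract_ngrams(ann, 2)
            space = pv.event_indicator_features(events, inv, ann,
                                                name="diphone")
            design = pv.stack_delays([space], delays=(2.0, 4.0))
            r = np.random.default_rng(seed)
            drive = cat_designs["short_word"].values.sum(axis=1)
            y = drive + 0.5 * drive.std() * r.standard_normal(len(drive))
            y = ((y - y.mean()) / y.std())[:, None]
            best, _ = pv.cv_search(design, y, folds=5,
                                   grid=pv.HyperGrid.default(1, 5))
            model = pv.fit_banded(design, y, best)
            contrib = pv.category_contribution(model, design, cat_designs,
                                               y, cats)
            vals = {c: contrib.normalized[c][0] for c in contrib.normalized
                    if np.isfinite(contrib.normalized[c][0])}
            if max(vals, key=vals.get) == "short_word":
                wins += 1
        assert wins / n_seeds > 0.9
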