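"""Feature-construction tests: parsing, n-grams, Lanczos filtering, delays."""

import numpy as np
import pytest

import phonovox as pv
from phonovox.stimulus_features import (NGRAM_SEP, ROLE_RESIDUE,
                                        ROLE_WHOLE_WORD,
                                        ROLE_WORD_BEGINNING,
                                        _impulse_features, lanczos_kernel)

from conftest import make_annotation


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


def write_tsv(tmp_path, body, story="s1", duration=10.0, tr=2.0045):
    path = tmp_path / "ann.tsv"
    header = f"#story_id={story}\n#duration={duration}\n#tr={tr}\n"
    path.write_text(header + body)
    return path


class TestParseAnnotation:
    def test_round_trip_single_word(self, tmp_path):
        body = ("0.0\t0.1\tM\t0\tmy\n"
                "0.1\t0.25\tAY\t0\tmy\n"
                "0.25\t0.4\tsp\t0\t\n")
        ann = pv.parse_annotation(write_tsv(tmp_path, body))
        assert len(ann.words) == 1
        assert ann.words[0] == ("my", ("M", "AY"))
        assert [e.label for e in ann.events] == ["M", "AY"]
        assert ann.tr == pytest.approx(2.0045)

    def test_empty_event_section(self, tmp_path):
        ann = pv.parse_annotation(write_tsv(tmp_path, "", duration=8.0))
        assert ann.events == []
        assert ann.duration == 8.0

    def test_unknown_label_rejected_by_name(self, tmp_path):
        path = write_tsv(tmp_path, "0.0\t0.1\tZZ\t0\tzz\n")
        with pytest.raises(ValueError, match="ZZ"):
            pv.parse_annotation(path)

    def test_unsorted_events_rejected(self, tmp_path):
        body = "1.0\t1.1\tM\t0\tmy\n0.0\t0.1\tAY\t0\tmy\n"
        with pytest.raises(ValueError, match="sorted"):
            pv.parse_annotation(write_tsv(tmp_path, body))

    def test_overlap_beyond_tolerance_rejected(self, tmp_path):
        body = "0.0\t0.5\tM\t0\tmy\n0.2\t0.6\tAY\t0\tmy\n"
        with pytest.raises(ValueError, match="overlap"):
            pv.parse_annotation(write_tsv(tmp_path, body))

    def test_write_read_round_trip(self, tmp_path, annotation):
        path = tmp_path / "rt.tsv"
        pv.write_annotation(annotation, path)
        back = pv.parse_annotation(path)
        assert len(back.events) == len(annotation.events)
        assert back.words == annotation.words
        assert back.duration == pytest.approx(annotation.duration)


# ---------------------------------------------------------------------------
# N-gram extraction and roles
# ---------------------------------------------------------------------------


class TestExtractNgrams:
    def test_word_beginning_and_residue(self):
        ann = make_annotation([("and", ("AE", "N", "D"))])
        grams = pv.extract_ngrams(ann, 2)
        assert [(g.label, g.role) for g in grams] == [
            ("AE.N", ROLE_WORD_BEGINNING), ("N.D", ROLE_RESIDUE)]

    def test_whole_word_diphone(self):
        ann = make_annotation([("my", ("M", "AY"))])
        grams = pv.extract_ngrams(ann, 2)
        assert [(g.label, g.role) for g in grams] == [
            ("M.AY", ROLE_WHOLE_WORD)]

    def test_single_phoneme_word_has_no_diphone(self):
        ann = make_annotation([("a", ("AH",))])
        assert pv.extract_ngrams(ann, 2) == []

    def test_no_cross_word_ngrams_by_default(self):
        ann = make_annotation([("my", ("M", "AY")), ("and", ("AE", "N", "D"))])
        labels = {g.label for g in pv.extract_ngrams(ann, 2)}
        assert "AY.AE" not in labels
        labels_x = {g.label for g in pv.extract_ngrams(ann, 2,
                                                       cross_word=True)}
        assert "AY.AE" in labels_x

    def test_onset_is_first_phoneme_onset(self):
        ann = make_annotation([("and", ("AE", "N", "D"))])
        grams = pv.extract_ngrams(ann, 3)
        assert grams[0].label == "AE.N.D"
        assert grams[0].onset == ann.events[0].onset
        assert grams[0].role == ROLE_WHOLE_WORD


class TestInventory:
    def test_default_inventory_size(self):
        inv = pv.NGramInventory.single_phonemes()
        assert len(inv) == 39
        assert len(pv.CONSONANTS) + len(pv.VOWELS) == 39
        assert sorted(inv.index.values()) == list(range(39))

    def test_possible_counts(self):
        assert pv.NGramInventory.n_possible(2) == 39 ** 2 == 1521
        assert pv.NGramInventory.n_possible(3) == 39 ** 3

    def test_from_annotation_is_sorted_unique(self, annotation):
        inv = pv.NGramInventory.from_annotation(annotation, 2)
        assert list(inv.units) == sorted(set(inv.units))
        assert all(NGRAM_SEP in u for u in inv.units)


# ---------------------------------------------------------------------------
# Lanczos resampling
# ---------------------------------------------------------------------------


class TestLanczos:
    def test_constant_preserved(self):
        t_src = np.arange(0, 40, 0.01)
        t_dst = np.arange(0.5, 38, 2.0045)
        out = pv.lanczos_resample(np.full_like(t_src, 3.25), t_src, t_dst)
        assert np.allclose(out, 3.25, atol=1e-12)

    def test_bandlimited_identity_on_tr_grid(self):
        # resampling a TR-grid signal onto the same grid is the identity:
        # the sinc kernel vanishes at every nonzero integer lag
        tr = 2.0
        t = np.arange(0, 400, tr)
        x = (np.sin(2 * np.pi * 0.03 * t) + 0.5 *
             np.cos(2 * np.pi * 0.07 * t))
        out = pv.lanczos_resample(x, t, t, cutoff=0.5 / tr)
        assert np.max(np.abs(out - x)) < 1e-6

    def test_brute_force_oracle_on_impulse_trains(self, rng):
        """Fast impulse path matches a dense windowed-sinc convolution."""
        tr, dur = 2.0045, 60.0
        n_tr = int(dur / tr)
        onsets = np.sort(rng.uniform(0, dur - 1, 80))
        dt = 0.01
        fine = np.arange(0, dur, dt)
        train = np.zeros_like(fine)
        for o in onsets:
            train[int(round(o / dt))] += 1.0 / dt
        t_dst = np.arange(n_tr) * tr
        cutoff = 0.5 / tr
        # independent dense oracle: normalized windowed-sinc rows
        W = lanczos_kernel(t_dst[:, None] - fine[None, :], cutoff, 3)
        expected = (W @ train) / W.sum(axis=1)
        got = _impulse_features([onsets], None, n_tr, tr, dur)[:, 0]
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_dst_outside_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            pv.lanczos_resample(np.zeros(10), np.arange(10.0),
                                np.array([-1.0, 2.0]))


# ---------------------------------------------------------------------------
# Indicator, count, semantic features
# ---------------------------------------------------------------------------


class TestIndicatorFeatures:
    def test_single_event_mass_and_empty_columns(self):
        ann = make_annotation([("my", ("M", "AY"))], tr=2.0, start=8.0)
        ann.duration = 24.0
        inv = pv.NGramInventory.from_annotation(ann, 2)
        fs = pv.event_indicator_features(pv.extract_ngrams(ann, 2), inv, ann)
        col = fs.values[:, inv.index["M.AY"]]
        # unit-area impulse: TR samples integrate to ~1 event
        assert col.sum() * ann.tr == pytest.approx(1.0, abs=0.05)
        other = np.delete(fs.values, inv.index["M.AY"], axis=1)
        assert np.all(other == 0)

    def test_linearity_two_events_vs_one(self):
        words = [("my", ("M", "AY"))]
        a1 = make_annotation(words, tr=2.0)
        a1.duration = 20.0
        a2 = make_annotation(words + words, tr=2.0, dur_per_phoneme=0.08)
        a2.duration = 20.0
        inv = pv.NGramInventory(order=2, units=("M.AY",))
        f1 = pv.event_indicator_features(pv.extract_ngrams(a1, 2), inv, a1)
        f2 = pv.event_indicator_features(pv.extract_ngrams(a2, 2), inv, a2)
        # superposition: response to both events = sum of single responses
        ev = pv.extract_ngrams(a2, 2)
        single = [pv.event_indicator_features([e], inv, a2) for e in ev]
        assert np.allclose(f2.values, sum(s.values for s in single),
                           atol=1e-12)
        assert f2.values.sum() == pytest.approx(2 * f1.values.sum(), rel=0.1)

    def test_event_outside_duration_rejected(self):
        ann = make_annotation([("my", ("M", "AY"))], tr=2.0)
        ann.duration = 20.0
        inv = pv.NGramInventory(order=1, units=("M",))
        bad = [pv.NGramEvent("M", 25.0, ROLE_WHOLE_WORD, 0)]
        with pytest.raises(ValueError, match="outside"):
            pv.event_indicator_features(bad, inv, ann)


class TestPhonemeCount:
    def test_onset_histogram(self):
        ann = make_annotation([("and", ("AE", "N", "D"))], tr=2.0,
                              dur_per_phoneme=0.3)
        ann.duration = 8.0
        counts = pv.phoneme_count_feature(ann).values[:, 0]
        assert counts.tolist() == [3, 0, 0, 0]

    def test_empty_annotation_zero_column(self):
        ann = pv.StimulusAnnotation(events=[], words=[], duration=8.0,
                                    tr=2.0)
        counts = pv.phoneme_count_feature(ann).values
        assert counts.shape == (4, 1)
        assert np.all(counts == 0)

    def test_synthetic_rate_in_configured_range(self, annotation):
        counts = pv.phoneme_count_feature(annotation).values[:, 0]
        frac = np.mean((counts >= 10) & (counts <= 40))
        assert frac >= 0.99


class TestSemanticFeatures:
    def test_single_word_profile_proportional_to_embedding(self):
        ann = make_annotation([("my", ("M", "AY"))], tr=2.0)
        ann.duration = 20.0
        emb = np.array([2.0, -1.0, 0.5])
        fs = pv.semantic_features(ann, {"my": emb})
        profile = fs.values[:, 0] / emb[0]
        for d in range(3):
            assert np.allclose(fs.values[:, d], emb[d] * profile, atol=1e-12)

    def test_out_of_lexicon_word_maps_to_zero(self):
        ann = make_annotation([("my", ("M", "AY")), ("and", ("AE", "N",
                                                            "D"))], tr=2.0)
        ann.duration = 20.0
        with_miss = pv.semantic_features(ann, {"my": np.array([1.0, 0.0])})
        zeroed = pv.semantic_features(ann, {"my": np.array([1.0, 0.0]),
                                            "and": np.zeros(2)})
        assert np.allclose(with_miss.values, zeroed.values, atol=1e-12)

    def test_superposition_of_orthogonal_words(self):
        w1, w2 = ("my", ("M", "AY")), ("and", ("AE", "N", "D"))
        ann = make_annotation([w1, w2], tr=2.0, gap=1.0)
        ann.duration = 20.0
        e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        lex = {"my": e1, "and": e2}
        fs = pv.semantic_features(ann, lex)
        fs1 = pv.semantic_features(ann, {"my": e1, "and": np.zeros(2)})
        fs2 = pv.semantic_features(ann, {"my": np.zeros(2), "and": e2})
        assert np.allclose(fs.values, fs1.values + fs2.values, atol=1e-12)

    def test_mixed_dimension_lexicon_rejected(self):
        ann = make_annotation([("my", ("M", "AY"))], tr=2.0)
        ann.duration = 20.0
        with pytest.raises(ValueError, match="dimension"):
            pv.semantic_features(ann, {"my": np.ones(3), "and": np.ones(4)})


# ---------------------------------------------------------------------------
# Spectrum features
# ---------------------------------------------------------------------------


class TestWelchBandPower:
    def test_448_bands_cover_15khz(self):
        assert pv.n_spectrum_bands() == 448
        # 447 bands would stop short of 15 kHz
        assert 25.0 + 33.5 * 447 < 15000.0 <= 25.0 + 33.5 * 448

    def test_pure_tone_lands_in_its_band(self):
        fs = 32000.0
        t = np.arange(0, 8.5, 1 / fs)
        tone = np.sin(2 * np.pi * 2801.0 * t)
        space = pv.welch_band_power(tone, fs, tr=2.0045, n_tr=3)
        band = np.argmax(space.values[1])
        lo = 25.0 + 33.5 * band
        assert lo <= 2801.0 < lo + 33.5

    def test_silence_gives_zero_power(self):
        space = pv.welch_band_power(np.zeros(80000), 32000.0, tr=2.0045,
                                    n_tr=1)
        assert np.all(space.values == 0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            pv.welch_band_power(np.zeros(10000), 16000.0)

    def test_short_audio_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            pv.welch_band_power(np.zeros(100), 32000.0)

    def test_white_noise_flat_spectrum(self, rng):
        fs = 32000.0
        x = rng.standard_normal(int(fs) * 30)
        space = pv.welch_band_power(x, fs, tr=2.0045)
        means = space.values.mean(axis=0)
        rel = means / means.mean()
        # flat to within a few Monte-Carlo standard errors
        se = np.std(rel) / np.sqrt(space.values.shape[0])
        assert np.all(np.abs(rel - 1.0) < max(3 * np.std(rel), 0.2))


# ---------------------------------------------------------------------------
# Delay stacking
# ---------------------------------------------------------------------------


class TestStackDelays:
    @pytest.mark.parametrize("sizes,expected", [
        ((448, 1), 1796),
        ((39, 858, 4841), 22952),
        ((39, 858, 4841, 985), 26892),
    ])
    def test_column_counts_match_hand_totals(self, sizes, expected, rng):
        nt = 5
        spaces = [
            pv.FeatureSpace(f"b{i}", rng.standard_normal((nt, nf)),
                            tuple(f"u{i}_{j}" for j in range(nf)))
            for i, nf in enumerate(sizes)
        ]
        design = pv.stack_delays(spaces)
        assert design.n_features == expected

    def test_delay_shift_semantics(self, rng):
        nt = 12
        fs = pv.FeatureSpace("a", rng.standard_normal((nt, 2)),
                             ("u0", "u1"), tr=2.0045)
        design = pv.stack_delays([fs], delays=[2.0, 4.0])
        sl = design.block_slices["a"]
        vals = design.values[:, sl]
        # delay 2 s = 1 TR, delay 4 s = 2 TR
        assert np.allclose(vals[1:, 0], fs.values[:-1, 0])
        assert np.all(vals[0, :2] == 0)
        assert np.allclose(vals[2:, 2], fs.values[:-2, 0])
        assert np.all(vals[:2, 2:] == 0)

    def test_empty_space_list(self):
        design = pv.stack_delays([], tr=2.0)
        assert design.n_features == 0

    def test_inconsistent_nt_rejected(self, rng):
        a = pv.FeatureSpace("a", rng.standard_normal((5, 2)), ("x", "y"))
        b = pv.FeatureSpace("b", rng.standard_normal((6, 1)), ("z",))
        with pytest.raises(ValueError, match="n_timepoints"):
            pv.stack_delays([a, b])

    def test_subset_preserves_columns(self, rng):
        nt = 8
        a = pv.FeatureSpace("a", rng.standard_normal((nt, 2)), ("x", "y"))
        b = pv.FeatureSpace("b", rng.standard_normal((nt, 3)),
                            ("u", "v", "w"))
        design = pv.stack_delays([a, b], delays=[2.0, 4.0])
        sub = design.subset(["b"])
        assert sub.block_names == ("b",)
        assert np.allclose(sub.values,
                           design.values[:, design.block_slices["b"]])

    def test_save_load_round_trip(self, tmp_path, rng):
        a = pv.FeatureSpace("a", rng.standard_normal((6, 2)), ("x", "y"))
        design = pv.stack_delays([a])
        path = tmp_path / "d.npz"
        pv.save_design(design, path)
        back = pv.load_design(path)
        assert np.allclose(back.values, design.values)
        assert back.block_names == design.block_names
        assert back.delays == design.delays
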