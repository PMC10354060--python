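"""Synthetic phoneme streams and simulated BOLD voxels.

Implements the feasibility simulations behind the encoding-model analysis:
a phonotactic generator emulating annotated narrative speech (10-40
phonemes per TR over a 39-phoneme inventory, Zipf-distributed words with
first-order phonotactics), model voxels sensitive to small sets of phonemic
units, and BOLD generation by HRF convolution, 0.1 Hz low-pass filtering
and Gaussian noise calibrated to a pass-band power SNR.  The same streams
serve as drop-in fixtures for every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .encoding import (default_lambda_grid, double_gamma_hrf,
                       nested_single_block_r2, single_block_cv_fit)

#: shrinkage candidates for the simulation fits: the large sparse indicator
#: blocks need penalties well above the default range's top
SIM_LAMBDAS = default_lambda_grid(10, 1e-1, 1e7)
from .preprocess import BoldRun, zscore_per_story
from .stimulus_features import (DEFAULT_TR, NGRAM_SEP, NGramInventory,
                                PhonemeEvent, PHONEME_INVENTORY,
                                StimulusAnnotation, DelayedDesign,
                                event_indicator_features, extract_ngrams,
                                phoneme_count_feature, stack_delays)

DEFAULT_N_TR = 3737          # ~2 h of narrated speech at TR = 2.0045 s
DEFAULT_RATE_RANGE = (10.0, 40.0)   # phonemes per TR
DEFAULT_LOWPASS_HZ = 0.1
DEFAULT_SNR = 1.0

ORDER_NAMES = {1: "phoneme", 2: "diphone", 3: "triphone", 4: "tetraphone",
               5: "pentaphone", 6: "hexaphone"}


# ---------------------------------------------------------------------------
# Phonotactic stream model
# ---------------------------------------------------------------------------


@dataclass
class PhonotacticModel:
    """Generative model of an annotated narrative phoneme stream."""

    inventory: tuple[str, ...]
    initial: np.ndarray                 # (n_phonemes,)
    transition: np.ndarray              # (n_phonemes, n_phonemes), rows sum 1
    lexicon: list[tuple[str, tuple[str, ...]]]
    frequencies: np.ndarray             # word-token probabilities
    rate_range: tuple[float, float] = DEFAULT_RATE_RANGE

    def __post_init__(self):
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        lo, hi = self.rate_range
        if not (0 < lo <= hi):
            raise ValueError("rate range must be positive and ordered")
        if len(self.lexicon) != len(self.frequencies):
            raise ValueError("one frequency per lexicon word required")


def default_phonotactics(seed: int = 0, n_words: int = 8000,
                         zipf_exponent: float = 1.05,
                         max_len: int = 10,
                         successors: int = 22) -> PhonotacticModel:
    """Seeded phonotactic model with realistically skewed statistics.

    Phoneme frequencies are Zipf-weighted, pronunciations come from a
    first-order Markov chain whose rows allow only ~``successors`` of the
    39 phonemes (English permits roughly 850 of the 1521 conceivable
    diphones), word-token frequencies follow a Zipf law, and frequent words
    are short (word length grows with frequency rank), so realized
    diphone/triphone/higher-order inventories match the size and frequency
    skew of natural narrative speech.
    """
    rng = np.random.default_rng(seed)
    n_ph = len(PHONEME_INVENTORY)
    perm = rng.permutation(n_ph)
    base = 1.0 / (1.0 + np.arange(n_ph)) ** 0.9
    pi = np.empty(n_ph)
    pi[perm] = base / base.sum()
    # rows biased toward the marginal distribution with multiplicative
    # noise, then restricted to each phoneme's permitted successors
    gains = rng.gamma(shape=2.0, scale=1.0, size=(n_ph, n_ph))
    trans = pi[None, :] * gains
    for i in range(n_ph):
        keep = np.argsort(trans[i])[::-1][:successors]
        mask = np.zeros(n_ph, dtype=bool)
        mask[keep] = True
        trans[i, ~mask] = 0.0
    trans /= trans.sum(axis=1, keepdims=True)

    lexicon: list[tuple[str, tuple[str, ...]]] = []
    seen: dict[str, int] = {}
    for rank in range(n_words):
        mean_len = 1.5 + 4.5 * ((rank + 1) / n_words) ** 0.35
        length = int(np.clip(1 + rng.poisson(mean_len - 1.0), 1, max_len))
        ph = [PHONEME_INVENTORY[rng.choice(n_ph, p=pi)]]
        for _ in range(length - 1):
            prev = PHONEME_INVENTORY.index(ph[-1])
            ph.append(PHONEME_INVENTORY[rng.choice(n_ph, p=trans[prev])])
        word = "".join(ph).lower()
        if word in seen:
            seen[word] += 1
            word = f"{word}~{seen[word]}"
        else:
            seen[word] = 0
        lexicon.append((word, tuple(ph)))
    freqs = 1.0 / (1.0 + np.arange(n_words)) ** zipf_exponent
    freqs /= freqs.sum()
    return PhonotacticModel(inventory=PHONEME_INVENTORY, initial=pi,
                            transition=trans, lexicon=lexicon,
                            frequencies=freqs)


def gen_stream(model: PhonotacticModel, n_tr: int, tr: float = DEFAULT_TR,
               seed: int = 0, story_id: str | None = None,
               mean_sentence_words: float = 9.0,
               pause_s: tuple[float, float] = (0.1, 0.6)
               ) -> StimulusAnnotation:
    """Sample an annotated phoneme stream of ``n_tr`` TRs.

    Words are drawn i.i.d. from the lexicon's Zipf frequencies; phoneme
    durations follow a slowly wandering articulation rate (a reflected
    random walk inside the configured per-TR range, with log-normal
    per-phoneme jitter).  Words are grouped into sentences of geometric
    length and separated by short pauses drawn from ``pause_s``, which
    gives the total phoneme count the strong slow modulation (breaths,
    sentence breaks, tempo drift) characteristic of narrated speech, while
    per-TR counts stay within the configured range for essentially all TRs.
    """
    if n_tr < 1:
        raise ValueError("n_tr must be >= 1")
    lo, hi = model.rate_range
    if hi / tr > 60.0 / 0.03:
        raise ValueError("rate range infeasible for realistic durations")
    rng = np.random.default_rng(seed)
    duration = n_tr * tr
    span = hi - lo
    # articulation-rate band chosen so that per-TR counts, net of pauses,
    # stay inside [lo, hi]: a TR overlapping a maximal pause still carries
    # walk_lo * (1 - pause_max/tr) >= lo phoneme onsets
    walk_lo = lo + 0.23 * span
    walk_hi = hi - 0.05 * span
    rate = rng.uniform(walk_lo + 0.2 * span, walk_hi - 0.2 * span)
    p_sentence_end = 1.0 / max(mean_sentence_words, 1.0)

    events: list[PhonemeEvent] = []
    words: list[tuple[str, tuple[str, ...]]] = []
    t = 0.0
    last_pause_end = -np.inf
    while t < duration:
        widx = len(words)
        word, phonemes = model.lexicon[
            rng.choice(len(model.lexicon), p=model.frequencies)]
        # reflected random-walk update of the articulation rate, per word
        rate += rng.normal(0.0, 0.08 * span)
        rate = float(np.clip(rate, walk_lo, walk_hi))
        emitted = []
        for pos, ph in enumerate(phonemes):
            dur = (tr / rate) * rng.lognormal(0.0, 0.12)
            if t >= duration:
                break
            events.append(PhonemeEvent(ph, t, min(t + dur, duration), widx,
                                       pos))
            emitted.append(ph)
            t += dur
        if emitted:
            # a word cut off by the stream end keeps only its emitted prefix
            words.append((word, tuple(emitted)))
        # pauses never cluster closer than ~1.5 TRs, so no TR loses more
        # than one pause's worth of phonemes
        if (rng.random() < p_sentence_end
                and t - last_pause_end > 1.5 * tr):
            t += float(np.clip(rng.lognormal(np.log(0.3), 0.5),
                               pause_s[0], pause_s[1]))
            last_pause_end = t
    return StimulusAnnotation(events=events, words=words,
                              story_id=story_id or f"sim-{seed}",
                              duration=duration, tr=tr)


# ---------------------------------------------------------------------------
# Simulated voxels
# ---------------------------------------------------------------------------


@dataclass
class VoxelSpec:
    """Ground-truth sensitivity of a simulated voxel."""

    order: int
    units: tuple[str, ...]
    weights: np.ndarray | None = None
    snr: float = DEFAULT_SNR

    def __post_init__(self):
        if not 1 <= self.order <= 6:
            raise ValueError("order must be in 1..6")
        if len(set(self.units)) != len(self.units):
            raise ValueError("voxel units must be distinct")
        if self.weights is None:
            self.weights = np.ones(len(self.units))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.units):
            raise ValueError("one weight per unit required")


@dataclass
class SimRun:
    """Simulated BOLD for one stream: clean signal, noise and bookkeeping."""

    annotation: StimulusAnnotation
    clean: np.ndarray           # (n_tr, n_voxels)
    bold: BoldRun
    sigma: np.ndarray           # per-voxel noise SD
    snr: np.ndarray             # requested pass-band power SNR per voxel
    seed: int


def hrf_kernel(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR."""
    t = np.arange(0.0, duration_s, tr)
    return double_gamma_hrf(t)


def hemodynamic_transform(signals: np.ndarray, tr: float,
                          lowpass_hz: float = DEFAULT_LOWPASS_HZ
                          ) -> np.ndarray:
    """HRF convolution followed by a zero-phase Butterworth low-pass."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] == 1 and signals.size == signals.shape[1]:
        signals = signals.T
    h = hrf_kernel(tr)
    conv = sps.fftconvolve(signals, h[:, None], mode="full",
                           axes=0)[:signals.shape[0]]
    sos = sps.butter(4, lowpass_hz, btype="low", fs=1.0 / tr, output="sos")
    return sps.sosfiltfilt(sos, conv, axis=0)


def band_power(x: np.ndarray, tr: float,
               band_hz: tuple[float, float] = (0.0, DEFAULT_LOWPASS_HZ)
               ) -> np.ndarray:
    """Per-column mean periodogram power inside the frequency band."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.size == x.shape[1]:
        x = x.T
    nt = x.shape[0]
    freqs = np.fft.rfftfreq(nt, d=tr)
    spec = np.abs(np.fft.rfft(x - x.mean(axis=0), axis=0)) ** 2 / nt
    lo, hi = band_hz
    sel = (freqs > lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"no FFT bins inside band {band_hz}")
    return spec[sel].mean(axis=0)


def noise_sigma_for_snr(clean: np.ndarray, tr: float, snr,
                        band_hz: tuple[float, float] = (0.0,
                                                        DEFAULT_LOWPASS_HZ)
                        ) -> np.ndarray:
    """White-noise SD giving the requested pass-band power SNR per voxel.

    The expected periodogram level of white noise with variance sigma^2 is
    sigma^2 * tr at every frequency (one-sided density aside), so matching
    mean band powers gives sigma^2 = band_power(clean) / snr directly in
    the mean-periodogram convention used by :func:`band_power`.
    """
    p_clean = band_power(clean, tr, band_hz)
    snr = np.asarray(snr, dtype=float)
    with np.errstate(divide="ignore"):
        var = np.where(np.isinf(snr), 0.0, p_clean / np.maximum(snr, 1e-300))
    return np.sqrt(var)


def _unit_design(annotation: StimulusAnnotation, order: int,
                 inventory: NGramInventory | None = None):
    """Indicator feature matrix for all units of the given order."""
    if inventory is None:
        inventory = NGramInventory.from_annotation(annotation, order)
    events = [t for t in extract_ngrams(annotation, order)
              if t.label in inventory.index]
    space = event_indicator_features(events, inventory, annotation,
                                     name=ORDER_NAMES.get(order,
                                                          f"ngram{order}"))
    return space, inventory


def simulate_voxels(specs: list[VoxelSpec], annotation: StimulusAnnotation,
                    lowpass_hz: float = DEFAULT_LOWPASS_HZ,
                    seed: int = 0,
                    unit_features: dict | None = None) -> SimRun:
    """Generate noisy BOLD for a batch of voxel specs on one stream.

    A voxel's clean signal is the weighted sum of its units' indicator
    trains put through :func:`hemodynamic_transform`; Gaussian white noise
    is calibrated per voxel to the requested pass-band power SNR.  Units
    that never occur in the stream contribute nothing (warning via zero
    column).  Pass ``unit_features`` (order -> (FeatureSpace, inventory))
    to reuse precomputed trains.
    """
    rng = np.random.default_rng(seed)
    nt = annotation.n_tr
    unit_features = dict(unit_features or {})
    drive = np.zeros((nt, len(specs)))
    for vi, spec in enumerate(specs):
        if spec.order not in unit_features:
            unit_features[spec.order] = _unit_design(annotation, spec.order)
        space, inv = unit_features[spec.order]
        for u, w in zip(spec.units, spec.weights):
            if u in inv.index:
                drive[:, vi] += w * space.values[:, inv.index[u]]
    clean = hemodynamic_transform(drive, annotation.tr, lowpass_hz)
    snrs = np.array([s.snr for s in specs], dtype=float)
    # noise shares the signal's pass band: raw white noise is low-passed with
    # the same filter, then scaled to the requested in-band power ratio, so
    # the broadband noise ceiling equals snr / (snr + 1) exactly
    sos = sps.butter(4, lowpass_hz, btype="low", fs=1.0 / annotation.tr,
                     output="sos")
    noise = sps.sosfiltfilt(sos, rng.standard_normal(clean.shape), axis=0)
    p_noise = band_power(noise, annotation.tr, (0.0, lowpass_hz))
    p_clean = band_power(clean, annotation.tr, (0.0, lowpass_hz))
    with np.errstate(divide="ignore"):
        gain = np.where(np.isinf(snrs), 0.0,
                        np.sqrt(p_clean / (np.maximum(snrs, 1e-300)
                                           * np.maximum(p_noise, 1e-300))))
    sigma = gain * noise.std(axis=0)
    noisy = clean + gain[None, :] * noise
    return SimRun(annotation=annotation, clean=clean,
                  bold=BoldRun(values=noisy, tr=annotation.tr,
                               story_id=annotation.story_id),
                  sigma=sigma, snr=snrs, seed=seed)


def simulate_voxel(spec: VoxelSpec, annotation: StimulusAnnotation,
                   lowpass_hz: float = DEFAULT_LOWPASS_HZ,
                   seed: int = 0) -> SimRun:
    """Single-voxel convenience wrapper around :func:`simulate_voxels`."""
    return simulate_voxels([spec], annotation, lowpass_hz, seed)


# ---------------------------------------------------------------------------
# Sensitivity sweep (identity VM vs phoneme-count VM)
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Identity-vs-count model comparison over voxel sensitivity k."""

    order: int
    k_grid: np.ndarray
    identity_r2: np.ndarray      # (n_k, n_resample)
    count_r2: np.ndarray
    crossover: float | None
    boundary_flag: str | None
    n_units_available: int

    @property
    def identity_mean(self) -> np.ndarray:
        return self.identity_r2.mean(axis=1)

    @property
    def count_mean(self) -> np.ndarray:
        return self.count_r2.mean(axis=1)


def _heldout_fit(design, Y, split: int, inner_folds: int,
                 return_weights: bool = False):
    """Fit on the first ``split`` rows (inner-CV shrinkage), score the tail.

    The design is z-scored over the whole stream first (stimulus
    statistics only), which keeps sparse indicator columns stable across
    the split.
    """
    from .encoding import _row_subset, _standardize_columns
    from .stimulus_features import DelayedDesign as _DD

    Xs, _, _ = _standardize_columns(design.values)
    design = _DD(values=Xs, delays=design.delays,
                 block_names=design.block_names,
                 block_slices=design.block_slices,
                 col_block=design.col_block, col_delay=design.col_delay,
                 tr=design.tr)
    nt = design.n_timepoints
    d_tr = _row_subset(design, np.arange(split))
    d_te = _row_subset(design, np.arange(split, nt))
    return single_block_cv_fit(d_tr, Y[:split], d_te, Y[split:],
                               lambdas=SIM_LAMBDAS, folds=inner_folds,
                               return_weights=return_weights,
                               standardize=False)


def sensitivity_sweep(order: int, k_grid, n_resample: int = 10,
                      snr: float = DEFAULT_SNR, n_tr: int = DEFAULT_N_TR,
                      tr: float = DEFAULT_TR, seed: int = 0,
                      outer_folds: int = 5, inner_folds: int = 5,
                      lowpass_hz: float = DEFAULT_LOWPASS_HZ,
                      model: PhonotacticModel | None = None) -> SweepResult:
    """Detectability threshold of phonemic identity at decreasing sensitivity.

    For each k, voxels sensitive to k randomly chosen equally weighted
    units are simulated at the requested SNR; the identity-based VM (all
    units of the order, delay-stacked, HRF prior) and the phoneme-count VM
    are scored by nested cross-validation (every contiguous outer fold
    predicted at inner-CV-selected shrinkage).  The crossover is the
    smallest k at which the count model's mean R^2 reaches the identity
    model's.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = default_phonotactics(seed=int(rng.integers(2 ** 31)))
    annotation = gen_stream(model, n_tr, tr, seed=int(rng.integers(2 ** 31)))
    space, inv = _unit_design(annotation, order)
    k_grid = np.asarray(sorted(int(k) for k in k_grid))
    if k_grid[-1] > len(inv):
        raise ValueError(
            f"k up to {k_grid[-1]} requested but only {len(inv)} units of "
            f"order {order} realized in the stream")

    specs = []
    for k in k_grid:
        for _ in range(n_resample):
            units = tuple(inv.units[i] for i in
                          rng.choice(len(inv), size=int(k), replace=False))
            specs.append(VoxelSpec(order=order, units=units, snr=snr))
    sim = simulate_voxels(specs, annotation, lowpass_hz,
                          seed=int(rng.integers(2 ** 31)),
                          unit_features={order: (space, inv)})
    Y = zscore_per_story([sim.bold])[0].values

    design_id = stack_delays([space])
    design_cnt = stack_delays([phoneme_count_feature(annotation)])
    r2_id = nested_single_block_r2(design_id, Y, lambdas=SIM_LAMBDAS,
                                   outer_folds=outer_folds,
                                   inner_folds=inner_folds)
    r2_cnt = nested_single_block_r2(design_cnt, Y, lambdas=SIM_LAMBDAS,
                                    outer_folds=outer_folds,
                                    inner_folds=inner_folds)
    n_k = len(k_grid)
    identity_r2 = r2_id.reshape(n_k, n_resample)
    count_r2 = r2_cnt.reshape(n_k, n_resample)

    crossover, flag = None, None
    cnt_mean, id_mean = count_r2.mean(axis=1), identity_r2.mean(axis=1)
    hit = np.flatnonzero(cnt_mean >= id_mean)
    if len(hit) == 0:
        crossover, flag = float(k_grid[-1]), "no_crossover_in_range"
    else:
        crossover = float(k_grid[hit[0]])
        if hit[0] == 0:
            flag = "crossover_at_lower_boundary"
    return SweepResult(order=order, k_grid=k_grid, identity_r2=identity_r2,
                       count_r2=count_r2, crossover=crossover,
                       boundary_flag=flag, n_units_available=len(inv))


# ---------------------------------------------------------------------------
# Order recovery
# ---------------------------------------------------------------------------

DEFAULT_ORDER_RESAMPLES = {1: 30, 2: 50, 3: 150, 4: 150, 5: 150, 6: 150}


@dataclass
class OrderRecovery:
    """Recoverability of one n-gram order's voxel model."""

    order: int
    n_units: int
    val_r2: np.ndarray             # per resample
    weight_corr: np.ndarray        # per resample
    noise_ceiling: float
    recoverable: bool


def order_recovery(orders=(1, 2, 3, 4, 5, 6), k: int = 3,
                   n_resample: int | dict | None = None,
                   snr: float = DEFAULT_SNR, n_tr: int = DEFAULT_N_TR,
                   tr: float = DEFAULT_TR, seed: int = 0,
                   inner_folds: int = 5, holdout_frac: float = 0.2,
                   lowpass_hz: float = DEFAULT_LOWPASS_HZ,
                   model: PhonotacticModel | None = None
                   ) -> dict[int, OrderRecovery]:
    """Fit matched-order identity VMs to voxels of orders 1..6.

    Each simulated voxel responds to ``k`` equally weighted units of its
    order.  The matched VM is fit on the first (1 - holdout_frac) of the
    stream with inner-CV shrinkage selection and scored on the held-out
    tail; weight recovery is the correlation between per-unit recovered
    weights (summed over delays) and the ground-truth sensitivity vector.
    An order counts as recoverable when the mean held-out R^2 reaches half
    the noise ceiling snr / (snr + 1).
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = default_phonotactics(seed=int(rng.integers(2 ** 31)))
    annotation = gen_stream(model, n_tr, tr, seed=int(rng.integers(2 ** 31)))
    ceiling = snr / (snr + 1.0)
    if n_resample is None:
        resamples = dict(DEFAULT_ORDER_RESAMPLES)
    elif isinstance(n_resample, dict):
        resamples = {o: n_resample.get(o, 10) for o in orders}
    else:
        resamples = {o: int(n_resample) for o in orders}

    nt = annotation.n_tr
    split = int(round(nt * (1.0 - holdout_frac)))
    out: dict[int, OrderRecovery] = {}
    for order in orders:
        space, inv = _unit_design(annotation, order)
        n_res = resamples[order]
        if len(inv) < k:
            raise ValueError(f"only {len(inv)} units at order {order}")
        unit_idx = [rng.choice(len(inv), size=k, replace=False)
                    for _ in range(n_res)]
        specs = [VoxelSpec(order=order,
                           units=tuple(inv.units[i] for i in idx), snr=snr)
                 for idx in unit_idx]
        sim = simulate_voxels(specs, annotation, lowpass_hz,
                              seed=int(rng.integers(2 ** 31)),
                              unit_features={order: (space, inv)})
        Y = zscore_per_story([sim.bold])[0].values

        design = stack_delays([space])
        _, _, val_r2, weights = _heldout_fit(design, Y, split, inner_folds,
                                             return_weights=True)

        n_delays = len(design.delays)
        per_unit = weights.reshape(n_delays, len(inv), n_res).sum(axis=0)
        corr = np.empty(n_res)
        for vi, idx in enumerate(unit_idx):
            truth = np.zeros(len(inv))
            truth[idx] = 1.0
            w = per_unit[:, vi]
            if np.std(w) < 1e-300:
                corr[vi] = 0.0
            else:
                corr[vi] = float(np.corrcoef(truth, w)[0, 1])
        out[order] = OrderRecovery(
            order=order, n_units=len(inv), val_r2=val_r2, weight_corr=corr,
            noise_ceiling=ceiling,
            recoverable=bool(val_r2.mean() >= 0.5 * ceiling))
    return out


# ---------------------------------------------------------------------------
# End-to-end fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Small seeded end-to-end fixture with ground-truth voxel types."""

    annotation: StimulusAnnotation
    annotation_val: StimulusAnnotation
    spaces: dict                      # name -> FeatureSpace (training)
    spaces_val: dict
    bold: BoldRun
    bold_val: BoldRun
    voxel_types: list[str]
    lexicon: dict[str, np.ndarray]
    seed: int


def gen_fixture_bundle(seed: int = 0, n_tr: int = 400, n_val_tr: int = 150,
                       n_per_type: int = 10, snr: float = DEFAULT_SNR,
                       embedding_dim: int = 16) -> FixtureBundle:
    """Generate a compact mixed-voxel fixture for integration tests.

    Voxel groups (``n_per_type`` each): phoneme-count driven, single-phoneme
    identity, diphone identity, semantic (a random direction in embedding
    space), and pure noise.  Identity voxels respond to small unit sets
    chosen with occurrence weighting (diphone voxels to 12 units) so the
    ground truth stays identifiable at this short stream length.  All
    outputs are deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    model = default_phonotactics(seed=int(rng.integers(2 ** 31)),
                                 n_words=500)
    ann = gen_stream(model, n_tr, seed=int(rng.integers(2 ** 31)),
                     story_id="fixture-train")
    ann_val = gen_stream(model, n_val_tr, seed=int(rng.integers(2 ** 31)),
                         story_id="fixture-val")

    lexicon = {w: rng.standard_normal(embedding_dim)
               for w, _ in model.lexicon}

    from .stimulus_features import semantic_features

    # short fixtures keep only the most frequent diphones so the diphone
    # block stays estimable at a few hundred TRs
    counts: dict[str, int] = {}
    for t in extract_ngrams(ann, 2):
        counts[t.label] = counts.get(t.label, 0) + 1
    top = sorted(sorted(counts), key=lambda u: -counts[u])[:80]
    di_inv = NGramInventory(order=2, units=tuple(sorted(top)))
    ph_inv = NGramInventory.single_phonemes()

    def build_spaces(a):
        ph_space, _ = _unit_design(a, 1, ph_inv)
        di_events = [t for t in extract_ngrams(a, 2)
                     if t.label in di_inv.index]
        di_space = event_indicator_features(di_events, di_inv, a,
                                            name="diphone")
        return {
            "count": phoneme_count_feature(a),
            "phoneme": ph_space,
            "diphone": di_space,
            "semantic": semantic_features(a, lexicon),
        }

    spaces = build_spaces(ann)
    spaces_val = build_spaces(ann_val)

    types, drives_tr, drives_va = [], [], []
    for _ in range(n_per_type):
        types.append("count")
        drives_tr.append(spaces["count"].values[:, 0])
        drives_va.append(spaces_val["count"].values[:, 0])
    for _ in range(n_per_type):
        idx = rng.choice(len(ph_inv), size=3, replace=False)
        types.append("phoneme")
        drives_tr.append(spaces["phoneme"].values[:, idx].sum(axis=1))
        drives_va.append(spaces_val["phoneme"].values[:, idx].sum(axis=1))
    for _ in range(n_per_type):
        idx = rng.choice(len(di_inv), size=8, replace=False)
        types.append("diphone")
        drives_tr.append(spaces["diphone"].values[:, idx].sum(axis=1))
        drives_va.append(spaces_val["diphone"].values[:, idx].sum(axis=1))
    for _ in range(n_per_type):
        direction = rng.standard_normal(embedding_dim)
        types.append("semantic")
        drives_tr.append(spaces["semantic"].values @ direction)
        drives_va.append(spaces_val["semantic"].values @ direction)
    for _ in range(n_per_type):
        types.append("noise")
        drives_tr.append(np.zeros(ann.n_tr))
        drives_va.append(np.zeros(ann_val.n_tr))

    clean_tr = hemodynamic_transform(np.column_stack(drives_tr), ann.tr)
    clean_va = hemodynamic_transform(np.column_stack(drives_va), ann_val.tr)
    noise_vox = np.array([t == "noise" for t in types])
    sigma = noise_sigma_for_snr(clean_tr, ann.tr, snr)
    sigma[noise_vox] = 1.0
    bold = BoldRun(clean_tr + sigma * rng.standard_normal(clean_tr.shape),
                   tr=ann.tr, story_id=ann.story_id)
    bold_val = BoldRun(clean_va + sigma * rng.standard_normal(clean_va.shape),
                       tr=ann_val.tr, story_id=ann_val.story_id)
    return FixtureBundle(annotation=ann, annotation_val=ann_val,
                         spaces=spaces, spaces_val=spaces_val, bold=bold,
                         bold_val=bold_val, voxel_types=types,
                         lexicon=lexicon, seed=seed)
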