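"""Stimulus feature construction for voxelwise encoding models.

Parses time-aligned phoneme annotations and builds the TR-sampled feature
spaces used to predict BOLD responses: spectral band power, phoneme count,
phoneme/diphone/triphone indicator features, and word-embedding (semantic)
features.  All event-locked features are built as impulse trains on a fine
time grid and low-pass resampled to the TR grid with a windowed-sinc
(Lanczos) filter, then concatenated at multiple temporal delays to form the
finite-impulse-response design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("phonovox")

DEFAULT_TR = 2.0045
FINE_RATE = 100.0  # Hz, fine grid for impulse trains
DEFAULT_DELAYS = (2.0, 4.0, 6.0, 8.0)

# 39-symbol ARPAbet phoneme inventory (CMU pronouncing dictionary, stress
# stripped): 24 consonants and 15 vowels.
CONSONANTS = (
    "B", "CH", "D", "DH", "F", "G", "HH", "JH", "K", "L", "M", "N",
    "NG", "P", "R", "S", "SH", "T", "TH", "V", "W", "Y", "Z", "ZH",
)
VOWELS = (
    "AA", "AE", "AH", "AO", "AW", "AY", "EH", "ER", "EY", "IH", "IY",
    "OW", "OY", "UH", "UW",
)
PHONEME_INVENTORY = tuple(sorted(CONSONANTS + VOWELS))

NGRAM_SEP = "."

# word-relative roles of an n-gram token
ROLE_WHOLE_WORD = "whole_word"
ROLE_WORD_BEGINNING = "word_beginning"
ROLE_RESIDUE = "residue"

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhonemeEvent:
    """A single time-stamped phoneme with its word membership."""

    label: str
    onset: float
    offset: float
    word_index: int
    pos_in_word: int

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError(
                f"phoneme event {self.label!r}: onset {self.onset} must "
                f"precede offset {self.offset}"
            )


@dataclass
class StimulusAnnotation:
    """Time-aligned phoneme events plus the word sequence they spell."""

    events: list[PhonemeEvent]
    words: list[tuple[str, tuple[str, ...]]]
    story_id: str = "story"
    duration: float = 0.0
    tr: float = DEFAULT_TR

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.events:
            onsets = [e.onset for e in self.events]
            if any(b < a for a, b in zip(onsets, onsets[1:])):
                raise ValueError("events must be sorted by onset")
            max_off = max(e.offset for e in self.events)
            if self.duration < max_off - 1e-9:
                raise ValueError(
                    f"duration {self.duration} shorter than last event "
                    f"offset {max_off}"
                )
            for e in self.events:
                if not (0 <= e.word_index < len(self.words)):
                    raise ValueError(
                        f"event {e.label!r} addresses missing word "
                        f"{e.word_index}"
                    )

    @property
    def n_tr(self) -> int:
        return int(np.ceil(self.duration / self.tr - 1e-9))

    def tr_times(self) -> np.ndarray:
        """Times of the TR samples (grid points at bin starts)."""
        return np.arange(self.n_tr) * self.tr


@dataclass(frozen=True)
class NGramEvent:
    """One n-gram token: its dot-joined label, onset and word-relative role."""

    label: str
    onset: float
    role: str
    word_index: int


@dataclass
class NGramInventory:
    """Ordered list of n-gram unit labels with a label -> column index map."""

    order: int
    units: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.order not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"unsupported n-gram order {self.order}")
        if len(set(self.units)) != len(self.units):
            raise ValueError("inventory units must be unique")
        if not self.index:
            self.index = {u: i for i, u in enumerate(self.units)}

    def __len__(self) -> int:
        return len(self.units)

    @classmethod
    def single_phonemes(cls) -> "NGramInventory":
        return cls(order=1, units=PHONEME_INVENTORY)

    @classmethod
    def from_annotation(cls, annotation: "StimulusAnnotation",
                        order: int) -> "NGramInventory":
        """Inventory of the n-gram types realized in an annotation."""
        if order == 1:
            return cls.single_phonemes()
        seen = sorted({ev.label for ev in extract_ngrams(annotation, order)})
        return cls(order=order, units=tuple(seen))

    @staticmethod
    def n_possible(order: int) -> int:
        """Count of all ordered phoneme tuples of the given length."""
        return len(PHONEME_INVENTORY) ** order


@dataclass
class FeatureSpace:
    """A named block of TR-sampled regressors."""

    name: str
    values: np.ndarray  # (n_timepoints, n_features)
    unit_labels: tuple[str, ...]
    tr: float = DEFAULT_TR

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (time x feature)")
        if self.values.shape[1] != len(self.unit_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.unit_labels)} unit labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"feature space {self.name!r} has non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class DelayedDesign:
    """Delay-stacked design matrix with block and delay bookkeeping.

    Columns are grouped by feature-space block; within a block they are
    ordered delay-major (all features at the first delay, then the second,
    ...).  ``col_block`` and ``col_delay`` give, per column, the block index
    and the delay index, which is what the banded solver needs to apply
    per-block shrinkage and the per-delay temporal prior.
    """

    values: np.ndarray
    delays: tuple[float, ...]
    block_names: tuple[str, ...]
    block_slices: dict[str, slice]
    col_block: np.ndarray
    col_delay: np.ndarray
    tr: float = DEFAULT_TR

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names) -> "DelayedDesign":
        """Design restricted to the named blocks (column order preserved)."""
        names = tuple(names)
        unknown = set(names) - set(self.block_names)
        if unknown:
            raise KeyError(f"unknown blocks: {sorted(unknown)}")
        keep = [n for n in self.block_names if n in names]
        cols = np.concatenate(
            [np.arange(self.block_slices[n].start, self.block_slices[n].stop)
             for n in keep]
        ) if keep else np.array([], dtype=int)
        slices, start = {}, 0
        for n in keep:
            width = self.block_slices[n].stop - self.block_slices[n].start
            slices[n] = slice(start, start + width)
            start += width
        return DelayedDesign(
            values=self.values[:, cols],
            delays=self.delays,
            block_names=tuple(keep),
            block_slices=slices,
            col_block=np.concatenate(
                [np.full(slices[n].stop - slices[n].start, i)
                 for i, n in enumerate(keep)]
            ) if keep else np.array([], dtype=int),
            col_delay=self.col_delay[cols],
            tr=self.tr,
        )


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

#: labels treated as silences/pauses and skipped on read
PAUSE_LABELS = {"", "sp", "sil", "pause"}


def parse_annotation(path, inventory=PHONEME_INVENTORY,
                     overlap_tol: float = 1e-3) -> StimulusAnnotation:
    """Read a tab-separated annotation file.

    Header lines ``#story_id=``, ``#duration=``, ``#tr=`` precede the event
    rows ``onset<TAB>offset<TAB>phoneme<TAB>word_index<TAB>word``.  Pause
    rows (phoneme field in :data:`PAUSE_LABELS`) are skipped.  Words are
    reconstructed from runs of equal ``word_index``.
    """
    inventory = set(inventory)
    meta = {"story_id": "story", "duration": None, "tr": DEFAULT_TR}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key in ("duration", "tr"):
                    meta[key] = float(val)
                elif key == "story_id":
                    meta[key] = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}: {line!r}"
                )
            onset, offset = float(parts[0]), float(parts[1])
            label = parts[2].strip()
            if label in PAUSE_LABELS:
                continue
            if label not in inventory:
                raise ValueError(
                    f"{path}:{lineno}: unknown phoneme label {label!r}"
                )
            rows.append((onset, offset, label, int(parts[3]), parts[4]))

    prev_off = -np.inf
    prev_onset = -np.inf
    word_map: dict[int, tuple[str, list[str]]] = {}
    events = []
    for onset, offset, label, widx, word in rows:
        if onset < prev_onset:
            raise ValueError(f"{path}: events not sorted at onset {onset}")
        if onset < prev_off - overlap_tol:
            raise ValueError(
                f"{path}: event {label!r} at {onset} overlaps the previous "
                f"event (ends {prev_off}) by more than {overlap_tol}s"
            )
        prev_onset, prev_off = onset, offset
        entry = word_map.setdefault(widx, (word, []))
        pos = len(entry[1])
        entry[1].append(label)
        events.append(PhonemeEvent(label, onset, offset, widx, pos))

    # compact word indices to 0..n-1 in order of first appearance
    order = sorted(word_map, key=lambda w: min(
        e.onset for e in events if e.word_index == w))
    remap = {w: i for i, w in enumerate(order)}
    events = [
        PhonemeEvent(e.label, e.onset, e.offset, remap[e.word_index],
                     e.pos_in_word)
        for e in events
    ]
    words = [(word_map[w][0], tuple(word_map[w][1])) for w in order]
    duration = meta["duration"]
    if duration is None:
        duration = max((e.offset for e in events), default=0.0)
    return StimulusAnnotation(events=events, words=words,
                              story_id=meta["story_id"],
                              duration=duration, tr=meta["tr"])


def write_annotation(annotation: StimulusAnnotation, path) -> None:
    """Write an annotation in the TSV dialect read by :func:`parse_annotation`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#story_id={annotation.story_id}\n")
        fh.write(f"#duration={annotation.duration!r}\n")
        fh.write(f"#tr={annotation.tr!r}\n")
        for e in annotation.events:
            word = annotation.words[e.word_index][0]
            fh.write(f"{e.onset!r}\t{e.offset!r}\t{e.label}\t"
                     f"{e.word_index}\t{word}\n")


# ---------------------------------------------------------------------------
# N-gram extraction
# ---------------------------------------------------------------------------


def extract_ngrams(annotation: StimulusAnnotation, order: int,
                   cross_word: bool = False) -> list[NGramEvent]:
    """List the n-gram tokens of a phoneme stream.

    N-grams are consecutive phoneme runs *within* a word (the word-relative
    role taxonomy — whole words, word beginnings, residues — is only
    exhaustive under this convention).  ``cross_word=True`` additionally
    yields n-grams spanning word boundaries, all with role ``residue``.
    The token onset is the onset of its first phoneme.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    by_word: dict[int, list[PhonemeEvent]] = {}
    for e in annotation.events:
        by_word.setdefault(e.word_index, []).append(e)
    out: list[NGramEvent] = []
    for widx in sorted(by_word):
        evs = sorted(by_word[widx], key=lambda e: e.pos_in_word)
        n = len(evs)
        for start in range(n - order + 1):
            chunk = evs[start:start + order]
            label = NGRAM_SEP.join(e.label for e in chunk)
            if order == n:
                role = ROLE_WHOLE_WORD
            elif start == 0:
                role = ROLE_WORD_BEGINNING
            else:
                role = ROLE_RESIDUE
            out.append(NGramEvent(label, chunk[0].onset, role, widx))
    if cross_word:
        evs = annotation.events
        for i in range(len(evs) - order + 1):
            chunk = evs[i:i + order]
            if len({e.word_index for e in chunk}) > 1:
                label = NGRAM_SEP.join(e.label for e in chunk)
                out.append(NGramEvent(label, chunk[0].onset, ROLE_RESIDUE,
                                      chunk[0].word_index))
    out.sort(key=lambda t: t.onset)
    return out


# ---------------------------------------------------------------------------
# Lanczos (windowed-sinc) resampling
# ---------------------------------------------------------------------------


def lanczos_kernel(t: np.ndarray, cutoff: float, lobes: int = 3) -> np.ndarray:
    """Lanczos-windowed sinc, low-pass at ``cutoff`` Hz with ``lobes`` lobes."""
    t = np.asarray(t, dtype=float)
    half_width = lobes / (2.0 * cutoff)
    x = 2.0 * cutoff * t
    val = np.sinc(x) * np.sinc(x / lobes)
    return np.where(np.abs(t) < half_width, val, 0.0)


def lanczos_resample(signal: np.ndarray, t_src: np.ndarray,
                     t_dst: np.ndarray, lobes: int = 3,
                     cutoff: float | None = None) -> np.ndarray:
    """Windowed-sinc low-pass interpolation from ``t_src`` to ``t_dst``.

    The cutoff defaults to the Nyquist frequency of the destination grid
    (0.5 / mean destination spacing).  Each output row of interpolation
    weights is normalized to unit sum, so constants are preserved exactly.
    """
    signal = np.asarray(signal, dtype=float)
    t_src = np.asarray(t_src, dtype=float)
    t_dst = np.asarray(t_dst, dtype=float)
    if t_src.ndim != 1 or np.any(np.diff(t_src) <= 0):
        raise ValueError("t_src must be strictly increasing")
    if np.any(t_dst < t_src[0] - 1e-9) or np.any(t_dst > t_src[-1] + 1e-9):
        raise ValueError("t_dst outside the span of t_src")
    if cutoff is None:
        if len(t_dst) < 2:
            raise ValueError("cannot infer cutoff from a single t_dst point")
        cutoff = 0.5 / float(np.mean(np.diff(t_dst)))
    weights = lanczos_kernel(t_dst[:, None] - t_src[None, :], cutoff, lobes)
    norm = weights.sum(axis=1)
    norm[norm == 0] = 1.0
    weights /= norm[:, None]
    return weights @ signal


def _lanczos_row_norms(t_dst: np.ndarray, fine_times: np.ndarray,
                       cutoff: float, lobes: int) -> np.ndarray:
    """Sum of kernel weights over the fine grid, per destination sample."""
    dt = fine_times[1] - fine_times[0] if len(fine_times) > 1 else 1.0
    half_width = lobes / (2.0 * cutoff)
    norms = np.empty(len(t_dst))
    for j, t in enumerate(t_dst):
        lo = max(0, int(np.ceil((t - half_width - fine_times[0]) / dt)))
        hi = min(len(fine_times), int(np.floor(
            (t + half_width - fine_times[0]) / dt)) + 1)
        norms[j] = lanczos_kernel(t - fine_times[lo:hi], cutoff, lobes).sum()
    norms[norms == 0] = 1.0
    return norms


def _impulse_features(onsets_per_unit: list[np.ndarray],
                      amplitudes_per_unit: list[np.ndarray] | None,
                      n_tr: int, tr: float, duration: float,
                      fine_rate: float = FINE_RATE,
                      lobes: int = 3) -> np.ndarray:
    """TR-sampled Lanczos filtering of unit-area impulse trains.

    Impulses are snapped to a ``fine_rate`` grid with amplitude 1/dt (unit
    area), then resampled to the TR grid.  Exploits the fact that resampling
    an impulse train reduces to evaluating the (normalized) kernel at the
    impulse times, which avoids materializing the fine grid per unit.
    """
    dt = 1.0 / fine_rate
    n_fine = int(round(duration / dt))
    if n_fine < 1:
        raise ValueError("duration shorter than one fine-grid step")
    fine_times = np.arange(n_fine) * dt
    t_dst = np.arange(n_tr) * tr
    cutoff = 0.5 / tr
    norms = _lanczos_row_norms(t_dst, fine_times, cutoff, lobes)
    half_width = lobes / (2.0 * cutoff)

    out = np.zeros((n_tr, len(onsets_per_unit)))
    for u, onsets in enumerate(onsets_per_unit):
        if len(onsets) == 0:
            continue
        onsets = np.asarray(onsets, dtype=float)
        if np.any(onsets < -1e-9) or np.any(onsets > duration + 1e-9):
            bad = onsets[(onsets < -1e-9) | (onsets > duration + 1e-9)]
            raise ValueError(f"event onset {bad[0]} outside [0, {duration}]")
        snapped = np.clip(np.round(onsets / dt), 0, n_fine - 1) * dt
        amps = (np.ones(len(onsets)) if amplitudes_per_unit is None
                else np.asarray(amplitudes_per_unit[u], dtype=float))
        for t_e, a in zip(snapped, amps):
            lo = max(0, int(np.ceil((t_e - half_width) / tr)))
            hi = min(n_tr, int(np.floor((t_e + half_width) / tr)) + 1)
            if lo >= hi:
                continue
            idx = np.arange(lo, hi)
            k = lanczos_kernel(idx * tr - t_e, cutoff, lobes)
            out[idx, u] += a * k / (dt * norms[idx])
    return out


def event_indicator_features(events: list[NGramEvent],
                             inventory: NGramInventory,
                             annotation: StimulusAnnotation,
                             fine_rate: float = FINE_RATE,
                             name: str | None = None) -> FeatureSpace:
    """One low-passed impulse-train regressor per n-gram unit.

    A unit-area impulse is placed at each token's onset (the onset of its
    first phoneme) on the fine grid and Lanczos-resampled to the TR grid.
    Columns follow the inventory's index order.
    """
    onsets: list[list[float]] = [[] for _ in range(len(inventory))]
    for ev in events:
        if ev.label not in inventory.index:
            raise ValueError(f"event label {ev.label!r} not in inventory")
        onsets[inventory.index[ev.label]].append(ev.onset)
    values = _impulse_features(
        [np.asarray(o) for o in onsets], None, annotation.n_tr,
        annotation.tr, annotation.duration, fine_rate)
    return FeatureSpace(
        name=name or f"ngram{inventory.order}",
        values=values, unit_labels=inventory.units, tr=annotation.tr)


def phoneme_count_feature(annotation: StimulusAnnotation) -> FeatureSpace:
    """Phoneme onsets counted in half-open TR bins [t, t + TR)."""
    n_tr = annotation.n_tr
    counts = np.zeros((max(n_tr, 1), 1))
    for e in annotation.events:
        b = int(e.onset / annotation.tr)
        if 0 <= b < counts.shape[0]:
            counts[b, 0] += 1
    return FeatureSpace(name="count", values=counts[:n_tr] if n_tr else counts[:0],
                        unit_labels=("phoneme_count",), tr=annotation.tr)


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

SPECTRUM_F_LO = 25.0
SPECTRUM_F_HI = 15000.0
SPECTRUM_BAND_HZ = 33.5
SPECTRUM_SEGMENT_S = 2.0


def n_spectrum_bands(f_lo: float = SPECTRUM_F_LO, f_hi: float = SPECTRUM_F_HI,
                     band_hz: float = SPECTRUM_BAND_HZ) -> int:
    """Smallest number of contiguous bands from ``f_lo`` covering ``f_hi``."""
    return int(np.ceil((f_hi - f_lo) / band_hz))


def welch_band_power(waveform: np.ndarray, sample_rate: float,
                     tr: float = DEFAULT_TR,
                     n_tr: int | None = None,
                     segment_s: float = SPECTRUM_SEGMENT_S,
                     subseg_s: float = 0.25) -> FeatureSpace:
    """Per-TR band powers of the audio in contiguous 33.5 Hz bands.

    For each TR a ``segment_s``-long window anchored at the TR start is
    analyzed with Welch's method (Hann sub-windows of ``subseg_s`` with 50%
    overlap) and the PSD is integrated over each band.  Anchoring analysis
    segments at exact TR starts keeps the rows aligned with the TR grid by
    construction.
    """
    from scipy import signal as sps

    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if sample_rate < 2 * SPECTRUM_F_HI:
        raise ValueError(
            f"sample rate {sample_rate} below Nyquist requirement "
            f"{2 * SPECTRUM_F_HI}")
    seg_len = int(round(segment_s * sample_rate))
    if len(waveform) < seg_len:
        raise ValueError("audio shorter than one analysis segment")
    if n_tr is None:
        n_tr = int(np.floor(len(waveform) / sample_rate / tr))
    nper = int(round(subseg_s * sample_rate))
    n_bands = n_spectrum_bands()
    edges = SPECTRUM_F_LO + SPECTRUM_BAND_HZ * np.arange(n_bands + 1)

    rows = np.zeros((n_tr, n_bands))
    for j in range(n_tr):
        start = int(round(j * tr * sample_rate))
        seg = waveform[start:start + seg_len]
        if len(seg) < nper:  # tail shorter than one sub-window: pad
            seg = np.pad(seg, (0, nper - len(seg)))
        freqs, psd = sps.welch(seg, fs=sample_rate, window="hann",
                               nperseg=nper, noverlap=nper // 2)
        band_idx = np.searchsorted(edges, freqs, side="right") - 1
        df = freqs[1] - freqs[0]
        for b in range(n_bands):
            rows[j, b] = psd[band_idx == b].sum() * df
    labels = tuple(
        f"band_{edges[b]:.1f}_{edges[b + 1]:.1f}Hz" for b in range(n_bands))
    return FeatureSpace(name="spectrum", values=rows, unit_labels=labels,
                        tr=tr)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono PCM/float WAV file, returning (waveform, sample_rate)."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float), float(rate)


# ---------------------------------------------------------------------------
# Semantic features
# ---------------------------------------------------------------------------


def read_lexicon(path) -> dict[str, np.ndarray]:
    """Read a word-embedding table: word<TAB>v1<TAB>v2..., one row per word."""
    table: dict[str, np.ndarray] = {}
    dim = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            vec = np.array([float(x) for x in parts[1:]])
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(
                    f"lexicon row {parts[0]!r} has {len(vec)} dims, "
                    f"expected {dim}")
            table[parts[0]] = vec
    return table


def semantic_features(annotation: StimulusAnnotation,
                      lexicon: dict[str, np.ndarray],
                      fine_rate: float = FINE_RATE) -> FeatureSpace:
    """Word-embedding impulse features: each word drops its embedding vector
    at the word onset; the train is Lanczos-resampled to the TR grid.

    Words missing from the lexicon map to the zero vector (logged).
    """
    dims = {len(v) for v in lexicon.values()}
    if len(dims) > 1:
        raise ValueError(f"lexicon rows have mixed dimensions: {sorted(dims)}")
    dim = dims.pop() if dims else 0

    onsets, vecs = [], []
    missing = set()
    first_event: dict[int, PhonemeEvent] = {}
    for e in annotation.events:
        cur = first_event.get(e.word_index)
        if cur is None or e.pos_in_word < cur.pos_in_word:
            first_event[e.word_index] = e
    for widx in sorted(first_event):
        word = annotation.words[widx][0]
        vec = lexicon.get(word)
        if vec is None:
            missing.add(word)
            continue
        onsets.append(first_event[widx].onset)
        vecs.append(vec)
    if missing:
        logger.warning("semantic_features: %d word(s) not in lexicon, "
                       "mapped to zero: %s", len(missing),
                       sorted(missing)[:10])

    values = np.zeros((annotation.n_tr, dim))
    if onsets:
        amp = np.stack(vecs)  # (n_words, dim)
        values = _impulse_features(
            [np.asarray(onsets)] * dim,
            [amp[:, d] for d in range(dim)],
            annotation.n_tr, annotation.tr, annotation.duration, fine_rate)
    labels = tuple(f"sem_{d}" for d in range(dim))
    return FeatureSpace(name="semantic", values=values, unit_labels=labels,
                        tr=annotation.tr)


# ---------------------------------------------------------------------------
# Delay stacking
# ---------------------------------------------------------------------------


def stack_delays(spaces: list[FeatureSpace],
                 delays=DEFAULT_DELAYS,
                 tr: float | None = None) -> DelayedDesign:
    """Concatenate feature spaces at several temporal delays.

    Each delay is snapped to the nearest integer multiple of TR; a block's
    columns at delay ``d = k*TR`` hold the block values shifted forward by
    ``k`` rows (zero-padded at the start), so the design is a
    finite-impulse-response expansion of each feature.
    """
    delays = tuple(float(d) for d in delays)
    if spaces:
        nts = {s.n_timepoints for s in spaces}
        if len(nts) > 1:
            raise ValueError(f"inconsistent n_timepoints across blocks: {nts}")
        nt = nts.pop()
        trs = {round(s.tr, 9) for s in spaces}
        if len(trs) > 1:
            raise ValueError(f"inconsistent TR across blocks: {trs}")
        tr = trs.pop()
    else:
        nt = 0
        tr = tr if tr is not None else DEFAULT_TR

    shifts = [int(round(d / tr)) for d in delays]
    cols, names, slices, col_block, col_delay = [], [], {}, [], []
    start = 0
    for bi, space in enumerate(spaces):
        width = space.n_features * len(delays)
        for di, k in enumerate(shifts):
            shifted = np.zeros_like(space.values)
            if k == 0:
                shifted[:] = space.values
            elif k < nt:
                shifted[k:] = space.values[:nt - k]
            cols.append(shifted)
            col_block.extend([bi] * space.n_features)
            col_delay.extend([di] * space.n_features)
        names.append(space.name)
        slices[space.name] = slice(start, start + width)
        start += width
    values = np.concatenate(cols, axis=1) if cols else np.zeros((nt, 0))
    return DelayedDesign(
        values=values, delays=delays, block_names=tuple(names),
        block_slices=slices,
        col_block=np.asarray(col_block, dtype=int),
        col_delay=np.asarray(col_delay, dtype=int),
        tr=tr,
    )


def save_design(design: DelayedDesign, path) -> None:
    """Store a delayed design in a compressed .npz container."""
    np.savez_compressed(
        path,
        values=design.values,
        delays=np.asarray(design.delays),
        block_names=np.asarray(design.block_names),
        block_starts=np.asarray(
            [design.block_slices[n].start for n in design.block_names]),
        block_stops=np.asarray(
            [design.block_slices[n].stop for n in design.block_names]),
        col_block=design.col_block,
        col_delay=design.col_delay,
        tr=design.tr,
    )


def load_design(path) -> DelayedDesign:
    with np.load(path, allow_pickle=False) as z:
        names = tuple(str(n) for n in z["block_names"])
        slices = {
            n: slice(int(a), int(b))
            for n, a, b in zip(names, z["block_starts"], z["block_stops"])
        }
        return DelayedDesign(
            values=z["values"], delays=tuple(float(d) for d in z["delays"]),
            block_names=names, block_slices=slices,
            col_block=z["col_block"], col_delay=z["col_delay"],
            tr=float(z["tr"]),
        )
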