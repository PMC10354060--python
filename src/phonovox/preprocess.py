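"""BOLD response conditioning and repeat-based SNR estimation.

Covers the minimal temporal preprocessing the encoding models assume: slow
drift removal with a Savitzky-Golay filter, per-story z-scoring, and a
power-ratio SNR estimate obtained from the spectral coherence between two
presentations of the same stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .stimulus_features import DEFAULT_TR

logger = logging.getLogger("phonovox")


@dataclass
class BoldRun:
    """A (time x voxel) BOLD response matrix for one story."""

    values: np.ndarray
    tr: float = DEFAULT_TR
    story_id: str = "story"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be 2-D (time x voxel)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values contain non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(path, values=self.values, tr=self.tr,
                            story_id=self.story_id)

    @classmethod
    def load(cls, path) -> "BoldRun":
        with np.load(path, allow_pickle=False) as z:
            return cls(values=z["values"], tr=float(z["tr"]),
                       story_id=str(z["story_id"]))


@dataclass
class RepeatPair:
    """Two BOLD runs recorded for the identical stimulus."""

    rep1: BoldRun
    rep2: BoldRun

    def __post_init__(self):
        if self.rep1.values.shape != self.rep2.values.shape:
            raise ValueError("repeat shapes differ")
        if self.rep1.story_id != self.rep2.story_id:
            raise ValueError("repeats come from different stories")


def savgol_window_tr(tr: float, window_s: float = 120.0) -> int:
    """Savitzky-Golay window of ~``window_s`` seconds, rounded to odd TRs."""
    w = int(round(window_s / tr))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def savgol_detrend(run: BoldRun, order: int = 2,
                   window_s: float = 120.0) -> BoldRun:
    """Remove slow drift: subtract a local polynomial (Savitzky-Golay) fit.

    A second-order filter reproduces quadratic drifts exactly, so scanner
    drift up to quadratic within the window is eliminated.
    """
    window = savgol_window_tr(run.tr, window_s)
    if window >= run.n_timepoints:
        raise ValueError(
            f"run of {run.n_timepoints} TRs shorter than the "
            f"{window}-TR detrending window")
    trend = sps.savgol_filter(run.values, window_length=window,
                              polyorder=order, axis=0, mode="interp")
    return BoldRun(values=run.values - trend, tr=run.tr,
                   story_id=run.story_id)


def zscore_per_story(runs: list[BoldRun], ddof: int = 0) -> list[BoldRun]:
    """Standardize each voxel to zero mean / unit variance within each story.

    Constant voxels become all-zero columns (with a logged warning) rather
    than NaN.
    """
    out = []
    for run in runs:
        if run.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints to z-score")
        mu = run.values.mean(axis=0)
        sd = run.values.std(axis=0, ddof=ddof)
        const = sd < 1e-300
        n_const = int(const.sum())
        if n_const:
            logger.warning("zscore_per_story: %d constant voxel(s) in "
                           "story %s set to zero", n_const, run.story_id)
        sd_safe = np.where(const, 1.0, sd)
        z = (run.values - mu) / sd_safe
        z[:, const] = 0.0
        out.append(BoldRun(values=z, tr=run.tr, story_id=run.story_id))
    return out


def coherence_snr(pair: RepeatPair, band_hz: tuple[float, float] = (0.0, 0.1),
                  nperseg: int = 64) -> np.ndarray:
    """Per-voxel power SNR from the coherence between two stimulus repeats.

    The magnitude-squared coherence between the repeats is averaged over
    ``band_hz``.  Under a shared-signal-plus-independent-noise model with
    per-repeat power SNR, the coherence between the two *noisy* repeats is
    (SNR / (SNR + 1))^2 — each repeat contributes one factor of the
    signal fraction — so the estimate maps back through
    SNR = sqrt(C) / (1 - sqrt(C)).  The small-sample null bias is removed
    first with the rescaling ``C_corr = (L*C - 1) / (L - 1)`` (L = number
    of Welch segments), which has null expectation 0 and leaves C = 1
    fixed; it is clipped to [0, 1) before the mapping.
    """
    nt = pair.rep1.n_timepoints
    if nt < 32:
        raise ValueError(f"{nt} timepoints is too short for spectral "
                         "coherence estimation (need >= 32)")
    nperseg = min(nperseg, nt)
    noverlap = nperseg // 2
    fs = 1.0 / pair.rep1.tr
    n_seg = (nt - noverlap) // (nperseg - noverlap)

    x, y = pair.rep1.values, pair.rep2.values
    freqs, coh = sps.coherence(x, y, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=noverlap, axis=0)
    lo, hi = band_hz
    in_band = (freqs > lo) & (freqs <= hi)
    if not np.any(in_band):
        raise ValueError(f"no coherence frequencies inside band {band_hz}")
    c_mean = coh[in_band].mean(axis=0)
    if n_seg > 1:
        c_corr = (n_seg * c_mean - 1.0) / (n_seg - 1.0)
    else:
        c_corr = c_mean
    root = np.sqrt(np.clip(c_corr, 0.0, 1.0 - 1e-9))
    return root / (1.0 - root)


def load_bold_nifti(path, mask=None, tr: float | None = None,
                    story_id: str = "story") -> BoldRun:
    """Flatten a 4-D NIfTI image to a (time x voxel) run.

    ``mask`` may be a boolean 3-D array; by default all voxels are kept.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI volume")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    values = data[mask].T  # (time, voxel)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldRun(values=values, tr=tr, story_id=story_id)
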