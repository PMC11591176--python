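"""Beat-wise ECG preprocessing.

Implements the full preprocessing chain used by the experiments:

1. QRS detection and delineation (Pan-Tompkins-style detector on lead II,
   refined by a multi-lead argmax; ST junction from the integrated QRS
   energy envelope; T-wave end by the tangent method).
2. 3 s strip extraction with class- and split-dependent oversampling.
3. Single-beat extraction: a 375-sample window spanning 250 ms before to
   500 ms after the R peak, padded past the T-wave end with the T-end value.
4. Partial-beat segmentation into the five intra-beat segments
   (P, PQRS, QRS, QRST, PQRST) with constant continuation outside the span.
5. Two-beat composition: consecutive beats stacked channel-wise (24
   channels), the last beat wrapping to the first.
6. Lead subsetting in canonical lead order.
7. Global scalar standardisation fitted on training data only.

All sample intervals are 0-based and half-open; sampling rate is 500 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import (
    BeatAnnotation,
    EcgRecord,
    LEAD_NAMES,
    N_SAMPLES,
    SAMPLING_RATE,
)

logger = logging.getLogger(__name__)

STRIP_LEN = 1500  # 3 s at 500 Hz
BEAT_LEN = 375    # 750 ms at 500 Hz
BEAT_PRE = 125    # 250 ms before R
BEAT_POST = 250   # 500 ms after R

SEGMENT_KINDS = ("P", "PQRS", "QRS", "QRST", "PQRST")

#: Strips per record by (split role, EF class): the class-dependent
#: oversampling factors, chosen to rebalance the rarer reduced-EF classes.
OVERSAMPLING_FACTORS = {
    "train": {"pEF": 4, "mrEF": 7, "rEF": 6},
    "dev": {"pEF": 4, "mrEF": 16, "rEF": 11},
    "test": {"pEF": 4, "mrEF": 16, "rEF": 11},
}


@dataclass
class StripTensor:
    """A 12 x 1500 three-second excerpt of one record."""

    data: np.ndarray
    start_offset: int
    case_id: str
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != STRIP_LEN:
            raise ValueError(f"strip must have {STRIP_LEN} columns, "
                             f"got shape {self.data.shape}")
        if not 0 <= self.start_offset <= N_SAMPLES - STRIP_LEN:
            raise ValueError(f"strip window out of bounds at {self.start_offset}")


@dataclass
class BeatTensor:
    """A fixed-length beat-anchored tensor: C x 375.

    C is 12 for single/partial beats, 24 for two-beat compositions, and
    1-12 for reduced-lead tensors.  ``segment`` records which intra-beat
    segment is unmasked; ``leads`` the channel names of the rows (first-beat
    names only for two-beat tensors).
    """

    data: np.ndarray
    case_id: str
    record_id: str = ""
    beat_index: int = 0
    segment: str = "PQRST"
    leads: tuple[str, ...] = LEAD_NAMES
    annotation: BeatAnnotation | None = None
    window_start: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != BEAT_LEN:
            raise ValueError(f"beat tensor must have {BEAT_LEN} columns, "
                             f"got shape {self.data.shape}")
        if self.segment not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.segment!r}")
        c = self.data.shape[0]
        if c not in set(range(1, 13)) | {24}:
            raise ValueError(f"beat tensor must have 1-12 or 24 rows, got {c}")


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------

def _detect_r_peaks(sig: np.ndarray, fs: int = SAMPLING_RATE) -> np.ndarray:
    """Pan-Tompkins-style R detection on lead II, refined across leads.

    Band-pass -> derivative -> squaring -> moving-window integration ->
    threshold with a 250 ms refractory period; each candidate is then moved
    to the argmax of the mean absolute band-passed multi-lead signal within
    +/-60 ms.
    """
    lead_ii = sig[1]
    if np.ptp(lead_ii) < 1e-12:
        return np.array([], dtype=int)
    sos = sps.butter(2, [5.0, 20.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, lead_ii)
    energy = np.gradient(bp) ** 2
    win = int(0.15 * fs)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    if integ.max() <= 0:
        return np.array([], dtype=int)
    # zero-pad so maxima at the record edges (truncated first/last beats)
    # still register as peaks
    padded = np.concatenate(([0.0], integ, [0.0]))
    peaks, _ = sps.find_peaks(padded, height=0.2 * integ.max(),
                              distance=int(0.25 * fs))
    peaks = np.clip(peaks - 1, 0, len(integ) - 1)
    if peaks.size == 0:
        return peaks
    bp_all = sps.sosfiltfilt(sos, sig, axis=1)
    envelope = np.abs(bp_all).mean(axis=0)
    half = int(0.06 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(envelope), p + half + 1)
        refined.append(lo + int(np.argmax(envelope[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory separation after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= int(0.25 * fs):
            keep.append(r)
    return np.asarray(keep, dtype=int)


def _qrs_bounds(integ: np.ndarray, r: int, fs: int) -> tuple[int, int]:
    """QRS onset/ST junction from the integrated energy envelope: the first
    samples before/after R where the envelope falls below 5% of its R value,
    bounded to physiological search windows."""
    level = 0.05 * max(integ[r], 1e-12)
    lo_lim = max(0, r - int(0.10 * fs))
    onset = lo_lim
    for i in range(r, lo_lim - 1, -1):
        if integ[i] < level:
            onset = i
            break
    hi_lim = min(len(integ) - 1, r + int(0.14 * fs))
    st_j = hi_lim
    for i in range(r, hi_lim + 1):
        if integ[i] < level:
            st_j = i
            break
    return onset, st_j


def _t_end_tangent(sig_lp: np.ndarray, st_j: int, search_end: int,
                   fs: int) -> int | None:
    """T-wave end by the tangent method on a low-pass-filtered lead: the
    intersection of the steepest post-peak tangent with the local baseline."""
    lo = st_j + int(0.04 * fs)
    if search_end - lo < int(0.08 * fs):
        return None
    window = sig_lp[lo:search_end]
    baseline = np.median(sig_lp[max(0, lo - int(0.02 * fs)):lo + 1])
    rel = window - baseline
    t_peak = int(np.argmax(np.abs(rel)))
    if np.abs(rel[t_peak]) < 1e-6:
        return None
    tail = rel[t_peak:]
    if len(tail) < 3:
        return None
    slope = np.gradient(tail)
    # steepest return towards baseline
    if rel[t_peak] > 0:
        i = int(np.argmin(slope))
        s = slope[i]
        if s >= 0:
            return None
    else:
        i = int(np.argmax(slope))
        s = slope[i]
        if s <= 0:
            return None
    dt = -tail[i] / s
    t_end = lo + t_peak + i + int(round(dt))
    return int(np.clip(t_end, lo + t_peak + 1, search_end - 1))


def delineate(record: EcgRecord) -> list[BeatAnnotation]:
    """Detect beats and their fiducials; returns annotations sorted by R peak.

    A flat or beat-free record yields an empty list.  Beats whose fiducials
    cannot be placed consistently (e.g. truncated at the record edge) are
    dropped.
    """
    sig = record.signal
    fs = record.sampling_rate
    r_peaks = _detect_r_peaks(sig, fs)
    if r_peaks.size == 0:
        return []
    lead_ii = sig[1]
    sos = sps.butter(2, [5.0, 20.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, lead_ii)
    win = int(0.15 * fs)
    integ = np.convolve(np.gradient(bp) ** 2, np.ones(win) / win, mode="same")
    sos_lp = sps.butter(2, 10.0, btype="lowpass", fs=fs, output="sos")
    lp = sps.sosfiltfilt(sos_lp, lead_ii)

    annotations = []
    n = sig.shape[1]
    for k, r in enumerate(r_peaks):
        onset, st_j = _qrs_bounds(integ, int(r), fs)
        next_r = r_peaks[k + 1] if k + 1 < len(r_peaks) else n
        search_end = int(min(r + 0.45 * fs, next_r - 0.08 * fs, n - 1))
        t_end = _t_end_tangent(lp, st_j, search_end, fs)
        if t_end is None:
            t_end = int(min(r + 0.40 * fs, n - 1))
        if not (0 <= onset < r < st_j < t_end < n):
            logger.debug("dropping beat at %d: inconsistent fiducials", r)
            continue
        annotations.append(BeatAnnotation(r_peak=int(r), qrs_onset=int(onset),
                                          st_junction=int(st_j),
                                          t_end=int(t_end)))
    return annotations


# ---------------------------------------------------------------------------
# Strips
# ---------------------------------------------------------------------------

def oversample_offsets(n_segments: int, record_len: int = N_SAMPLES,
                       strip_len: int = STRIP_LEN) -> list[int]:
    """Evenly spaced, endpoint-inclusive strip start offsets.

    n offsets from 0 to record_len - strip_len with stride
    (record_len - strip_len)/(n-1), rounded to integer samples; n=1 gives
    the single offset 0.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if strip_len > record_len:
        raise ValueError("strip_len exceeds record_len")
    span = record_len - strip_len
    if n_segments == 1:
        return [0]
    return [int(round(i * span / (n_segments - 1))) for i in range(n_segments)]


def extract_strips(record: EcgRecord, ef_class: str | None = None,
                   split_role: str = "train") -> list[StripTensor]:
    """Cut the class/split-dependent number of 3 s strips from one record."""
    if split_role not in OVERSAMPLING_FACTORS:
        raise ValueError(f"split_role must be one of "
                         f"{sorted(OVERSAMPLING_FACTORS)}, got {split_role!r}")
    cls = ef_class if ef_class is not None else record.ef_class
    factors = OVERSAMPLING_FACTORS[split_role]
    if cls not in factors:
        raise ValueError(f"unknown EF class {cls!r}")
    n = factors[cls]
    return [StripTensor(data=record.signal[:, off:off + STRIP_LEN],
                        start_offset=off, case_id=record.case_id)
            for off in oversample_offsets(n)]


# ---------------------------------------------------------------------------
# Single beats, partial segments, two-beat composition
# ---------------------------------------------------------------------------

def extract_single_beats(record: EcgRecord,
                         annotations: list[BeatAnnotation]) -> list[BeatTensor]:
    """Cut 12 x 375 windows ([R-250 ms, R+500 ms)) around each beat.

    Samples at or past the T-wave end are replaced by the value at the
    T-end sample (per lead).  Beats whose window would leave the record are
    dropped and counted in the log.
    """
    beats = []
    dropped = 0
    for bi, ann in enumerate(annotations):
        start = ann.r_peak - BEAT_PRE
        stop = ann.r_peak + BEAT_POST
        if start < 0 or stop > record.signal.shape[1]:
            dropped += 1
            continue
        data = record.signal[:, start:stop].copy()
        k = ann.t_end - start
        if 0 <= k < BEAT_LEN:
            data[:, k:] = data[:, k][:, None]
        beats.append(BeatTensor(data=data, case_id=record.case_id,
                                beat_index=bi, annotation=ann,
                                window_start=start))
    if dropped:
        logger.info("%s: dropped %d beat(s) with out-of-bounds windows",
                    record.case_id, dropped)
    return beats


def _segment_span(annotation: BeatAnnotation, window_start: int,
                  kind: str) -> tuple[int, int]:
    """Half-open [lo, hi) span of a segment kind in window coordinates.

    The P/QRS boundary is 100 ms (50 samples) before the detected QRS onset.
    """
    b = annotation.qrs_onset - 50 - window_start
    j = annotation.st_junction - window_start
    t = min(annotation.t_end - window_start, BEAT_LEN)
    if not (0 < b < j < t <= BEAT_LEN):
        raise ValueError(
            f"segment boundaries out of order/bounds: b={b}, j={j}, t={t}")
    spans = {"P": (0, b), "QRS": (b, j), "QRST": (b, t),
             "PQRS": (0, j), "PQRST": (0, BEAT_LEN)}
    return spans[kind]


def make_partial(beat: BeatTensor, annotation: BeatAnnotation | None = None,
                 kind: str = "PQRST") -> BeatTensor:
    """Mask a single-beat tensor down to one intra-beat segment.

    Output stays C x 375: samples left of the span take the span's first
    value, samples right of it the span's last value (constant
    continuation), so one network input size serves all five segment kinds.
    """
    if kind not in SEGMENT_KINDS:
        raise ValueError(f"unknown segment kind {kind!r}")
    ann = annotation if annotation is not None else beat.annotation
    if ann is None:
        raise ValueError("beat has no annotation; pass one explicitly")
    lo, hi = _segment_span(ann, beat.window_start, kind)
    data = beat.data.copy()
    if lo > 0:
        data[:, :lo] = data[:, lo][:, None]
    if hi < BEAT_LEN:
        data[:, hi:] = data[:, hi - 1][:, None]
    return BeatTensor(data=data, case_id=beat.case_id,
                      record_id=beat.record_id, beat_index=beat.beat_index,
                      segment=kind, leads=beat.leads, annotation=ann,
                      window_start=beat.window_start)


def compose_two_beats(beats: list[BeatTensor]) -> list[BeatTensor]:
    """Stack consecutive beats channel-wise into 24 x 375 tensors.

    Item i holds beat i in rows 0-11 and beat i+1 in rows 12-23; the final
    beat wraps around to the first, so output count equals input count.
    """
    n = len(beats)
    out = []
    for i in range(n):
        nxt = beats[(i + 1) % n]
        data = np.vstack([beats[i].data, nxt.data])
        out.append(BeatTensor(data=data, case_id=beats[i].case_id,
                              record_id=beats[i].record_id,
                              beat_index=beats[i].beat_index,
                              segment=beats[i].segment,
                              leads=beats[i].leads,
                              annotation=beats[i].annotation,
                              window_start=beats[i].window_start))
    return out


def subset_leads(tensor: BeatTensor, leads) -> BeatTensor:
    """Restrict a 12-row beat tensor to a lead subset, in canonical order."""
    leads = set(leads)
    if not leads:
        raise ValueError("lead subset must be non-empty")
    unknown = leads - set(LEAD_NAMES)
    if unknown:
        raise ValueError(f"unknown lead names: {sorted(unknown)}")
    if tensor.data.shape[0] != 12:
        raise ValueError("lead subsetting requires a 12-row tensor")
    keep = [i for i, name in enumerate(LEAD_NAMES) if name in leads]
    names = tuple(LEAD_NAMES[i] for i in keep)
    return BeatTensor(data=tensor.data[keep], case_id=tensor.case_id,
                      record_id=tensor.record_id,
                      beat_index=tensor.beat_index, segment=tensor.segment,
                      leads=names, annotation=tensor.annotation,
                      window_start=tensor.window_start)


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

class GlobalStandardizer(BaseEstimator, TransformerMixin):
    """Scalar standardisation by the overall mean and SD of the training set.

    A single global mean and standard deviation are computed over every
    sample of every channel of the training tensors; validation and test
    data reuse the training statistics unchanged.
    """

    def fit(self, X, y=None):
        flat = self._flatten(X)
        if flat.size == 0:
            raise ValueError("cannot fit standardizer on empty data")
        self.mean_ = float(flat.mean())
        self.scale_ = float(flat.std())
        if self.scale_ <= 0:
            raise ValueError("training data is constant (sd = 0)")
        return self

    def transform(self, X):
        if not hasattr(self, "mean_"):
            raise ValueError("standardizer is not fitted")
        if isinstance(X, (list, tuple)):
            return [(np.asarray(x, dtype=float) - self.mean_) / self.scale_
                    for x in X]
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    @staticmethod
    def _flatten(X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            arrays = [np.asarray(getattr(x, "data", x), dtype=float).ravel()
                      for x in X]
            return np.concatenate(arrays) if arrays else np.array([])
        return np.asarray(X, dtype=float).ravel()


def fit_standardiser(train_tensors) -> GlobalStandardizer:
    """Fit the global scalar standardiser on training tensors/arrays."""
    arrays = [getattr(t, "data", t) for t in train_tensors] \
        if isinstance(train_tensors, (list, tuple)) else train_tensors
    return GlobalStandardizer().fit(arrays)


def apply_standardiser(standardiser: GlobalStandardizer, tensors):
    """Apply fitted training statistics to tensors/arrays (never refits)."""
    if isinstance(tensors, (list, tuple)):
        return [standardiser.transform(getattr(t, "data", t)) for t in tensors]
    return standardiser.transform(tensors)
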