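"""From raw impedance movies to segmented breaths.

A reconstructed EIT recording is a stack of pixel maps of relative impedance
(arbitrary units, AU) at a fixed sampling rate.  This module turns such a
movie into the objects the index calculations need:

* a zero-phase low-pass filtered copy (cardiac oscillations live above
  50 min⁻¹ and are removed before any breath-level analysis),
* the global impedance curve (sum over a pixel mask per frame),
* a breath segmentation (end-expiration minima and the end-inspiration
  maximum between them) with a selected run of consecutive artifact-free
  breaths, and
* the respiratory rate derived from the selected breaths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


class InsufficientBreathsError(ValueError):
    """Raised when a recording does not contain the required number of
    consecutive artifact-free breathing cycles."""


@dataclass(frozen=True)
class FrameSequence:
    """A reconstructed EIT movie: relative impedance per pixel per frame.

    ``frames`` has shape (n_frames, n_rows, n_cols); row 0 is ventral and the
    time axis is uniform with frame 0 the earliest sample.
    """

    frames: np.ndarray
    sampling_rate: float
    session_label: str = "t0"
    subject_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be (time, rows, cols), got shape {frames.shape}")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate


@dataclass(frozen=True)
class GlobalCurve:
    """Per-frame sum of impedance over an analysis mask."""

    values: np.ndarray
    sampling_rate: float
    mask_id: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class BreathSegmentation:
    """Breath landmarks on a global curve.

    ``breaths`` is an (n, 3) integer array of frame indices
    (start end-expiration, end-inspiration, end end-expiration); consecutive
    breaths share their boundary minima.  ``selected`` marks the longest run
    of consecutive artifact-free breaths used for all index calculations.
    """

    breaths: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.breaths, dtype=int)
        s = np.asarray(self.selected, dtype=bool)
        object.__setattr__(self, "breaths", b)
        object.__setattr__(self, "selected", s)
        if b.ndim != 2 or b.shape[1] != 3:
            raise ValueError("breaths must be an (n, 3) index array")
        if s.shape != (b.shape[0],):
            raise ValueError("selected must have one flag per breath")
        flat = b.reshape(-1)
        within = np.all(np.diff(b, axis=1) > 0)
        across = np.all(b[1:, 0] == b[:-1, 2]) if len(b) > 1 else True
        if not (within and across):
            raise ValueError("breath indices must increase and share boundary minima")

    @property
    def n_breaths(self) -> int:
        return self.breaths.shape[0]

    @property
    def selected_breaths(self) -> np.ndarray:
        return self.breaths[self.selected]


# ---------------------------------------------------------------------------
# filtering


def _lowpass_sos(cutoff_per_min: float, sampling_rate: float, order: int):
    cutoff_hz = cutoff_per_min / 60.0
    nyquist = sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"low-pass cutoff {cutoff_per_min} min⁻¹ ({cutoff_hz:.3f} Hz) is at or above "
            f"the Nyquist frequency {nyquist:.3f} Hz of a {sampling_rate} Hz recording"
        )
    return sps.butter(order, cutoff_hz, btype="low", fs=sampling_rate, output="sos")


def lowpass_filter(
    seq: FrameSequence, cutoff_per_min: float = 50.0, order: int = 4
) -> FrameSequence:
    """Zero-phase low-pass filter of every pixel trace.

    Realized as a forward-backward Butterworth filter, so landmark times are
    preserved (zero phase) and the DC gain is exactly 1.  The default cutoff
    of 50 min⁻¹ removes cardiac-frequency oscillations while leaving
    respiratory content (typically 10–35 min⁻¹) essentially untouched.
    """
    sos = _lowpass_sos(cutoff_per_min, seq.sampling_rate, order)
    filtered = sps.sosfiltfilt(sos, seq.frames, axis=0)
    return FrameSequence(
        frames=filtered,
        sampling_rate=seq.sampling_rate,
        session_label=seq.session_label,
        subject_id=seq.subject_id,
    )


def lowpass_curve(
    curve: GlobalCurve, cutoff_per_min: float = 50.0, order: int = 4
) -> GlobalCurve:
    """Same zero-phase low-pass applied to a global curve only."""
    sos = _lowpass_sos(cutoff_per_min, curve.sampling_rate, order)
    return GlobalCurve(
        values=sps.sosfiltfilt(sos, curve.values),
        sampling_rate=curve.sampling_rate,
        mask_id=curve.mask_id,
    )


# ---------------------------------------------------------------------------
# global curve


def compute_global_curve(seq: FrameSequence, mask: np.ndarray | None = None,
                         mask_id: str = "all") -> GlobalCurve:
    """Sum impedance over ``mask`` per frame (all pixels when mask is None)."""
    if mask is None:
        values = seq.frames.reshape(seq.n_frames, -1).sum(axis=1)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != seq.grid_shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid {seq.grid_shape}"
            )
        if not mask.any():
            raise ValueError("mask is empty")
        values = seq.frames[:, mask].sum(axis=1)
    return GlobalCurve(values=values, sampling_rate=seq.sampling_rate, mask_id=mask_id)


# ---------------------------------------------------------------------------
# breath detection


def detect_breaths(
    curve: GlobalCurve,
    min_breaths: int = 10,
    prominence_fraction: float = 0.10,
) -> BreathSegmentation:
    """Segment the (already filtered) global curve into breathing cycles.

    End-expirations are local minima, end-inspiration is the maximum between
    consecutive minima.  Extrema must have a prominence of at least
    ``prominence_fraction`` of the curve's median peak-to-trough excursion,
    which suppresses noise-born wiggles.  Partial breaths at the edges are
    discarded, breaths with outlying duration or amplitude are flagged as
    artifacts, and the longest run of consecutive clean breaths (earliest on
    ties) is marked selected.  Raises :class:`InsufficientBreathsError` when
    fewer than ``min_breaths`` consecutive clean cycles are found.
    """
    v = np.asarray(curve.values, dtype=float)
    rough_max, _ = sps.find_peaks(v)
    rough_min, _ = sps.find_peaks(-v)
    if len(rough_max) == 0 or len(rough_min) == 0:
        raise InsufficientBreathsError(
            "insufficient breaths: no oscillation found in the global curve"
        )
    swing = np.median(v[rough_max]) - np.median(v[rough_min])
    if swing <= 0:
        raise InsufficientBreathsError("insufficient breaths: curve has no tidal swing")
    minima, _ = sps.find_peaks(-v, prominence=prominence_fraction * swing)
    if len(minima) < 2:
        raise InsufficientBreathsError(
            f"insufficient breaths: {max(len(minima) - 1, 0)} complete cycle(s) found"
        )

    breaths = []
    for m0, m1 in zip(minima[:-1], minima[1:]):
        interior = v[m0 + 1 : m1]
        if interior.size == 0:
            continue
        peak = m0 + 1 + int(np.argmax(interior))
        if v[peak] <= max(v[m0], v[m1]):
            continue
        breaths.append((m0, peak, m1))
    if len(breaths) < 1:
        raise InsufficientBreathsError("insufficient breaths: no complete cycles")
    b = np.array(breaths, dtype=int)

    durations = (b[:, 2] - b[:, 0]).astype(float)
    amplitudes = v[b[:, 1]] - 0.5 * (v[b[:, 0]] + v[b[:, 2]])
    med_d = np.median(durations)
    med_a = np.median(amplitudes)
    clean = (
        (amplitudes >= 0.5 * med_a)
        & (durations >= 0.4 * med_d)
        & (durations <= 1.75 * med_d)
    )

    best_start, best_len = 0, 0
    run_start, run_len = 0, 0
    for i, ok in enumerate(clean):
        if ok:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    if best_len < min_breaths:
        raise InsufficientBreathsError(
            f"insufficient breaths: longest artifact-free run has {best_len} "
            f"cycle(s), {min_breaths} required"
        )
    selected = np.zeros(len(b), dtype=bool)
    selected[best_start : best_start + best_len] = True
    return BreathSegmentation(breaths=b, selected=selected)


def respiratory_rate(seg: BreathSegmentation, sampling_rate: float) -> float:
    """Breaths per minute: 60 over the mean selected breath duration."""
    sel = seg.selected_breaths
    if len(sel) < 2:
        raise ValueError("respiratory rate requires at least two selected breaths")
    durations = (sel[:, 2] - sel[:, 0]) / sampling_rate
    return 60.0 / float(np.mean(durations))
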