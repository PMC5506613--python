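"""Ventilation indices computed from a segmented EIT session.

The index set mirrors what functional-EIT weaning studies report:

* **Tidal image** ``DI_xy``: per-pixel impedance rise of a breath
  (end-inspiration minus the breath-start end-expiration), averaged over the
  selected breaths.
* **Lung mask**: pixels whose maximum tidal amplitude over all sessions of a
  study reaches a fraction (default 20%) of the global maximum.
* **TIV** (tidal impedance variation): breath-averaged global impedance
  swing, referenced to the baseline session = 100%.
* **ΔEELI**: change of the end-expiratory level (local minima of the global
  curve) versus baseline, normalized by the baseline TIV so that −65% means a
  loss of 0.65 baseline tidal swings.
* **IR** (impedance ratio): ventral over dorsal tidal impedance,
  (ROI1+ROI2)/(ROI3+ROI4), for static quartile bands and for bands adapted to
  the ventilated row extent (IR_adapt).
* **GI** (global inhomogeneity index): Σ|DI_xy − median(DI_lung)| / Σ DI_xy
  over lung pixels; 0 for perfectly homogeneous ventilation.  The raw value
  is ~0–1; results are conventionally reported ×100.
* **spRVD** (regional ventilation delay during spontaneous breathing): per
  pixel, the delay from the global inspiration onset until the pixel's
  impedance rise reaches a threshold (40/60/80%) of its tidal amplitude, as a
  percentage of the global inspiration duration; summarized across pixels by
  their standard deviation (heterogeneity) and mean.
* **RSBI_EIT**: respiratory rate over normalized TIV, the EIT analog of the
  rapid shallow breathing index (rises under rapid shallow breathing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .signals import (
    BreathSegmentation,
    FrameSequence,
    GlobalCurve,
    compute_global_curve,
    detect_breaths,
    lowpass_curve,
    lowpass_filter,
    respiratory_rate,
)

SESSION_LABELS = ("t0", "t1", "t2")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TidalImage:
    """Mean per-pixel inspiratory impedance change over selected breaths."""

    di: np.ndarray
    breath_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "di", np.asarray(self.di, dtype=float))


@dataclass(frozen=True)
class LungMask:
    """Pixels counted as lung: max tidal amplitude ≥ threshold · global max."""

    member: np.ndarray
    threshold_fraction: float
    source_sessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        member = np.asarray(self.member, dtype=bool)
        object.__setattr__(self, "member", member)
        if not member.any():
            raise ValueError("lung mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.member.sum())


@dataclass(frozen=True)
class ROIPartition:
    """Four horizontal bands numbered 1..4 from ventral (row 0) to dorsal.

    ``rows`` holds the (start, stop) half-open row range of each band.
    """

    rows: tuple[tuple[int, int], ...]
    mode: str = "static"

    def __post_init__(self) -> None:
        if len(self.rows) != 4:
            raise ValueError("partition must have exactly 4 bands")
        for (a, b), (c, _) in zip(self.rows[:-1], self.rows[1:]):
            if not (a < b and b == c):
                raise ValueError("bands must be contiguous, disjoint and non-empty")
        if not self.rows[-1][0] < self.rows[-1][1]:
            raise ValueError("bands must be non-empty")


@dataclass(frozen=True)
class SessionIndices:
    """The full index set of one session (time point)."""

    subject_id: str
    session_label: str
    rr: float
    tiv_au: float
    tiv_percent: float
    eeli_au: float
    delta_eeli_percent: float
    ir: float
    ir_adapt: float
    gi: float          # reported scale (raw × 100)
    gi_raw: float
    sp_rvd: dict       # threshold -> value of the configured summary
    sp_rvd_sd: dict    # threshold -> across-pixel SD, averaged over breaths
    sp_rvd_mean: dict  # threshold -> across-pixel mean, averaged over breaths
    rsbi_eit: float
    n_breaths_selected: int
    rvd_unreached: int

    def as_row(self) -> dict:
        """Flatten to one table row (per-threshold columns expanded)."""
        row = {
            "subject_id": self.subject_id,
            "session_label": self.session_label,
            "rr": self.rr,
            "tiv_au": self.tiv_au,
            "tiv_percent": self.tiv_percent,
            "eeli_au": self.eeli_au,
            "delta_eeli_percent": self.delta_eeli_percent,
            "ir": self.ir,
            "ir_adapt": self.ir_adapt,
            "gi": self.gi,
            "gi_raw": self.gi_raw,
            "rsbi_eit": self.rsbi_eit,
            "n_breaths_selected": self.n_breaths_selected,
            "rvd_unreached": self.rvd_unreached,
        }
        for thr in sorted(self.sp_rvd):
            row[f"sp_rvd_{thr}"] = self.sp_rvd[thr]
            row[f"sp_rvd_sd_{thr}"] = self.sp_rvd_sd[thr]
            row[f"sp_rvd_mean_{thr}"] = self.sp_rvd_mean[thr]
        return row


@dataclass(frozen=True)
class BaselineRefs:
    """Baseline (t0) quantities that non-baseline sessions are referred to."""

    tiv_au: float
    eeli_au: float


@dataclass(frozen=True)
class RVDResult:
    """Regional ventilation delay summaries for one threshold."""

    threshold_percent: float
    sd: float
    mean: float
    per_breath_sd: np.ndarray
    per_breath_mean: np.ndarray
    n_unreached: int


# ---------------------------------------------------------------------------
# operations


def tidal_image(seq: FrameSequence, seg: BreathSegmentation) -> TidalImage:
    """Per-breath end-inspiration minus breath-start frame, breath-averaged."""
    sel = seg.selected_breaths
    ids = tuple(int(i) for i in np.flatnonzero(seg.selected))
    if len(sel) == 0:
        raise ValueError("no selected breaths to form a tidal image")
    di = np.mean(
        [seq.frames[ei] - seq.frames[s] for s, ei, _ in sel], axis=0
    )
    return TidalImage(di=di, breath_ids=ids)


def build_lung_mask(
    tidal_images: Sequence[TidalImage],
    threshold_fraction: float = 0.20,
    source_sessions: Sequence[str] = (),
) -> LungMask:
    """Threshold the per-pixel maximum tidal amplitude across sessions.

    A pixel is lung when its maximum DI over the supplied tidal images is at
    least ``threshold_fraction`` of the global maximum (boundary inclusive).
    """
    if len(tidal_images) == 0:
        raise ValueError("at least one tidal image required")
    stack = np.stack([t.di for t in tidal_images])
    max_di = stack.max(axis=0)
    global_max = float(max_di.max())
    if global_max <= 0:
        raise ValueError("all tidal images are non-positive; no ventilated region")
    member = max_di >= threshold_fraction * global_max
    return LungMask(
        member=member,
        threshold_fraction=threshold_fraction,
        source_sessions=tuple(source_sessions),
    )


def static_partition(grid_shape: tuple[int, int]) -> ROIPartition:
    """Four static bands of 25% of the grid rows each."""
    n_rows = grid_shape[0]
    if n_rows % 4 != 0:
        raise ValueError(f"static quartile bands need rows divisible by 4, got {n_rows}")
    h = n_rows // 4
    rows = tuple((i * h, (i + 1) * h) for i in range(4))
    return ROIPartition(rows=rows, mode="static")


def adapted_partition(mask: LungMask) -> ROIPartition:
    """Split the ventilated row extent into 4 equal-height bands.

    When the extent is not divisible by 4 the remainder rows are assigned to
    the dorsal-most bands (a stable, documented rule).
    """
    row_any = mask.member.any(axis=1)
    rows_idx = np.flatnonzero(row_any)
    first, last = int(rows_idx[0]), int(rows_idx[-1])
    n = last - first + 1
    if n < 4:
        raise ValueError(f"ventilated extent spans {n} row(s); 4 bands need at least 4")
    base, rem = divmod(n, 4)
    heights = [base] * 4
    for k in range(rem):  # remainder to the dorsal-most bands
        heights[3 - k] += 1
    bounds = []
    start = first
    for h in heights:
        bounds.append((start, start + h))
        start += h
    return ROIPartition(rows=tuple(bounds), mode="adapted")


def impedance_ratio(img: TidalImage, part: ROIPartition) -> float:
    """Ventral over dorsal tidal impedance: (ΣROI1+ΣROI2)/(ΣROI3+ΣROI4)."""
    sums = [float(img.di[a:b].sum()) for a, b in part.rows]
    ventral = sums[0] + sums[1]
    dorsal = sums[2] + sums[3]
    if dorsal == 0:
        raise ZeroDivisionError("IR undefined: dorsal tidal impedance sums to zero")
    return ventral / dorsal


def tiv(
    curve: GlobalCurve,
    seg: BreathSegmentation,
    baseline_tiv_au: float | None = None,
) -> tuple[float, float]:
    """Tidal impedance variation in AU and as % of the baseline session.

    The AU value is the mean, over selected breaths, of the global curve at
    end-inspiration minus at the breath-start end-expiration.  When
    ``baseline_tiv_au`` is None this session *is* the baseline and the
    percentage is 100 by definition.
    """
    sel = seg.selected_breaths
    if len(sel) == 0:
        raise ValueError("no selected breaths")
    v = curve.values
    swings = v[sel[:, 1]] - v[sel[:, 0]]
    tiv_au = float(np.mean(swings))
    if tiv_au <= 0:
        raise ValueError("invalid breath landmarks: non-positive tidal swing")
    if baseline_tiv_au is None:
        return tiv_au, 100.0
    return tiv_au, 100.0 * tiv_au / baseline_tiv_au


def session_eeli(curve: GlobalCurve, seg: BreathSegmentation) -> float:
    """Mean global-curve value at the selected end-expiration minima."""
    sel = seg.selected_breaths
    if len(sel) == 0:
        raise ValueError("no selected breaths")
    return float(np.mean(curve.values[sel[:, 0]]))


def delta_eeli(
    curve: GlobalCurve,
    seg: BreathSegmentation,
    baseline_eeli_au: float,
    baseline_tiv_au: float,
) -> tuple[float, float]:
    """End-expiratory level change vs baseline, in AU and % of baseline TIV."""
    eeli_au = session_eeli(curve, seg)
    change = eeli_au - baseline_eeli_au
    return eeli_au, 100.0 * change / baseline_tiv_au


def gi(img: TidalImage, mask: LungMask) -> float:
    """Global inhomogeneity index (raw, ~0–1 scale).

    Sum of absolute deviations of lung-pixel DI from their median, divided by
    the total lung-pixel DI.  Report ×100 for the conventional scale.
    """
    vals = img.di[mask.member]
    total = float(vals.sum())
    if total <= 0:
        raise ValueError("GI undefined: lung-pixel DI sums to a non-positive value")
    med = float(np.median(vals))
    return float(np.sum(np.abs(vals - med))) / total


def regional_ventilation_delay(
    seq: FrameSequence,
    seg: BreathSegmentation,
    mask: LungMask,
    threshold_percent: float = 40.0,
) -> RVDResult:
    """Per-pixel inspiratory delay map, summarized across pixels.

    For every selected breath and lung pixel, the delay Δt is measured from
    the global inspiration onset (the breath-start end-expiration minimum of
    the global curve) to the first time the pixel's impedance rise reaches
    ``threshold_percent`` of that pixel's tidal amplitude; the crossing time
    is linearly interpolated between samples.  RVD = Δt / (global inspiration
    duration) × 100, clamped to [0, 100].  A pixel's own end-expiration may
    precede the global minimum, so the per-pixel baseline is searched in a
    short look-back window before the breath start.  Pixels that never reach
    the threshold within the breath are set to 100 and counted in
    ``n_unreached``.  Per-breath across-pixel SD and mean are averaged over
    the selected breaths.
    """
    q = threshold_percent / 100.0
    if not 0 < q < 1:
        raise ValueError("threshold_percent must be in (0, 100)")
    sel = seg.selected_breaths
    if len(sel) == 0:
        raise ValueError("no selected breaths")
    pix = mask.member
    sds, means = [], []
    n_unreached = 0
    for s, ei, ee in sel:
        insp_len = ei - s
        lookback = min(int(s), max(1, round(0.25 * (ee - s))))
        w = seq.frames[s - lookback : ee + 1][:, pix]  # (L, P)
        onset = lookback  # index of the global breath start within the window
        insp_end = onset + insp_len
        # per-pixel end-expiration: minimum from the look-back up to global
        # end-inspiration (captures delayed and slightly advanced pixels)
        pre = w[: insp_end + 1]
        jmin = np.argmin(pre, axis=0)
        base = pre[jmin, np.arange(w.shape[1])]
        amp = w.max(axis=0) - base
        ok_amp = amp > 0
        rel = np.zeros_like(w)
        rel[:, ok_amp] = (w[:, ok_amp] - base[ok_amp]) / amp[ok_amp]
        above = rel >= q
        t_idx = np.arange(w.shape[0])[:, None]
        above &= t_idx >= jmin[None, :]
        reached = above.any(axis=0) & ok_amp
        first = np.argmax(above, axis=0)

        cols = np.arange(w.shape[1])
        j = first
        jm1 = np.maximum(j - 1, 0)
        r1 = rel[j, cols]
        r0 = rel[jm1, cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(r1 > r0, (q - r0) / (r1 - r0), 0.0)
        t_cross = jm1 + np.clip(frac, 0.0, 1.0)
        t_cross = np.where(j == jm1, j.astype(float), t_cross)

        delta = t_cross - onset  # samples since global inspiration onset
        rvd = 100.0 * delta / insp_len
        rvd = np.where(reached, rvd, 100.0)
        n_unreached += int(np.sum(~reached))
        rvd = np.clip(rvd, 0.0, 100.0)
        sds.append(float(np.std(rvd)))
        means.append(float(np.mean(rvd)))
    return RVDResult(
        threshold_percent=threshold_percent,
        sd=float(np.mean(sds)),
        mean=float(np.mean(means)),
        per_breath_sd=np.asarray(sds),
        per_breath_mean=np.asarray(means),
        n_unreached=n_unreached,
    )


def sp_rvd(
    seq: FrameSequence,
    seg: BreathSegmentation,
    mask: LungMask,
    threshold_percent: float = 40.0,
    summary: str = "sd",
) -> float:
    """spRVD for one threshold under the chosen across-pixel summary."""
    res = regional_ventilation_delay(seq, seg, mask, threshold_percent)
    if summary == "sd":
        return res.sd
    if summary == "mean":
        return res.mean
    raise ValueError(f"summary must be 'sd' or 'mean', got {summary!r}")


def rsbi_eit(rr: float, tiv_percent: float) -> float:
    """Respiratory rate over normalized TIV (TIV%/100).

    Defined in this direction so the index rises under rapid shallow
    breathing (higher rate, lower tidal swing), matching its clinical use.
    """
    if tiv_percent <= 0:
        raise ValueError("tiv_percent must be positive")
    return rr / (tiv_percent / 100.0)


# ---------------------------------------------------------------------------
# session / study orchestration


def _prepare(seq: FrameSequence, mask: np.ndarray | None, cfg: RunConfig):
    """Filter, build the global curve over ``mask`` and segment it."""
    if cfg.pixelwise_filter:
        filt = lowpass_filter(seq, cfg.cutoff_per_min, cfg.filter_order)
        curve = compute_global_curve(filt, mask, mask_id="lung" if mask is not None else "all")
    else:
        filt = seq
        curve = compute_global_curve(seq, mask, mask_id="lung" if mask is not None else "all")
        curve = lowpass_curve(curve, cfg.cutoff_per_min, cfg.filter_order)
    seg = detect_breaths(curve, cfg.min_breaths, cfg.prominence_fraction)
    return filt, curve, seg


def analyze_session(
    seq: FrameSequence,
    mask: LungMask | None = None,
    baseline: BaselineRefs | None = None,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> SessionIndices:
    """Run the full index pipeline on one session.

    ``mask`` is normally shared across the three sessions of a study (built
    from the maximum tidal extent); when omitted it is built from this
    session alone.  ``baseline`` must be given for non-baseline sessions
    (anything not labelled t0); for the baseline session TIV% is 100 and
    ΔEELI is 0 by definition.
    """
    if seq.session_label != "t0" and baseline is None:
        raise ValueError(
            f"session {seq.session_label!r} of subject {seq.subject_id!r} needs "
            "baseline references (t0 TIV and EELI); none were provided"
        )
    if mask is None:
        filt0, curve0, seg0 = _prepare(seq, None, cfg)
        timg0 = tidal_image(filt0, seg0)
        mask = build_lung_mask([timg0], cfg.mask_threshold_fraction, (seq.session_label,))
    filt, curve, seg = _prepare(seq, mask.member, cfg)
    return _session_indices(filt, curve, seg, mask, baseline, cfg)


def _session_indices(
    filt: FrameSequence,
    curve: GlobalCurve,
    seg: BreathSegmentation,
    mask: LungMask,
    baseline: BaselineRefs | None,
    cfg: RunConfig,
) -> SessionIndices:
    timg = tidal_image(filt, seg)
    rr = respiratory_rate(seg, filt.sampling_rate)
    tiv_au, tiv_percent = tiv(
        curve, seg, None if baseline is None else baseline.tiv_au
    )
    if baseline is None:
        eeli_au = session_eeli(curve, seg)
        delta_pct = 0.0
    else:
        eeli_au, delta_pct = delta_eeli(curve, seg, baseline.eeli_au, baseline.tiv_au)
    ir = impedance_ratio(timg, static_partition(filt.grid_shape))
    ir_ad = impedance_ratio(timg, adapted_partition(mask))
    gi_raw = gi(timg, mask)
    rvd_sd, rvd_mean, rvd_summary = {}, {}, {}
    unreached = 0
    for thr in cfg.rvd_thresholds:
        res = regional_ventilation_delay(filt, seg, mask, thr)
        rvd_sd[thr] = res.sd
        rvd_mean[thr] = res.mean
        rvd_summary[thr] = res.sd if cfg.rvd_summary == "sd" else res.mean
        unreached += res.n_unreached
    return SessionIndices(
        subject_id=filt.subject_id,
        session_label=filt.session_label,
        rr=rr,
        tiv_au=tiv_au,
        tiv_percent=tiv_percent,
        eeli_au=eeli_au,
        delta_eeli_percent=delta_pct,
        ir=ir,
        ir_adapt=ir_ad,
        gi=100.0 * gi_raw,
        gi_raw=gi_raw,
        sp_rvd=rvd_summary,
        sp_rvd_sd=rvd_sd,
        sp_rvd_mean=rvd_mean,
        rsbi_eit=rsbi_eit(rr, tiv_percent),
        n_breaths_selected=int(seg.selected.sum()),
        rvd_unreached=unreached,
    )


@dataclass(frozen=True)
class StudyResult:
    """Indices of all sessions of one subject plus the shared lung mask."""

    indices: dict  # session_label -> SessionIndices
    mask: LungMask
    baseline: BaselineRefs


def analyze_study(
    seqs: Mapping[str, FrameSequence],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> StudyResult:
    """Analyze the t0/t1/t2 sessions of one subject with a shared lung mask.

    First pass: filter each session and form its tidal image from a
    whole-image segmentation.  The lung mask is the maximum tidal extent over
    all supplied sessions.  Second pass: global curves over the shared mask,
    re-segmentation, and the full index set with t0 as the baseline.
    """
    if "t0" not in seqs:
        raise ValueError("a study requires a t0 baseline session")
    labels = [l for l in SESSION_LABELS if l in seqs] + [
        l for l in seqs if l not in SESSION_LABELS
    ]
    prepared = {}
    timgs = []
    for label in labels:
        filt, curve, seg = _prepare(seqs[label], None, cfg)
        prepared[label] = filt
        timgs.append(tidal_image(filt, seg))
    mask = build_lung_mask(timgs, cfg.mask_threshold_fraction, tuple(labels))

    indices: dict[str, SessionIndices] = {}
    baseline: BaselineRefs | None = None
    for label in labels:
        filt = prepared[label]
        curve = compute_global_curve(filt, mask.member, mask_id="lung")
        if not cfg.pixelwise_filter:
            curve = lowpass_curve(curve, cfg.cutoff_per_min, cfg.filter_order)
        seg = detect_breaths(curve, cfg.min_breaths, cfg.prominence_fraction)
        if label == "t0":
            idx = _session_indices(filt, curve, seg, mask, None, cfg)
            baseline = BaselineRefs(tiv_au=idx.tiv_au, eeli_au=idx.eeli_au)
        else:
            idx = _session_indices(filt, curve, seg, mask, baseline, cfg)
        indices[label] = idx
    assert baseline is not None
    return StudyResult(indices=indices, mask=mask, baseline=baseline)
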