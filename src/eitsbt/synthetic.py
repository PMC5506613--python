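"""Synthetic thorax phantoms and virtual cohorts with known ground truth.

The phantom emulates a reconstructed EIT recording of a spontaneously
breathing subject: tidal pixel oscillation with a spatial amplitude map over
two elliptical lung fields, per-pixel inspiratory delays (pure phase shifts),
a cardiogenic oscillation above the 50 min⁻¹ analysis cutoff, per-breath
end-expiratory baseline (EELI) offsets, and additive Gaussian noise.  Every
frame is

    frame(t, x, y) = eeli(t)·A_xy/ΣA + A_xy·w(t − τ_xy) + cardiac(t)·A_xy/ΣA + noise

where ``w`` is a periodic raised-cosine breath waveform rising from 0 to 1
during inspiration and returning to 0 during expiration.  The EELI and
cardiac terms are distributed over lung pixels in proportion to their tidal
amplitude, so on the lung-masked global curve they appear with exactly the
programmed amplitude (in AU of that curve).

Ground truth for every index is computed analytically from the phantom
parameters — never from the generated movie — so pipeline outputs can be
checked by parameter recovery.

The virtual cohort emulates the three-session weaning-trial protocol
(t0 baseline on pressure support, t1 T-piece trial, t2 return to pressure
support): per patient, t1 parameters are the t0 parameters transformed by
configurable effects (tidal amplitude factor, EELI shift, respiratory-rate
increment, inhomogeneity inflation, delay-spread inflation) and t2 returns
toward t0.  Baseline GI scores are drawn lognormally per outcome group, which
gives a closed-form (binormal on the log scale) theoretical AUC stored with
the cohort; tidal volumes at t0/t2 are drawn from group-conditional normal
models so that realized deterioration labels (V_T drop ≥ 20 ml) match the
latent group in all but a negligible fraction of draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .indices import LungMask, gi as gi_index, TidalImage, static_partition, impedance_ratio
from .signals import FrameSequence

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "GIDistribution",
    "T1Effects",
    "T2Effects",
    "VTModel",
    "CohortSpec",
    "SessionParams",
    "PatientInput",
    "Cohort",
    "breath_waveform",
    "lung_ellipse_map",
    "default_phantom_spec",
    "generate_phantom",
    "analytic_ground_truth",
    "generate_cohort",
    "build_phantom_spec",
]


# ---------------------------------------------------------------------------
# phantom


def breath_waveform(phase: np.ndarray, inspiration_fraction: float) -> np.ndarray:
    """Raised-cosine breath waveform on phase in [0, 1).

    Rises 0→1 over ``inspiration_fraction`` of the cycle and falls 1→0 over
    the remainder; smooth extrema keep peak detection well-posed.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    fi = inspiration_fraction
    insp = phase < fi
    out = np.empty_like(phase)
    out[insp] = 0.5 * (1.0 - np.cos(np.pi * phase[insp] / fi))
    out[~insp] = 0.5 * (1.0 + np.cos(np.pi * (phase[~insp] - fi) / (1.0 - fi)))
    return out


def lung_ellipse_map(grid_shape: tuple[int, int] = (32, 32)) -> np.ndarray:
    """Uniform unit-amplitude map over two elliptical lung fields."""
    rows, cols = grid_shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    r0 = (rows - 1) / 2.0
    a_r, a_c = 0.33 * rows, 0.18 * cols
    left = ((r - r0) / a_r) ** 2 + ((c - 0.30 * (cols - 1)) / a_c) ** 2 <= 1.0
    right = ((r - r0) / a_r) ** 2 + ((c - 0.70 * (cols - 1)) / a_c) ** 2 <= 1.0
    return (left | right).astype(float)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic EIT recording.

    ``lung_amplitude_map`` is the per-pixel tidal amplitude in arbitrary
    impedance units (AU), non-zero only inside the lung fields;
    ``delay_map`` holds per-pixel inspiratory delays in seconds (zero where
    the amplitude is zero); ``eeli_trajectory`` is a per-breath baseline
    offset of the lung-masked global curve in AU.  ``cardiac_amplitude`` is
    likewise the amplitude the cardiac oscillation has on the global curve.
    """

    lung_amplitude_map: np.ndarray
    delay_map: np.ndarray
    respiratory_rate: float = 23.5
    inspiration_fraction: float = 0.5
    eeli_trajectory: np.ndarray | None = None
    cardiac_rate: float = 90.0
    cardiac_amplitude: float = 0.0
    noise_sd: float = 0.0
    sampling_rate: float = 20.0
    duration: float = 45.0
    seed: int = 0
    session_label: str = "t0"
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        amp = np.asarray(self.lung_amplitude_map, dtype=float)
        delay = np.asarray(self.delay_map, dtype=float)
        object.__setattr__(self, "lung_amplitude_map", amp)
        object.__setattr__(self, "delay_map", delay)
        if amp.shape != delay.shape:
            raise ValueError("amplitude and delay maps must share one grid shape")
        if np.any(amp < 0):
            raise ValueError("tidal amplitudes must be non-negative")
        if np.any(delay < 0):
            raise ValueError("inspiratory delays must be non-negative")
        if np.any((amp == 0) & (delay != 0)):
            raise ValueError("delays must be zero where the amplitude is zero")
        if not 0 < self.inspiration_fraction < 1:
            raise ValueError("inspiration_fraction must be in (0, 1)")
        if self.respiratory_rate <= 0 or self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("rates and duration must be positive")
        if self.n_breaths < 12:
            raise ValueError(
                f"duration {self.duration} s covers only {self.n_breaths} full "
                f"breaths at {self.respiratory_rate} min⁻¹; at least 12 required"
            )
        if self.eeli_trajectory is not None:
            object.__setattr__(
                self, "eeli_trajectory", np.asarray(self.eeli_trajectory, dtype=float)
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.lung_amplitude_map.shape

    @property
    def breath_period(self) -> float:
        return 60.0 / self.respiratory_rate

    @property
    def inspiration_duration(self) -> float:
        return self.inspiration_fraction * self.breath_period

    @property
    def n_breaths(self) -> int:
        return int(np.floor(self.duration / self.breath_period))

    @property
    def lung_mask(self) -> np.ndarray:
        return self.lung_amplitude_map > 0


@dataclass(frozen=True)
class GroundTruth:
    """Index values computed analytically from a :class:`PhantomSpec`."""

    expected_tiv: float
    expected_gi: float
    expected_rvd_map: dict            # threshold -> % map (delay fraction)
    expected_ir: float
    expected_eeli_offsets: np.ndarray
    lung_mask: np.ndarray
    expected_di: np.ndarray
    expected_rr: float


def _analytic_landmarks(spec: PhantomSpec, n_dense: int = 4096):
    """Analytic end-expiration/end-inspiration times of the noiseless global
    curve over one breath period, from a dense evaluation of the closed-form
    superposition (independent of the movie's sampling and noise)."""
    T = spec.breath_period
    amp = spec.lung_amplitude_map
    mask = spec.lung_mask
    taus = spec.delay_map[mask]
    amps = amp[mask]
    uniq = np.unique(taus)
    t = np.linspace(0.0, T, n_dense, endpoint=False)
    g = np.zeros(n_dense)
    for tau in uniq:
        weight = amps[taus == tau].sum()
        g += weight * breath_waveform((t - tau) / T, spec.inspiration_fraction)
    t_ee = t[int(np.argmin(g))]
    t_ei = t[int(np.argmax(g))]
    return t_ee, t_ei


def analytic_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Evaluate every expected index directly from the phantom parameters."""
    T = spec.breath_period
    mask = spec.lung_mask
    t_ee, t_ei = _analytic_landmarks(spec)
    w_ei = breath_waveform((t_ei - spec.delay_map) / T, spec.inspiration_fraction)
    w_ee = breath_waveform((t_ee - spec.delay_map) / T, spec.inspiration_fraction)
    di = spec.lung_amplitude_map * (w_ei - w_ee)
    di[~mask] = 0.0
    expected_tiv = float(di.sum())
    lmask = LungMask(member=mask, threshold_fraction=0.0)
    expected_gi = gi_index(TidalImage(di=di, breath_ids=()), lmask)
    rows = spec.grid_shape[0]
    if rows % 4 == 0:
        expected_ir = impedance_ratio(
            TidalImage(di=di, breath_ids=()), static_partition(spec.grid_shape)
        )
    else:
        expected_ir = float("nan")
    # RVD ground truth: programmed delay as a fraction of inspiration time,
    # identical for every threshold by construction.
    rvd = np.zeros(spec.grid_shape)
    rvd[mask] = 100.0 * spec.delay_map[mask] / spec.inspiration_duration
    rvd = np.clip(rvd, 0.0, 100.0)
    traj = (
        np.zeros(spec.n_breaths)
        if spec.eeli_trajectory is None
        else np.asarray(spec.eeli_trajectory, dtype=float)
    )
    return GroundTruth(
        expected_tiv=expected_tiv,
        expected_gi=expected_gi,
        expected_rvd_map={40: rvd, 60: rvd, 80: rvd},
        expected_ir=expected_ir,
        expected_eeli_offsets=traj,
        lung_mask=mask.copy(),
        expected_di=di,
        expected_rr=spec.respiratory_rate,
    )


def generate_phantom(spec: PhantomSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render the phantom movie and its analytic ground truth.

    Two calls with equal specs (including the seed) produce bit-identical
    frame stacks.
    """
    T = spec.breath_period
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    mask = spec.lung_mask
    amps = spec.lung_amplitude_map[mask]
    taus = spec.delay_map[mask]
    total_amp = float(amps.sum())
    if total_amp <= 0:
        raise ValueError("phantom has no ventilated pixels")

    lung_traces = np.zeros((n, amps.size))
    for tau in np.unique(taus):
        sel = taus == tau
        wave = breath_waveform((t - tau) / T, spec.inspiration_fraction)
        lung_traces[:, sel] = wave[:, None] * amps[sel][None, :]

    # EELI offsets and cardiac oscillation, distributed ∝ amplitude so the
    # lung-masked global curve carries them with the programmed AU amplitude.
    share = amps / total_amp
    if spec.eeli_trajectory is not None:
        traj = np.asarray(spec.eeli_trajectory, dtype=float)
        breath_idx = np.minimum((t // T).astype(int), len(traj) - 1)
        lung_traces += traj[breath_idx][:, None] * share[None, :]
    if spec.cardiac_amplitude > 0:
        cardiac = spec.cardiac_amplitude * np.sin(
            2.0 * np.pi * (spec.cardiac_rate / 60.0) * t
        )
        lung_traces += cardiac[:, None] * share[None, :]

    frames = np.zeros((n,) + spec.grid_shape)
    frames[:, mask] = lung_traces
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)

    seq = FrameSequence(
        frames=frames,
        sampling_rate=fs,
        session_label=spec.session_label,
        subject_id=spec.subject_id,
    )
    return seq, analytic_ground_truth(spec)


def default_phantom_spec(**overrides) -> PhantomSpec:
    """A 32×32 two-ellipse phantom with unit amplitudes and no delays."""
    grid = overrides.pop("grid_shape", (32, 32))
    amp = overrides.pop("lung_amplitude_map", None)
    if amp is None:
        amp = lung_ellipse_map(grid)
    delay = overrides.pop("delay_map", None)
    if delay is None:
        delay = np.zeros_like(np.asarray(amp, dtype=float))
    return PhantomSpec(lung_amplitude_map=amp, delay_map=delay, **overrides)


# ---------------------------------------------------------------------------
# virtual cohort

_Z_AUC_073 = float(norm.ppf(0.73))
_NEG_LOG_MEAN = math.log(43.0)
_LOG_SD = 0.55
_POS_LOG_MEAN = _NEG_LOG_MEAN + _Z_AUC_073 * _LOG_SD * math.sqrt(2.0)


@dataclass(frozen=True)
class GIDistribution:
    """Lognormal baseline-GI model per outcome group (reported ×100 scale).

    Log-GI is normal within each group, so the theoretical AUC of GI versus
    the group label is the binormal closed form on the log scale — and AUC is
    invariant under the monotone exponential, hence exact for GI itself.  The
    defaults place the non-deteriorating group at median 43 and separate the
    deteriorating group so that the theoretical AUC is 0.73.
    """

    neg_log_mean: float = _NEG_LOG_MEAN
    neg_log_sd: float = _LOG_SD
    pos_log_mean: float = _POS_LOG_MEAN
    pos_log_sd: float = _LOG_SD

    def theoretical_auc(self) -> float:
        delta = self.pos_log_mean - self.neg_log_mean
        spread = math.hypot(self.neg_log_sd, self.pos_log_sd)
        return float(norm.cdf(delta / spread))

    @classmethod
    def with_theoretical_auc(cls, auc: float, neg_log_mean: float = _NEG_LOG_MEAN,
                             log_sd: float = _LOG_SD) -> "GIDistribution":
        delta = float(norm.ppf(auc)) * log_sd * math.sqrt(2.0)
        return cls(neg_log_mean, log_sd, neg_log_mean + delta, log_sd)


@dataclass(frozen=True)
class T1Effects:
    """Multiplicative/additive shifts applied during the T-piece trial."""

    tiv_factor: float = 0.72
    eeli_shift_tiv: float = -0.65   # units of the t0 tidal swing
    rr_increment: float = 2.5
    gi_factor: float = 81.5 / 59.3
    delay_factor: float = 16.98 / 12.55


@dataclass(frozen=True)
class T2Effects:
    """Residual shifts after return to pressure support (near-recovery)."""

    tiv_factor: float = 0.99
    eeli_shift_tiv: float = -0.01
    rr_increment: float = 0.5
    gi_factor: float = 57.1 / 59.3
    delay_factor: float = 12.66 / 12.55


@dataclass(frozen=True)
class VTModel:
    """Group-conditional tidal-volume model (ml): baseline and t2 change."""

    pos_baseline_mean: float = 531.0
    pos_baseline_sd: float = 60.0
    neg_baseline_mean: float = 425.0
    neg_baseline_sd: float = 60.0
    pos_change_mean: float = -57.0
    pos_change_sd: float = 20.0
    neg_change_mean: float = 55.0
    neg_change_sd: float = 25.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a virtual weaning cohort."""

    n_patients: int = 31
    deterioration_fraction: float = 13.0 / 31.0
    gi_model: GIDistribution = field(default_factory=GIDistribution)
    t1_effects: T1Effects = field(default_factory=T1Effects)
    t2_effects: T2Effects = field(default_factory=T2Effects)
    vt_model: VTModel = field(default_factory=VTModel)
    grid_shape: tuple[int, int] = (32, 32)
    sampling_rate: float = 20.0
    duration: float = 45.0
    inspiration_fraction: float = 0.5
    baseline_rr_mean: float = 23.5
    baseline_rr_sd: float = 3.0
    # Ventral→dorsal linear delay ramp, as a fraction of inspiration time.
    # Over the elliptical lungs the row-pixel weighting is semicircular, so
    # the across-pixel delay SD is spread·25(%); 0.50 targets spRVD SD ≈12.5.
    delay_spread_fraction: float = 0.50
    amp_scale_log_sd: float = 0.2
    hotspot_fraction: float = 0.3
    noise_sd_fraction: float = 0.05       # of the mean lung-pixel amplitude
    cardiac_fraction: float = 0.05        # of the global tidal swing
    cardiac_rate: float = 90.0
    gi_session_jitter_sd: float = 0.15    # lognormal jitter of t1/t2 factors
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.deterioration_fraction < 1:
            raise ValueError("deterioration_fraction must be in (0, 1)")
        exp_pos = self.n_patients * self.deterioration_fraction
        exp_neg = self.n_patients - exp_pos
        if exp_pos < 2 or exp_neg < 2:
            raise ValueError(
                "cohort must expect at least 2 patients per outcome group "
                f"(expected {exp_pos:.1f} positive / {exp_neg:.1f} negative); "
                "ROC analysis is undefined otherwise"
            )


@dataclass(frozen=True)
class SessionParams:
    """Compact, fully deterministic recipe for one session's phantom."""

    gi_movie_raw: float        # clipped raw GI realized in the amplitude map
    amp_scale: float           # AU per pixel of the cold lung pixels
    delay_fraction: float      # delay spread as a fraction of inspiration time
    rr: float
    eeli_shift_tiv: float      # EELI offset in units of the t0 tidal swing
    movie_seed: int


@dataclass(frozen=True)
class PatientInput:
    """One virtual patient: latent outcome, tidal volumes, GI scores and the
    three per-session phantom recipes."""

    subject_id: str
    latent_deteriorated: bool
    vt_t0: float
    vt_t2: float
    gi_scores: dict            # session -> drawn GI (reported scale)
    sessions: dict             # session -> SessionParams
    hotspot_seed: int


@dataclass(frozen=True)
class Cohort:
    patients: list
    theoretical_auc: float
    spec: CohortSpec


def _hotspot_map(spec: CohortSpec, patient: PatientInput, gi_raw: float,
                 amp_scale: float) -> np.ndarray:
    """Amplitude map realizing a target raw GI with a fixed hot-spot set.

    A fraction f of lung pixels gets amplitude h, the rest 1; with
    x = f·(h−1) the map's GI is x/(1+x), so h = 1 + g/(f·(1−g)).  The map is
    then rescaled to a mean lung amplitude of ``amp_scale``, so the total
    tidal amplitude is independent of the inhomogeneity target (GI is
    scale-invariant) and session TIV factors act exactly.  The hot-pixel set
    is drawn once per patient so the lung mask stays stable across sessions.
    """
    base = lung_ellipse_map(spec.grid_shape)
    lung = np.flatnonzero(base.reshape(-1) > 0)
    rng = np.random.default_rng(patient.hotspot_seed)
    n_hot = int(round(spec.hotspot_fraction * lung.size))
    hot = rng.choice(lung, size=n_hot, replace=False)
    g = float(np.clip(gi_raw, 1e-6, 0.999))
    h = 1.0 + g / (spec.hotspot_fraction * (1.0 - g))
    amp = base.copy()
    amp.reshape(-1)[hot] *= h
    amp *= amp_scale * lung.size / amp.sum()
    return amp


def _delay_ramp(amp: np.ndarray, delay_spread_s: float) -> np.ndarray:
    """Linear ventral→dorsal delay ramp over the ventilated rows."""
    mask = amp > 0
    rows_idx = np.flatnonzero(mask.any(axis=1))
    first, last = rows_idx[0], rows_idx[-1]
    span = max(int(last - first), 1)
    row_delay = (np.arange(amp.shape[0]) - first) / span * delay_spread_s
    delay = np.clip(row_delay, 0.0, None)[:, None] * np.ones(amp.shape[1])[None, :]
    delay[~mask] = 0.0
    return delay


def _session_map_and_truth(spec: CohortSpec, patient: PatientInput, session: str):
    """Amplitude/delay maps of one session plus their analytic ground truth."""
    p = patient.sessions[session]
    amp = _hotspot_map(spec, patient, p.gi_movie_raw, p.amp_scale)
    period = 60.0 / p.rr
    delay = _delay_ramp(amp, p.delay_fraction * spec.inspiration_fraction * period)
    gt = analytic_ground_truth(
        PhantomSpec(
            lung_amplitude_map=amp,
            delay_map=delay,
            respiratory_rate=p.rr,
            inspiration_fraction=spec.inspiration_fraction,
            sampling_rate=spec.sampling_rate,
            duration=spec.duration,
        )
    )
    return amp, delay, gt


def build_phantom_spec(
    spec: CohortSpec, patient: PatientInput, session: str
) -> PhantomSpec:
    """Construct the PhantomSpec of one patient session from its recipe.

    For t1/t2 the amplitude map is calibrated against the analytic global
    tidal swing so that the session's analytic TIV is exactly the programmed
    factor times the t0 analytic TIV: regional desynchronization (the wider
    t1 delay spread) would otherwise shrink the global swing on top of the
    amplitude factor.  GI is scale-invariant, so the calibration leaves the
    inhomogeneity target untouched.
    """
    p = patient.sessions[session]
    amp, delay, gt = _session_map_and_truth(spec, patient, session)
    eeli = None
    if session != "t0":
        t0 = patient.sessions["t0"]
        _, _, gt0 = _session_map_and_truth(spec, patient, "t0")
        target_tiv = (p.amp_scale / t0.amp_scale) * gt0.expected_tiv
        amp = amp * (target_tiv / gt.expected_tiv)
        if p.eeli_shift_tiv != 0.0:
            period = 60.0 / p.rr
            n_breaths = int(np.floor(spec.duration / period)) + 1
            eeli = np.full(n_breaths, p.eeli_shift_tiv * gt0.expected_tiv)

    mean_amp = float(amp[amp > 0].mean())
    return PhantomSpec(
        lung_amplitude_map=amp,
        delay_map=delay,
        respiratory_rate=p.rr,
        inspiration_fraction=spec.inspiration_fraction,
        eeli_trajectory=eeli,
        cardiac_rate=spec.cardiac_rate,
        cardiac_amplitude=spec.cardiac_fraction * float(amp.sum()),
        noise_sd=spec.noise_sd_fraction * mean_amp,
        sampling_rate=spec.sampling_rate,
        duration=spec.duration,
        seed=p.movie_seed,
        session_label=session,
        subject_id=patient.subject_id,
    )


# Movie-level GI targets are clipped so the cold lung pixels stay inside the
# 20%-of-max lung mask: raw GI 0.50 gives a hot/cold amplitude ratio of 4.33,
# i.e. cold pixels at 23% of the maximum — above the threshold with margin.
_GI_MOVIE_CLIP = (0.03, 0.50)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a virtual cohort: labels, GI scores, tidal volumes, phantoms.

    Latent deterioration labels are Bernoulli(``deterioration_fraction``);
    baseline GI is drawn from the group-conditional lognormal model; t1/t2 GI
    applies the session effects with a mild lognormal jitter; tidal volumes
    follow the group-conditional V_T model.  Phantom recipes (amplitude
    scale, respiratory rate, delay spread, EELI shift, movie seed) are drawn
    per patient and transformed by the session effects.  The movie-level GI
    target is the drawn score clipped to what a 20%-threshold lung mask can
    express; the drawn (unclipped) score remains the canonical baseline GI.
    """
    rng = np.random.default_rng(spec.seed)
    gim = spec.gi_model
    patients: list[PatientInput] = []
    for i in range(spec.n_patients):
        latent = bool(rng.random() < spec.deterioration_fraction)
        log_mu = gim.pos_log_mean if latent else gim.neg_log_mean
        log_sd = gim.pos_log_sd if latent else gim.neg_log_sd
        gi_t0 = float(np.exp(rng.normal(log_mu, log_sd)))
        jit1 = float(np.exp(rng.normal(0.0, spec.gi_session_jitter_sd)))
        jit2 = float(np.exp(rng.normal(0.0, spec.gi_session_jitter_sd)))
        gi_t1 = gi_t0 * spec.t1_effects.gi_factor * jit1
        gi_t2 = gi_t0 * spec.t2_effects.gi_factor * jit2

        vtm = spec.vt_model
        if latent:
            vt0 = rng.normal(vtm.pos_baseline_mean, vtm.pos_baseline_sd)
            change = rng.normal(vtm.pos_change_mean, vtm.pos_change_sd)
        else:
            vt0 = rng.normal(vtm.neg_baseline_mean, vtm.neg_baseline_sd)
            change = rng.normal(vtm.neg_change_mean, vtm.neg_change_sd)
        vt0 = max(vt0, 50.0)
        vt2 = max(vt0 + change, 50.0)

        amp_scale = float(np.exp(rng.normal(0.0, spec.amp_scale_log_sd)))
        # lower clip keeps ≥12 full breaths inside the default 45 s recording
        rr0 = float(np.clip(rng.normal(spec.baseline_rr_mean, spec.baseline_rr_sd),
                            17.0, 40.0))
        seeds = rng.integers(0, 2**31, size=4)

        def clip_gi(x: float) -> float:
            return float(np.clip(x / 100.0, *_GI_MOVIE_CLIP))

        t1, t2 = spec.t1_effects, spec.t2_effects
        sessions = {
            "t0": SessionParams(
                gi_movie_raw=clip_gi(gi_t0),
                amp_scale=amp_scale,
                delay_fraction=spec.delay_spread_fraction,
                rr=rr0,
                eeli_shift_tiv=0.0,
                movie_seed=int(seeds[1]),
            ),
            "t1": SessionParams(
                gi_movie_raw=clip_gi(gi_t1),
                amp_scale=amp_scale * t1.tiv_factor,
                delay_fraction=spec.delay_spread_fraction * t1.delay_factor,
                rr=rr0 + t1.rr_increment,
                eeli_shift_tiv=t1.eeli_shift_tiv,
                movie_seed=int(seeds[2]),
            ),
            "t2": SessionParams(
                gi_movie_raw=clip_gi(gi_t2),
                amp_scale=amp_scale * t2.tiv_factor,
                delay_fraction=spec.delay_spread_fraction * t2.delay_factor,
                rr=rr0 + t2.rr_increment,
                eeli_shift_tiv=t2.eeli_shift_tiv,
                movie_seed=int(seeds[3]),
            ),
        }
        patients.append(
            PatientInput(
                subject_id=f"p{i + 1:03d}",
                latent_deteriorated=latent,
                vt_t0=float(vt0),
                vt_t2=float(vt2),
                gi_scores={"t0": gi_t0, "t1": gi_t1, "t2": gi_t2},
                sessions=sessions,
                hotspot_seed=int(seeds[0]),
            )
        )
    return Cohort(
        patients=patients,
        theoretical_auc=gim.theoretical_auc(),
        spec=spec,
    )
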