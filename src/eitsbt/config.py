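"""Run configuration: analysis parameters, defaults, and YAML round-tripping.

Every tunable of the offline analysis lives here so that a run is fully
described by one small, hashable object.  The defaults encode the standard
analysis settings: a 50 min⁻¹ low-pass to remove cardiac oscillations, at
least ten consecutive breaths per session, a lung mask at 20% of the maximum
pixel tidal amplitude, RVD thresholds of 40/60/80% of each pixel's tidal
rise, and a decision cutoff on the baseline global inhomogeneity index (GI,
reported ×100) of 41.5.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All analysis parameters with their documented defaults.

    Attributes
    ----------
    cutoff_per_min:
        Low-pass cutoff in min⁻¹ applied to remove cardiac-frequency content.
    filter_order:
        Butterworth order of the (forward-backward, hence zero-phase) filter.
    pixelwise_filter:
        If True (default) the filter is applied to every pixel trace, so tidal
        images and regional delay maps also use filtered signals; if False
        only the global impedance curve is filtered.
    mask_threshold_fraction:
        A pixel belongs to the lung mask when its maximum tidal amplitude over
        all sessions reaches this fraction of the global maximum (inclusive).
    rvd_thresholds:
        Percentages of the per-pixel tidal rise at which regional delays are
        read off (spRVD40/60/80).
    rvd_summary:
        Across-pixel summary of the regional delay map reported as "the"
        spRVD value: "sd" (heterogeneity reading, default) or "mean".
    delta_eeli_normalization:
        How end-expiratory level changes are scaled: "baseline_tiv" divides
        the impedance change by the baseline tidal impedance variation.
    min_breaths:
        Minimum number of consecutive artifact-free breaths a session must
        provide; sessions below this are rejected.
    prominence_fraction:
        Minimum prominence of breath extrema as a fraction of the median
        peak-to-trough excursion of the global curve.
    roc_cutoff:
        Baseline-GI decision cutoff (reported scale) used when an operating
        point is requested; classification rule is score > cutoff.
    seed:
        Seed for every source of randomness in simulation.
    """

    cutoff_per_min: float = 50.0
    filter_order: int = 4
    pixelwise_filter: bool = True
    mask_threshold_fraction: float = 0.20
    rvd_thresholds: tuple[int, ...] = (40, 60, 80)
    rvd_summary: str = "sd"
    delta_eeli_normalization: str = "baseline_tiv"
    min_breaths: int = 10
    prominence_fraction: float = 0.10
    roc_cutoff: float = 41.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rvd_summary not in ("sd", "mean"):
            raise ValueError(f"rvd_summary must be 'sd' or 'mean', got {self.rvd_summary!r}")
        if self.delta_eeli_normalization not in ("baseline_tiv",):
            raise ValueError(
                f"unknown delta_eeli_normalization {self.delta_eeli_normalization!r}"
            )
        if not 0 < self.mask_threshold_fraction <= 1:
            raise ValueError("mask_threshold_fraction must be in (0, 1]")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rvd_thresholds"] = list(self.rvd_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rvd_thresholds" in d:
            d["rvd_thresholds"] = tuple(int(t) for t in d["rvd_thresholds"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def sha256(self) -> str:
        """Stable hash of the configuration, stamped into output tables."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
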