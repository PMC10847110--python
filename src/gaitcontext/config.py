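"""Configuration objects for cohort synthesis and pipeline runs.

Every tunable distribution parameter, threshold, and seed lives in one of
the dataclasses below so that a run is fully described by a single YAML (or
JSON) document plus a master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Gravitational acceleration used for dimensionless normalization (m s^-2).
GRAVITY = 9.81

#: Standing gaps shorter than this merge adjacent stepping bouts into one
#: walking period (strictly-less-than rule).
GAP_MAX_S = 60.0


@dataclass
class ContextProfile:
    """Class-conditional generative description of one walking context.

    Period durations are log-normal (positive, right-skewed); standing
    interruptions are Poisson-placed along the period with uniform lengths
    strictly below the bout-grouping threshold, so a generated period always
    survives segmentation as a single walking period.
    """

    context_label: str
    duration_mean_min: float
    duration_cv: float = 0.8
    interruption_rate_per_min: float = 0.5
    interruption_len_s: tuple[float, float] = (5.0, 55.0)
    stride_speed_mean_ms: float = 1.2
    stride_speed_sd_ms: float = 0.4
    period_count_weight: float = 1.0

    def validate(self) -> None:
        if self.duration_mean_min <= 0:
            raise ValueError("mean period duration must be positive")
        if self.duration_cv <= 0 or self.stride_speed_sd_ms <= 0:
            raise ValueError("dispersion parameters must be positive")
        if self.interruption_rate_per_min < 0:
            raise ValueError("interruption rate must be non-negative")
        lo, hi = self.interruption_len_s
        if not (0 < lo < hi):
            raise ValueError("interruption length bounds must satisfy 0 < lo < hi")
        if hi >= GAP_MAX_S:
            raise ValueError(
                f"interruption lengths must stay below the {GAP_MAX_S:.0f} s "
                "grouping threshold"
            )


def _interruption_rate_for_continuity(continuity_pct: float,
                                      mean_gap_s: float = 30.0) -> float:
    """Gaps per minute giving an expected continuity of ``continuity_pct``.

    E[standing per minute of period] = rate * mean_gap_s seconds, hence
    continuity = 100 * (1 - rate * mean_gap_s / 60).
    """
    return (1.0 - continuity_pct / 100.0) * 60.0 / mean_gap_s


def default_indoor_profile() -> ContextProfile:
    return ContextProfile(
        context_label="indoor",
        duration_mean_min=2.2,
        duration_cv=0.8,
        interruption_rate_per_min=_interruption_rate_for_continuity(61.6),
        stride_speed_mean_ms=1.10,
        stride_speed_sd_ms=0.43,
        period_count_weight=0.8,
    )


def default_outdoor_profile() -> ContextProfile:
    return ContextProfile(
        context_label="outdoor",
        duration_mean_min=11.4,
        duration_cv=0.8,
        interruption_rate_per_min=_interruption_rate_for_continuity(81.7),
        stride_speed_mean_ms=1.38,
        stride_speed_sd_ms=0.31,
        period_count_weight=0.2,
    )


@dataclass
class CohortConfig:
    """Parameters of the synthetic free-living cohort.

    The defaults emulate a 20-participant thigh-accelerometer study: an
    80:20 indoor:outdoor period mix, indoor periods short and frequently
    interrupted, outdoor periods long and continuous, and outdoor stride
    speeds ~0.28 m/s faster than indoor on average.
    """

    n_participants: int = 20
    periods_per_participant: int = 170
    indoor: ContextProfile = field(default_factory=default_indoor_profile)
    outdoor: ContextProfile = field(default_factory=default_outdoor_profile)

    # participant-level parameter ranges (uniform draws)
    leg_length_range_m: tuple[float, float] = (0.80, 0.95)
    speed_a_range: tuple[float, float] = (1.2, 1.4)
    speed_b_range: tuple[float, float] = (0.3, 0.5)
    # indoor proportion per participant ~ Beta(mix*conc, (1-mix)*conc)
    context_mix_mean: float = 0.8
    context_mix_concentration: float = 40.0
    # participant-level log-normal duration multiplier (mean 1)
    duration_scale_sigma: float = 0.05

    # label-table composition among generated periods
    mixed_fraction: float = 0.02
    unlabeled_fraction: float = 0.05

    # stride-speed support and within-period stride jitter
    speed_support_ms: tuple[float, float] = (0.5, 2.6)
    stride_speed_jitter_ms: float = 0.03

    # schedule geometry
    min_bout_s: float = 6.0
    min_period_duration_min: float = 0.4
    max_period_duration_min: float = 60.0
    inter_period_gap_s: tuple[float, float] = (75.0, 120.0)

    # raw waveform synthesis
    sampling_rate_hz: float = 20.0
    noise_sd_g: float = 0.05
    harmonic_amplitudes_g: tuple[float, float, float] = (0.35, 0.15, 0.06)
    clip_g: float = 4.0

    # held-out test subset
    test_fraction: float = 0.25

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError(
                "need at least 2 participants (leave-one-out is undefined "
                "for a single participant)"
            )
        if self.periods_per_participant < 1:
            raise ValueError("periods_per_participant must be positive")
        for prof in (self.indoor, self.outdoor):
            prof.validate()
        a_lo, a_hi = self.speed_a_range
        b_lo, b_hi = self.speed_b_range
        if a_lo <= 0:
            raise ValueError("speed parameter a must be positive")
        if b_hi >= 1:
            raise ValueError("speed parameter b must be < 1")
        l_lo, l_hi = self.leg_length_range_m
        if not (0.5 < l_lo < l_hi < 1.3):
            raise ValueError("leg length range must lie in (0.5, 1.3) m")
        if not 0 <= self.context_mix_mean <= 1:
            raise ValueError("context_mix_mean must be in [0, 1]")
        if self.sampling_rate_hz < 20:
            raise ValueError("sampling rate must be >= 20 Hz")
        if self.mixed_fraction + self.unlabeled_fraction > 0.5:
            raise ValueError("mixed + unlabeled fractions unreasonably large")


@dataclass
class SegmentationConfig:
    """Thresholds for bout detection, grouping, and running exclusion."""

    gap_max_s: float = GAP_MAX_S
    bout_min_s: float = 5.0
    bout_rms_threshold_g: float = 0.06
    bout_window_s: float = 1.0
    bout_refine_level: float = 0.6
    bout_close_gap_s: float = 1.0
    cadence_max_hz: float = 1.4
    min_strides_per_period: int = 4


@dataclass
class ClassifierConfig:
    """Learning-algorithm hyperparameters (grid-search winners)."""

    rf_n_estimators: int = 40
    svm_n_estimators: int = 60
    svm_kernel: str = "rbf"
    positive_label: str = "indoor"


@dataclass
class RunConfig:
    """Full description of one end-to-end pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def validate(self) -> None:
        self.cohort.validate()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            val = _from_plain(f.type, val)
        kwargs[f.name] = val
    return cls(**kwargs)


def run_config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def run_config_from_dict(data: dict) -> RunConfig:
    cohort = data.get("cohort", {})
    indoor = cohort.pop("indoor", None)
    outdoor = cohort.pop("outdoor", None)
    cohort_cfg = _coerce(CohortConfig, cohort)
    if indoor is not None:
        cohort_cfg.indoor = _coerce(ContextProfile, indoor)
    if outdoor is not None:
        cohort_cfg.outdoor = _coerce(ContextProfile, outdoor)
    cfg = RunConfig(
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "results/run")),
        cohort=cohort_cfg,
        segmentation=_coerce(SegmentationConfig, data.get("segmentation", {})),
        classifier=_coerce(ClassifierConfig, data.get("classifier", {})),
    )
    cfg.validate()
    return cfg


def _coerce(cls, data: dict):
    kwargs = {}
    tuple_fields = {
        f.name for f in dataclasses.fields(cls)
        if "tuple" in str(f.type)
    }
    for f in dataclasses.fields(cls):
        if f.name in data:
            val = data[f.name]
            if f.name in tuple_fields and isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return run_config_from_dict(data or {})


def save_run_config(config: RunConfig, path: str | Path) -> None:
    data = run_config_to_dict(config)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
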