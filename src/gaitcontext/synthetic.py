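"""Synthetic free-living cohort generator.

Emulates a thigh-accelerometer study of everyday walking: each participant
produces a stream of walking periods — groups of stepping bouts separated
by sub-minute standing gaps — whose class-conditional statistics are set by
two :class:`~gaitcontext.config.ContextProfile` objects (indoor: short,
interrupted, slower; outdoor: long, continuous, faster). The generator
emits raw tri-axial waveforms whose stride timing matches the scheduled
per-stride frequency series, together with full ground truth, so the whole
signal → segmentation → features → statistics chain can be validated
without any real recording.

Idle (non-walking) time between periods is shortened to ~1.5–2 min of
standing rather than the full free-living day; an event table keeps the
true timeline offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .config import CohortConfig, ContextProfile
from .signals import AccelerometerRecording
from .speed import SpeedModel, stride_frequency

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant anthropometrics and speed-model calibration."""

    participant_id: str
    leg_length_m: float
    speed_param_a: float
    speed_param_b: float
    context_mix: float
    duration_scale: float = 1.0
    is_test: bool = False

    def __post_init__(self) -> None:
        if not (0.5 < self.leg_length_m < 1.3):
            raise ValueError("leg length must lie in (0.5, 1.3) m")
        if self.speed_param_a <= 0:
            raise ValueError("speed parameter a must be positive")
        if self.speed_param_b >= 1:
            raise ValueError("speed parameter b must be < 1")
        if not (0.0 <= self.context_mix <= 1.0):
            raise ValueError("context_mix must lie in [0, 1]")

    @property
    def speed_model(self) -> SpeedModel:
        return SpeedModel(self.speed_param_a, self.speed_param_b)


@dataclass
class PeriodSchedule:
    """One scheduled walking period with full ground truth.

    ``context`` is the true class (indoor / outdoor / mixed);
    ``majority_context`` resolves mixed periods to the longer segment's
    class; ``label`` is what the published label table will say (indoor /
    outdoor / mixed / unlabeled).
    """

    participant_id: str
    period_id: str
    context: str
    majority_context: str
    label: str
    start_s: float
    end_s: float
    bouts: list[tuple[float, float]]
    bout_events: list[np.ndarray]            # stride events per bout (abs s)
    stride_frequencies: np.ndarray           # per completed stride (Hz)
    stride_speeds: np.ndarray                # per completed stride (m/s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def standing_time_s(self) -> float:
        stepping = sum(e - s for s, e in self.bouts)
        return self.duration_s - stepping

    @property
    def stride_events(self) -> np.ndarray:
        return np.concatenate(self.bout_events) if self.bout_events else np.empty(0)

    def validate(self) -> None:
        assert self.end_s > self.start_s
        for (s, e), ev in zip(self.bouts, self.bout_events):
            assert e > s
            if ev.size:
                assert np.all(np.diff(ev) > 0), "stride events must increase"
                assert ev[0] >= s - 1e-9 and ev[-1] <= e + 1e-9, \
                    "stride events must lie inside their bout"


# --------------------------------------------------------------------------
# distribution helpers

_TRUNCNORM_CACHE: dict[tuple, tuple[float, float]] = {}


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float
                      ) -> tuple[float, float]:
    """Parent (mu, sigma) whose truncation to [lo, hi] has the given moments.

    Moment matching keeps the configured class mean/SD exact even though
    speeds are confined to a physically sensible support.
    """
    key = (round(mean, 9), round(sd, 9), round(lo, 9), round(hi, 9))
    if key in _TRUNCNORM_CACHE:
        return _TRUNCNORM_CACHE[key]

    def residual(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sstats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(residual, x0=[mean, np.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    _TRUNCNORM_CACHE[key] = (mu, sigma)
    return mu, sigma


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size=None):
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sstats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size,
                                random_state=rng)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


_LOGNORM_TRUNC_CACHE: dict[tuple, float] = {}


def _lognormal_trunc_mu(mean: float, cv: float, lo: float, hi: float) -> float:
    """Parent location of a log-normal whose truncation to [lo, hi] has
    mean ``mean`` (shape fixed by the configured CV). Walking periods have
    a bounded realistic support — multi-hour uninterrupted periods do not
    occur in free-living data — and moment matching keeps the configured
    class mean exact under that bound."""
    key = (round(mean, 9), round(cv, 9), round(lo, 9), round(hi, 9))
    if key in _LOGNORM_TRUNC_CACHE:
        return _LOGNORM_TRUNC_CACHE[key]
    from scipy import integrate, optimize

    mu0, sigma = _lognormal_params(mean, cv)

    def trunc_mean(mu):
        d = sstats.lognorm(s=sigma, scale=np.exp(mu))
        mass = d.cdf(hi) - d.cdf(lo)
        m, _ = integrate.quad(lambda x: x * d.pdf(x), lo, hi, limit=200)
        return m / mass

    mu = float(optimize.brentq(lambda m: trunc_mean(m) - mean,
                               mu0 - 1.0, mu0 + 1.5))
    _LOGNORM_TRUNC_CACHE[key] = mu
    return mu


def _sample_duration_min(rng: np.random.Generator, profile: ContextProfile,
                         scale: float, min_duration_min: float,
                         max_duration_min: float = 60.0) -> float:
    mean = profile.duration_mean_min * scale
    hi = max(max_duration_min, 2.0 * mean)
    mu = _lognormal_trunc_mu(mean, profile.duration_cv, min_duration_min, hi)
    _, sigma = _lognormal_params(mean, profile.duration_cv)
    for _ in range(1000):
        d = float(rng.lognormal(mu, sigma))
        if min_duration_min <= d <= hi:
            return d
    return mean


# --------------------------------------------------------------------------
# period scheduling

#: Spread of the per-period standing fraction around its class mean.
_STANDING_FRACTION_CONCENTRATION = 8.0


def _sample_interruptions(rng: np.random.Generator, profile: ContextProfile,
                          duration_s: float, min_bout_s: float) -> np.ndarray:
    """Standing-gap lengths for one period.

    The interruption rate (gaps per minute, mean gap length = midpoint of
    the configured bounds) implies a mean standing fraction
    q = rate * mean_gap / 60. Each period draws its own fraction from a
    Beta distribution with that mean and realizes it exactly as gaps, so
    the class-mean continuity matches the closed-form value at every
    period duration — a compound-Poisson draw cannot fit the target
    fraction into short periods without bias.
    """
    lo, hi = profile.interruption_len_s
    mean_gap = 0.5 * (lo + hi)
    q_mean = profile.interruption_rate_per_min * mean_gap / 60.0
    if q_mean <= 0:
        return np.empty(0)
    if q_mean >= 0.85:
        raise ValueError("interruption rate implies >85% standing")

    conc = _STANDING_FRACTION_CONCENTRATION
    q = float(rng.beta(q_mean * conc, (1.0 - q_mean) * conc))
    standing = q * duration_s
    # feasibility: leave at least two bouts' worth of stepping
    standing = min(standing, duration_s - 2.0 * min_bout_s)
    if standing < 2.0:
        return np.empty(0)

    n = max(1, int(round(standing / mean_gap)))
    n = max(n, int(np.ceil(standing / hi)))          # no gap above the bound
    max_n = int(np.floor((duration_s - standing) / min_bout_s)) - 1
    if max_n < 1:
        return np.empty(0)
    n = min(n, max_n)

    shares = rng.gamma(4.0, 1.0, size=n)
    lengths = standing * shares / shares.sum()
    # redistribute any mass above the per-gap upper bound
    for _ in range(20):
        over = lengths > hi
        if not over.any():
            break
        excess = float((lengths[over] - hi).sum())
        lengths[over] = hi
        free = ~over
        if not free.any():
            break
        lengths[free] += excess * lengths[free] / lengths[free].sum()
    return lengths[lengths >= 1.0]


def _layout_bouts(rng: np.random.Generator, duration_s: float,
                  gap_lengths: np.ndarray, min_bout_s: float
                  ) -> list[tuple[float, float]]:
    """Split a period of ``duration_s`` into alternating bouts and gaps,
    bout lengths Dirichlet-distributed above the per-bout floor."""
    n_bouts = gap_lengths.size + 1
    stepping = duration_s - gap_lengths.sum()
    extra = stepping - n_bouts * min_bout_s
    weights = rng.gamma(1.0, 1.0, size=n_bouts)
    shares = min_bout_s + extra * weights / weights.sum()
    bouts = []
    t = 0.0
    for i, share in enumerate(shares):
        bouts.append((t, t + share))
        t += share
        if i < gap_lengths.size:
            t += gap_lengths[i]
    return bouts


def _fill_strides(rng: np.random.Generator, bout: tuple[float, float],
                  mean_speed: float, participant: ParticipantProfile,
                  cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stride events / frequencies / speeds filling one bout.

    Speeds jitter around the period mean; each stride's duration is the
    reciprocal of the frequency implied by the power-law speed model, so
    ground-truth speeds and frequencies are exactly consistent.
    """
    start, end = bout
    lo, hi = cfg.speed_support_ms
    model = participant.speed_model
    events = [start]
    freqs: list[float] = []
    speeds: list[float] = []
    t = start
    while True:
        v = float(np.clip(mean_speed + rng.normal(0.0, cfg.stride_speed_jitter_ms),
                          lo, hi))
        f = stride_frequency(v, model)
        t_next = t + 1.0 / f
        if t_next > end:
            break
        events.append(t_next)
        freqs.append(f)
        speeds.append(v)
        t = t_next
    return np.array(events), np.array(freqs), np.array(speeds)


def _schedule_segment(rng: np.random.Generator, profile: ContextProfile,
                      participant: ParticipantProfile, cfg: CohortConfig,
                      duration_min: float | None = None
                      ) -> tuple[list[tuple[float, float]], list[np.ndarray],
                                 np.ndarray, np.ndarray, float]:
    """Bouts + strides for one single-context stretch starting at t=0.

    Returns (bouts, per-bout events, frequencies, speeds, duration_s).
    """
    if duration_min is None:
        duration_min = _sample_duration_min(
            rng, profile, participant.duration_scale,
            cfg.min_period_duration_min, cfg.max_period_duration_min)
    duration_s = duration_min * 60.0
    gaps = _sample_interruptions(rng, profile, duration_s, cfg.min_bout_s)
    bouts = _layout_bouts(rng, duration_s, gaps, cfg.min_bout_s)
    mean_speed = float(_sample_truncnorm(
        rng, profile.stride_speed_mean_ms, profile.stride_speed_sd_ms,
        *cfg.speed_support_ms))
    bout_events, freqs, speeds = [], [], []
    for bout in bouts:
        ev, f, v = _fill_strides(rng, bout, mean_speed, participant, cfg)
        bout_events.append(ev)
        freqs.append(f)
        speeds.append(v)
    return (bouts, bout_events,
            np.concatenate(freqs) if freqs else np.empty(0),
            np.concatenate(speeds) if speeds else np.empty(0),
            duration_s)


def _shift(bouts, bout_events, offset: float):
    return ([(s + offset, e + offset) for s, e in bouts],
            [ev + offset for ev in bout_events])


def sample_schedule(participant: ParticipantProfile, n_periods: int,
                    profiles: tuple[ContextProfile, ContextProfile],
                    seed: int | np.random.Generator,
                    config: CohortConfig | None = None) -> list[PeriodSchedule]:
    """Sample ``n_periods`` walking periods for one participant.

    ``profiles`` must contain one indoor and one outdoor profile. Periods
    are laid out consecutively on the participant's timeline, separated by
    standing stretches longer than the grouping threshold. Identical seeds
    reproduce identical schedules.
    """
    if n_periods <= 0:
        raise ValueError("n_periods must be positive")
    by_label = {p.context_label: p for p in profiles}
    if set(by_label) != {"indoor", "outdoor"}:
        raise ValueError("profiles must contain one indoor and one outdoor entry")
    cfg = config or CohortConfig()
    # participant validity (b < 1 etc.) is enforced by the profile itself
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    schedules: list[PeriodSchedule] = []
    t = 30.0  # leading margin
    for k in range(n_periods):
        u = rng.uniform()
        if u < cfg.mixed_fraction:
            kind = "mixed"
        elif u < cfg.mixed_fraction + cfg.unlabeled_fraction:
            kind = "unlabeled"
        else:
            kind = "pure"

        if kind == "mixed":
            period = _sample_mixed_period(rng, participant, by_label, cfg, t, k)
        else:
            context = "indoor" if rng.uniform() < participant.context_mix \
                else "outdoor"
            bouts, events, freqs, speeds, dur = _schedule_segment(
                rng, by_label[context], participant, cfg)
            bouts, events = _shift(bouts, events, t)
            period = PeriodSchedule(
                participant_id=participant.participant_id,
                period_id=f"{participant.participant_id}_{k:04d}",
                context=context,
                majority_context=context,
                label="unlabeled" if kind == "unlabeled" else context,
                start_s=t,
                end_s=t + dur,
                bouts=bouts,
                bout_events=events,
                stride_frequencies=freqs,
                stride_speeds=speeds,
            )
        schedules.append(period)
        t = period.end_s + rng.uniform(*cfg.inter_period_gap_s)
    return schedules


def _sample_mixed_period(rng, participant, by_label, cfg, t0, k
                         ) -> PeriodSchedule:
    """A mixed period: a majority-context segment followed (or preceded) by
    a shorter minority segment, joined by a sub-threshold standing gap."""
    majority = "indoor" if rng.uniform() < participant.context_mix else "outdoor"
    minority = "outdoor" if majority == "indoor" else "indoor"
    maj_dur = 0.7 * _sample_duration_min(rng, by_label[majority],
                                         participant.duration_scale,
                                         cfg.min_period_duration_min,
                                         cfg.max_period_duration_min)
    min_dur = 0.3 * _sample_duration_min(rng, by_label[minority],
                                         participant.duration_scale,
                                         cfg.min_period_duration_min,
                                         cfg.max_period_duration_min)
    maj_dur = max(maj_dur, cfg.min_period_duration_min)
    min_dur = max(min(min_dur, 0.8 * maj_dur), cfg.min_period_duration_min / 2)
    segments = [(majority, maj_dur), (minority, min_dur)]
    if rng.uniform() < 0.5:
        segments.reverse()

    bouts, events, freqs, speeds = [], [], [], []
    t = t0
    for i, (ctx, dur) in enumerate(segments):
        b, ev, f, v, seg_dur = _schedule_segment(
            rng, by_label[ctx], participant, cfg, duration_min=dur)
        b, ev = _shift(b, ev, t)
        bouts.extend(b)
        events.extend(ev)
        freqs.append(f)
        speeds.append(v)
        t += seg_dur
        if i == 0:
            t += rng.uniform(*by_label[ctx].interruption_len_s)
    return PeriodSchedule(
        participant_id=participant.participant_id,
        period_id=f"{participant.participant_id}_{k:04d}",
        context="mixed",
        majority_context=majority,
        label="mixed",
        start_s=t0,
        end_s=bouts[-1][1],
        bouts=bouts,
        bout_events=events,
        stride_frequencies=np.concatenate(freqs),
        stride_speeds=np.concatenate(speeds),
    )


# --------------------------------------------------------------------------
# waveform synthesis

def synthesize_recording(schedule: list[PeriodSchedule],
                         participant: ParticipantProfile,
                         sampling_rate: float,
                         seed: int | np.random.Generator,
                         config: CohortConfig | None = None
                         ) -> AccelerometerRecording:
    """Render a schedule into a raw tri-axial waveform.

    Walking is a harmonic pulse train phase-locked to the scheduled stride
    events (fundamental at the stride frequency plus two harmonics),
    superposed on a fixed gravity projection; standing is gravity plus
    low-amplitude noise. Samples are clipped to the sensor's ±4 g range.
    An empty schedule yields an empty but valid recording.
    """
    cfg = config or CohortConfig()
    if sampling_rate < 20:
        raise ValueError("sampling rate must be >= 20 Hz")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    if not schedule:
        return AccelerometerRecording(participant.participant_id,
                                      sampling_rate, np.empty((0, 3)))

    total_s = schedule[-1].end_s + 30.0
    n = int(round(total_s * sampling_rate))
    t = np.arange(n) / sampling_rate

    # fixed sensor orientation: gravity mostly on +z, slight tilt
    tilt = rng.normal(0.0, 0.05, size=2)
    grav = np.array([0.15 + tilt[0], 0.05 + tilt[1], 1.0])
    grav = grav / np.linalg.norm(grav)
    # gait oscillation direction: mostly along the thigh's swing axis
    gait_dir = np.array([0.9, 0.35 + rng.normal(0, 0.05), -0.25])
    gait_dir = gait_dir / np.linalg.norm(gait_dir)

    sig = np.tile(grav.astype(np.float64), (n, 1))
    amps = cfg.harmonic_amplitudes_g

    for period in schedule:
        for (b_start, b_end), events in zip(period.bouts, period.bout_events):
            if events.size < 2:
                continue
            i0 = int(np.ceil(b_start * sampling_rate))
            i1 = min(int(np.floor(b_end * sampling_rate)) + 1, n)
            tt = t[i0:i1]
            # piecewise-linear phase: 2*pi*k at stride event k, extended to
            # the bout edges at the edge strides' frequencies
            phase_knots = 2.0 * np.pi * np.arange(events.size)
            f_first = 1.0 / (events[1] - events[0])
            f_last = 1.0 / (events[-1] - events[-2])
            knots_t = np.concatenate(([b_start], events, [b_end]))
            knots_p = np.concatenate((
                [phase_knots[0] - 2 * np.pi * (events[0] - b_start) * f_first],
                phase_knots,
                [phase_knots[-1] + 2 * np.pi * (b_end - events[-1]) * f_last],
            ))
            phase = np.interp(tt, knots_t, knots_p)
            wave = sum(a * np.cos((h + 1) * phase) for h, a in enumerate(amps))
            sig[i0:i1] += gait_dir[None, :] * wave[:, None]

    if cfg.noise_sd_g > 0:
        sig += rng.normal(0.0, cfg.noise_sd_g, size=sig.shape)
    np.clip(sig, -cfg.clip_g, cfg.clip_g, out=sig)
    return AccelerometerRecording(participant.participant_id, sampling_rate,
                                  sig.astype(np.float32))


# --------------------------------------------------------------------------
# cohort assembly

@dataclass
class Cohort:
    """A full synthetic cohort: participants, schedules, and lazy waveforms."""

    config: CohortConfig
    seed: int
    participants: list[ParticipantProfile]
    schedules: dict[str, list[PeriodSchedule]]

    def participant(self, pid: str) -> ParticipantProfile:
        return next(p for p in self.participants if p.participant_id == pid)

    def recording(self, pid: str) -> AccelerometerRecording:
        """Synthesize (deterministically) the raw waveform for one
        participant; repeated calls return bit-identical streams."""
        idx = [p.participant_id for p in self.participants].index(pid)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 1000 + idx]))
        return synthesize_recording(self.schedules[pid],
                                    self.participants[idx],
                                    self.config.sampling_rate_hz, rng,
                                    self.config)

    # ---- tables -----------------------------------------------------------

    def participant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "leg_length_m": [p.leg_length_m for p in self.participants],
                "a": [p.speed_param_a for p in self.participants],
                "b": [p.speed_param_b for p in self.participants],
                "is_test": [p.is_test for p in self.participants],
            }
        )

    def bout_table(self) -> pd.DataFrame:
        """Ground-truth activity events: stepping bouts and the standing
        gaps inside each period."""
        rows = []
        for pid, periods in self.schedules.items():
            for per in periods:
                prev_end = None
                for (s, e) in per.bouts:
                    if prev_end is not None and s > prev_end:
                        rows.append((pid, prev_end, s, "standing"))
                    rows.append((pid, s, e, "stepping"))
                    prev_end = e
        return pd.DataFrame(rows, columns=["participant_id", "start_s",
                                           "end_s", "activity"])

    def label_table(self) -> pd.DataFrame:
        rows = [
            (per.participant_id, per.start_s, per.end_s, per.label)
            for periods in self.schedules.values() for per in periods
        ]
        return pd.DataFrame(rows, columns=["participant_id", "period_start_s",
                                           "period_end_s", "label"])

    def truth_table(self) -> pd.DataFrame:
        """Period-level ground truth for calibration and recovery checks."""
        rows = []
        for periods in self.schedules.values():
            for per in periods:
                dur_min = per.duration_s / 60.0
                continuity = 100.0 * (1.0 - per.standing_time_s / per.duration_s)
                rows.append(
                    {
                        "participant_id": per.participant_id,
                        "period_id": per.period_id,
                        "context": per.context,
                        "majority_context": per.majority_context,
                        "label": per.label,
                        "start_s": per.start_s,
                        "end_s": per.end_s,
                        "duration_min": dur_min,
                        "standing_time_s": per.standing_time_s,
                        "continuity_pct": continuity,
                        "n_strides": int(per.stride_frequencies.size),
                        "mean_stride_freq_hz": float(per.stride_frequencies.mean())
                        if per.stride_frequencies.size else np.nan,
                        "mean_stride_speed_ms": float(per.stride_speeds.mean())
                        if per.stride_speeds.size else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path, waveforms: bool = False) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participant_table().to_csv(out / "participants.csv", index=False)
        self.bout_table().to_csv(out / "bouts.csv", index=False)
        self.label_table().to_csv(out / "labels.csv", index=False)
        self.truth_table().to_csv(out / "ground_truth.csv", index=False)
        if waveforms:
            for p in self.participants:
                self.recording(p.participant_id).to_csv(
                    out / f"{p.participant_id}.csv")


def generate_cohort(n_participants: int, periods_per_participant: int,
                    config: CohortConfig | None = None,
                    seed: int = 0) -> Cohort:
    """Generate a labeled synthetic cohort.

    Participant parameters (leg length, speed-model (a, b), indoor mix,
    duration scale) are drawn from the configured ranges; a random subset
    of participants is flagged as the held-out test set. Identical seeds
    and config reproduce identical cohorts.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if periods_per_participant < 1:
        raise ValueError("periods_per_participant must be positive")
    cfg = config or CohortConfig()
    cfg = dataclass_replace(cfg, n_participants=n_participants,
                            periods_per_participant=periods_per_participant)
    cfg.validate()

    root = np.random.SeedSequence([seed, 0])
    rng = np.random.default_rng(root)

    mix_a = cfg.context_mix_mean * cfg.context_mix_concentration
    mix_b = (1.0 - cfg.context_mix_mean) * cfg.context_mix_concentration
    n_test = int(round(cfg.test_fraction * n_participants))
    test_ids = set(rng.choice(n_participants, size=n_test, replace=False))

    participants = []
    for i in range(n_participants):
        participants.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                leg_length_m=float(rng.uniform(*cfg.leg_length_range_m)),
                speed_param_a=float(rng.uniform(*cfg.speed_a_range)),
                speed_param_b=float(rng.uniform(*cfg.speed_b_range)),
                context_mix=float(rng.beta(mix_a, mix_b))
                if cfg.context_mix_concentration > 0 else cfg.context_mix_mean,
                duration_scale=float(np.exp(
                    rng.normal(0.0, cfg.duration_scale_sigma)
                    - cfg.duration_scale_sigma**2 / 2.0)),
                is_test=i in test_ids,
            )
        )

    profiles = (cfg.indoor, cfg.outdoor)
    schedules = {}
    for i, part in enumerate(participants):
        part_rng = np.random.default_rng(np.random.SeedSequence([seed, 2000 + i]))
        schedules[part.participant_id] = sample_schedule(
            part, periods_per_participant, profiles, part_rng, cfg)
    return Cohort(cfg, seed, participants, schedules)


def dataclass_replace(cfg, **kwargs):
    import dataclasses
    return dataclasses.replace(cfg, **kwargs)


def feature_table_from_truth(cohort: Cohort) -> pd.DataFrame:
    """Ground-truth biomechanics feature table (no signal processing).

    Uses the scheduled stride frequencies directly; useful as a fast,
    noise-free stand-in for the detected feature table in classifier and
    statistics checks.
    """
    from .config import GRAVITY
    rows = []
    for periods in cohort.schedules.values():
        for per in periods:
            f = per.stride_frequencies
            if f.size < 3:
                continue
            part = cohort.participant(per.participant_id)
            norm = np.sqrt(GRAVITY * part.leg_length_m)
            rows.append(
                {
                    "participant_id": per.participant_id,
                    "period_id": per.period_id,
                    "duration_min": per.duration_s / 60.0,
                    "continuity_pct": 100.0 * (1.0 - per.standing_time_s
                                               / per.duration_s),
                    "mean_norm_stride_freq": float(f.mean()) / norm,
                    "sd_norm_stride_freq": float(f.std(ddof=1)) / norm,
                    "n_strides": int(f.size),
                    "label": per.label,
                    "context": per.context,
                    "majority_context": per.majority_context,
                }
            )
    return pd.DataFrame(rows)
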