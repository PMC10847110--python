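"""Biomechanics feature set of a walking period.

Four features summarize how a period was walked: its duration (minutes),
its continuity (the percentage of the period spent stepping rather than
standing), and the mean and standard deviation of stride frequency,
normalized by sqrt(g * l0) with l0 the participant's leg length to remove
body-size effects. Short indoor walks are typically brief and frequently
interrupted; outdoor walks long, continuous, and faster — which is what a
context classifier exploits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import GRAVITY
from .segmentation import WalkingPeriod, period_frequencies

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "duration_min",
    "continuity_pct",
    "mean_norm_stride_freq",
    "sd_norm_stride_freq",
]

#: Minimum stride count for a period to enter the feature table (the SD of
#: stride frequency is too unstable below this).
MIN_STRIDES = 4


def continuity(period: WalkingPeriod) -> float:
    """Walking-period continuity, percent of the period spent stepping:

        continuity = (duration - standing_time) / duration * 100

    100 means no standing time at all.
    """
    duration = period.duration_s
    if duration <= 0:
        raise ValueError("period duration must be positive")
    standing = period.standing_time_s
    if standing >= duration:
        raise ValueError("standing time must be below the period duration")
    return (duration - standing) / duration * 100.0


def normalized_frequency_stats(frequencies: np.ndarray, leg_length_m: float,
                               g: float = GRAVITY
                               ) -> tuple[float, float] | None:
    """Mean and sample SD (n-1) of stride frequency divided by
    sqrt(g * l0). Returns None when fewer than 3 frequencies are available.
    """
    if leg_length_m <= 0:
        raise ValueError("leg length must be positive")
    f = np.asarray(frequencies, dtype=float)
    if f.size < 3:
        return None
    norm = np.sqrt(g * leg_length_m)
    return float(f.mean() / norm), float(f.std(ddof=1) / norm)


def assign_labels(periods: list[WalkingPeriod],
                  label_table: pd.DataFrame) -> list[str]:
    """Label each detected period from a context-label table
    (participant_id, period_start_s, period_end_s, label) by maximal
    temporal overlap; periods without overlap are 'unlabeled'."""
    by_pid = {
        pid: (g["period_start_s"].to_numpy(), g["period_end_s"].to_numpy(),
              g["label"].to_numpy())
        for pid, g in label_table.groupby("participant_id")
    }
    labels = []
    for period in periods:
        starts, ends, labs = by_pid.get(period.participant_id,
                                        (np.empty(0), np.empty(0),
                                         np.empty(0, dtype=object)))
        if starts.size == 0:
            labels.append("unlabeled")
            continue
        overlap = np.minimum(period.end_s, ends) - np.maximum(period.start_s,
                                                              starts)
        k = int(np.argmax(overlap))
        labels.append(str(labs[k]) if overlap[k] > 0 else "unlabeled")
    return labels


def build_feature_table(periods: list[WalkingPeriod],
                        participants: pd.DataFrame,
                        labels: list[str] | pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """One row of biomechanics features per surviving walking period.

    Periods with fewer than 4 plausible strides are excluded (counted in
    the log). ``labels`` may be a pre-aligned list or a context-label
    table; omitted labels default to 'unlabeled'.

    Raises
    ------
    KeyError
        If a period's participant is missing from the metadata table.
    """
    meta = participants.set_index("participant_id")
    if isinstance(labels, pd.DataFrame):
        labels = assign_labels(periods, labels)
    elif labels is None:
        labels = ["unlabeled"] * len(periods)

    rows = []
    n_short = 0
    for period, label in zip(periods, labels):
        if period.participant_id not in meta.index:
            raise KeyError(
                f"participant {period.participant_id!r} missing from metadata")
        freqs = period_frequencies(period)
        stats = normalized_frequency_stats(
            freqs, float(meta.loc[period.participant_id, "leg_length_m"]))
        if freqs.size < MIN_STRIDES or stats is None:
            n_short += 1
            continue
        rows.append(
            {
                "participant_id": period.participant_id,
                "period_id": period.period_id,
                "duration_min": period.duration_s / 60.0,
                "continuity_pct": continuity(period),
                "mean_norm_stride_freq": stats[0],
                "sd_norm_stride_freq": stats[1],
                "n_strides": int(freqs.size),
                "label": label,
            }
        )
    if n_short:
        logger.info("excluded %d periods with < %d strides", n_short, MIN_STRIDES)
    return pd.DataFrame(
        rows,
        columns=["participant_id", "period_id", *FEATURE_COLUMNS,
                 "n_strides", "label"],
    )
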