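"""Quartile summaries, channel/well filtering, activity classification and
comparison of simulated feature summaries against the embedded reference."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .bursts import FEATURE_COLUMNS

__all__ = [
    "Quartiles",
    "summarize",
    "select_units_and_pool",
    "summarize_features",
    "filter_inactive",
    "classify_activity",
    "compare_to_reference",
]


class Quartiles(NamedTuple):
    q1: float
    median: float
    q3: float
    n: int


def summarize(values) -> Quartiles:
    """Q1/median/Q3 by linear interpolation between closest ranks.

    NaN entries (absent features) are dropped first; an all-absent input
    yields an absent summary (NaN triple, n = 0).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return Quartiles(np.nan, np.nan, np.nan, 0)
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    return Quartiles(float(q1), float(med), float(q3), len(v))


def select_units_and_pool(run_tables, n_units: int = 9) -> dict:
    """Pool the first ``n_units`` units of each run's feature table.

    Returns ``{feature: 1-D array of len(run_tables) * n_units values}``
    (burst shape features may contain NaN for burst-free units).
    """
    pooled = {f: [] for f in FEATURE_COLUMNS}
    for k, table in enumerate(run_tables):
        if len(table) < n_units:
            raise ValueError(
                f"run {k} has {len(table)} units, need at least {n_units}"
            )
        head = table.iloc[:n_units]
        for f in FEATURE_COLUMNS:
            pooled[f].append(head[f].to_numpy(dtype=float))
    return {f: np.concatenate(cols) for f, cols in pooled.items()}


def summarize_features(pooled: dict) -> dict:
    return {f: summarize(v) for f, v in pooled.items()}


def filter_inactive(channel_rates: pd.DataFrame,
                    last_mtp_rate_threshold: float = 20.0,
                    min_active_channels: int = 2):
    """Apply the inactive-channel and sparse-well exclusion rules.

    ``channel_rates`` has one row per channel with columns ``well``,
    ``channel`` and one spike-rate column per measurement time point (NaN
    where not measured). A channel is inactive when its rate at its last
    measured time point is strictly below the threshold; wells retaining
    fewer than ``min_active_channels`` active channels are dropped
    entirely. Returns ``(filtered_table, exclusion_log)`` where the
    filtered table gains a boolean ``active`` column.
    """
    df = channel_rates.copy()
    mtp_cols = [c for c in df.columns if c not in ("well", "channel")]
    if not mtp_cols:
        raise ValueError("channel table has no measurement columns")

    def last_rate(row):
        vals = row[mtp_cols].astype(float)
        vals = vals[vals.notna()]
        return vals.iloc[-1] if len(vals) else np.nan

    last = df.apply(last_rate, axis=1)
    df["active"] = last >= last_mtp_rate_threshold

    log = []
    for _, row in df.loc[~df["active"]].iterrows():
        log.append(
            {
                "kind": "channel",
                "well": row["well"],
                "channel": row["channel"],
                "reason": f"rate at last measured time point < "
                          f"{last_mtp_rate_threshold} spikes/min",
            }
        )

    active_per_well = df.groupby("well")["active"].sum()
    bad_wells = active_per_well[active_per_well < min_active_channels].index
    for w in bad_wells:
        log.append(
            {
                "kind": "well",
                "well": w,
                "channel": None,
                "reason": f"fewer than {min_active_channels} active channels",
            }
        )
    filtered = df[~df["well"].isin(bad_wells)].reset_index(drop=True)
    return filtered, log


def classify_activity(mean_spike_rate: float) -> str:
    """Activity class from the mean spike rate at the reference time point:
    < 50 low, 50-250 (inclusive) medium, > 250 high."""
    if mean_spike_rate < 0:
        raise ValueError("spike rate must be >= 0")
    if mean_spike_rate < 50.0:
        return "low"
    if mean_spike_rate <= 250.0:
        return "medium"
    return "high"


def compare_to_reference(sim_summaries: dict,
                         reference: pd.DataFrame) -> pd.DataFrame:
    """Check simulated medians against reference quartile ranges.

    ``sim_summaries`` maps mtp -> {feature: Quartiles}; ``reference`` is
    indexed by (mtp, feature) with columns q1/median/q3. Emits one row
    per (mtp, feature) with closed-interval containment and the signed
    deviation of medians, normalized by the reference median when it is
    nonzero.
    """
    rows = []
    for (mtp, feature), ref in reference.iterrows():
        summary = sim_summaries.get(mtp, {}).get(feature)
        if summary is None or not np.isfinite(summary.median):
            rows.append(
                {
                    "mtp": mtp, "feature": feature, "sim_median": np.nan,
                    "ref_q1": ref["q1"], "ref_median": ref["median"],
                    "ref_q3": ref["q3"], "in_range": False, "deviation": np.nan,
                    "status": "absent",
                }
            )
            continue
        med = summary.median
        diff = med - ref["median"]
        dev = diff / ref["median"] if ref["median"] != 0 else diff
        rows.append(
            {
                "mtp": mtp, "feature": feature, "sim_median": med,
                "ref_q1": ref["q1"], "ref_median": ref["median"],
                "ref_q3": ref["q3"],
                "in_range": bool(ref["q1"] <= med <= ref["q3"]),
                "deviation": dev, "status": "ok",
            }
        )
    return pd.DataFrame(rows)
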