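"""Per-session behavioral measures and phase/value/discrimination breakdowns.

All measures are computed per session (the session, not the trial, is the
unit of analysis for the downstream statistics): initiation and completion
percentages, light-on latency, reward counts, forced-choice accuracy,
free-choice high-value preference, reaction/movement times and well times.
Breakdowns split free-choice preference by learning phase (first vs last 10
free-choice trials per block) and forced-choice accuracy by phase (first vs
last 20 block trials) and cued value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SessionSummary",
    "summarize_session",
    "summarize_sessions",
    "breakdown_free_choice",
    "breakdown_forced_choice",
    "latency_accuracy_pairs",
]

SUMMARY_COLUMNS = [
    "session_id",
    "condition",
    "pct_initiated",
    "mean_lo_latency",
    "pct_completed",
    "n_rewarded",
    "forced_choice_pct_correct",
    "free_choice_pct_high_value",
    "mean_rt",
    "mean_mt",
    "mean_well_time",
    "completed_session",
]


@dataclass(frozen=True)
class SessionSummary:
    """One session's behavioral measures (percentages in [0, 100])."""

    session_id: str
    condition: str
    pct_initiated: float
    mean_lo_latency: float
    pct_completed: float
    n_rewarded: int
    forced_choice_pct_correct: float
    free_choice_pct_high_value: float
    mean_rt: float
    mean_mt: float
    mean_well_time: float
    completed_session: bool


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else np.nan


def summarize_session(
    records: pd.DataFrame, n_blocks: int = 4, trials_per_block: int = 60
) -> SessionSummary:
    """Session-level measures from one session's trial log.

    ``pct_initiated`` is over presented trials, ``pct_completed`` over
    initiated trials; forced accuracy over completed forced trials;
    free-choice high-value preference over completed free trials. A session
    counts as completed when every scheduled trial was presented.
    """
    if len(records) == 0:
        raise ValueError("empty session")
    sid = records["session_id"].iloc[0]
    if records["session_id"].nunique() != 1:
        raise ValueError("records must form a single session")

    initiated = records["initiated"]
    completed = records["completed"]
    forced = records["odor"].isin(["forced_left", "forced_right"])
    free = records["odor"] == "free"

    fc = records[forced & completed]
    fr = records[free & completed]
    return SessionSummary(
        session_id=sid,
        condition=records["condition"].iloc[0],
        pct_initiated=_pct(int(initiated.sum()), len(records)),
        mean_lo_latency=float(records["lo_latency"].mean()),
        pct_completed=_pct(int(completed.sum()), int(initiated.sum())),
        n_rewarded=int(records["rewarded"].sum()),
        forced_choice_pct_correct=_pct(int(fc["correct"].sum()), len(fc)),
        free_choice_pct_high_value=_pct(
            int((fr["choice_side"] == fr["high_value_side"]).sum()), len(fr)
        ),
        mean_rt=float(records["rt"].mean()),
        mean_mt=float(records["mt"].mean()),
        mean_well_time=float(records["well_time"].mean()),
        completed_session=bool(len(records) == n_blocks * trials_per_block),
    )


def summarize_sessions(logs: pd.DataFrame, **kw) -> pd.DataFrame:
    """Apply :func:`summarize_session` per session; one row per session."""
    rows = [
        summarize_session(g, **kw).__dict__ for _, g in logs.groupby("session_id", sort=False)
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def breakdown_free_choice(records: pd.DataFrame, n_edge_trials: int = 10) -> pd.DataFrame:
    """Early/late free-choice high-value preference per block.

    Early is the first ``n_edge_trials`` completed free-choice trials of a
    block, late the last ``n_edge_trials``. Blocks with fewer than
    ``2 * n_edge_trials`` completed free-choice trials yield NA cells (the
    windows must be disjoint). Returns one row per session x block x phase
    with the grouping keys (phase, discrimination, block_type) and
    ``pct_high_value``.
    """
    rows = []
    for (sid, block), g in records.groupby(["session_id", "block_index"], sort=False):
        free = g[(g["odor"] == "free") & g["completed"]].sort_values("trial_index_in_block")
        hv = (free["choice_side"] == free["high_value_side"]).to_numpy()
        enough = len(free) >= 2 * n_edge_trials
        for phase, sel in (
            ("early", hv[:n_edge_trials]),
            ("late", hv[len(hv) - n_edge_trials :] if enough else hv[:0]),
        ):
            rows.append(
                {
                    "session_id": sid,
                    "condition": g["condition"].iloc[0],
                    "block_index": block,
                    "block_type": g["block_type"].iloc[0],
                    "discrimination": g["discrimination"].iloc[0],
                    "phase": phase,
                    "n_trials": int(sel.size) if enough else 0,
                    "pct_high_value": 100.0 * sel.mean() if enough else np.nan,
                }
            )
    return pd.DataFrame(rows)


def breakdown_forced_choice(records: pd.DataFrame, n_edge_trials: int = 20) -> pd.DataFrame:
    """Early/late forced-choice accuracy per block and cued value.

    Phase windows are the first/last ``n_edge_trials`` *scheduled* trials of
    each block; the metric is % correct over completed forced trials in the
    window, split by whether the cued side is the block's high-value side.
    Cells with no completed forced trials are NA.
    """
    rows = []
    for (sid, block), g in records.groupby(["session_id", "block_index"], sort=False):
        t = g["trial_index_in_block"]
        t_max = int(t.max())
        forced = g[g["odor"].isin(["forced_left", "forced_right"]) & g["completed"]].copy()
        cued = np.where(forced["odor"] == "forced_left", "left", "right")
        forced["value"] = np.where(
            cued == forced["high_value_side"].to_numpy(), "high", "low"
        )
        for phase, lo, hi in (
            ("early", 1, n_edge_trials),
            ("late", t_max - n_edge_trials + 1, t_max),
        ):
            win = forced[(forced["trial_index_in_block"] >= lo) & (forced["trial_index_in_block"] <= hi)]
            for value in ("high", "low"):
                cell = win[win["value"] == value]
                rows.append(
                    {
                        "session_id": sid,
                        "condition": g["condition"].iloc[0],
                        "block_index": block,
                        "block_type": g["block_type"].iloc[0],
                        "discrimination": g["discrimination"].iloc[0],
                        "phase": phase,
                        "value": value,
                        "n_trials": len(cell),
                        "pct_correct": 100.0 * cell["correct"].mean() if len(cell) else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def latency_accuracy_pairs(summaries: pd.DataFrame, min_sessions: int = 4) -> dict:
    """Per-condition (mean LO latency, forced accuracy) session pairs.

    Sessions with an undefined latency or accuracy are excluded (count
    logged). Raises when a condition retains fewer than ``min_sessions``
    usable pairs.
    """
    out = {}
    for cond, g in summaries.groupby("condition", sort=False):
        ok = g[["mean_lo_latency", "forced_choice_pct_correct"]].notna().all(axis=1)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("condition %s: excluded %d sessions with undefined pairs", cond, n_dropped)
        pairs = g.loc[ok, ["mean_lo_latency", "forced_choice_pct_correct"]].to_numpy()
        if len(pairs) < min_sessions:
            raise ValueError(
                f"condition {cond!r} has {len(pairs)} usable sessions; need >= {min_sessions}"
            )
        out[cond] = pairs
    return out
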