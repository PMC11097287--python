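"""Synthetic generator for the blocked delay/size reversal task.

A session consists of four 60-trial blocks. Each trial begins with houselight
onset; the rat may initiate by entering a central odor port within 5 s, hold
for 1 s through odor delivery, and then respond at the left or right fluid
well within 3 s. One of three odors is presented per trial: forced-left,
forced-right, or free-choice. In blocks 1-2 reward value is manipulated by
delay (one side 0.5 s, the other an adaptive 1-7 s), in blocks 3-4 by size
(one vs two reward boli, both at 0.5 s). Side-value contingencies reverse
between consecutive blocks; blocks 1 and 3 carry the "original"
discrimination, blocks 2 and 4 its "reversal". An LED flag is raised on a
random 50% of trials (optogenetic illumination epoch); by default it has no
per-trial behavioral consequence, because inhibition effects are modeled
session-wide.

Free-choice choices and response times come from a drift-diffusion agent
whose drift toward the high-value side ramps over the first 20 trials of a
block (negative at reversal onset, reflecting the carried-over association),
so post-learning trials are stationary at the session's DDM parameters.

Sessions that exhaust a 2 h simulated time budget end early: trials never
presented produce no rows, so a completed session is exactly one whose log
contains every scheduled trial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ddm import DDMParams, simulate_trials

__all__ = [
    "GenerativeConfig",
    "TRIAL_COLUMNS",
    "assign_block_contingencies",
    "adaptive_delay_schedule",
    "generate_session",
    "write_trial_log",
    "read_trial_log",
]

#: Fixed trial-log schema (CSV header order).
TRIAL_COLUMNS = [
    "session_id",
    "condition",
    "block_index",
    "block_type",
    "discrimination",
    "trial_index_in_block",
    "odor",
    "led_on",
    "high_value_side",
    "initiated",
    "completed",
    "choice_side",
    "correct",
    "rewarded",
    "lo_latency",
    "rt",
    "mt",
    "well_time",
    "current_long_delay",
]

_BOOL_COLS = ["led_on", "initiated", "completed", "rewarded"]
_FLOAT_COLS = ["lo_latency", "rt", "mt", "well_time", "current_long_delay"]

SHORT_DELAY = 0.5  # s, reward delay on the short / non-manipulated side
LONG_DELAY_START = 1.0  # s, adaptive long delay starting value
LONG_DELAY_CAP = 7.0  # s, adaptive long delay ceiling
ODOR_DURATION = 0.5  # s, odor presentation within the 1 s hold
HOLD_DURATION = 1.0  # s, nose-poke hold required for completion


def _default_ddm_params() -> dict:
    return {
        "delay": DDMParams(alpha=1.6, tau=0.35, beta=0.55, delta=1.2),
        "size": DDMParams(alpha=1.5, tau=0.30, beta=0.55, delta=1.4),
    }


@dataclass
class GenerativeConfig:
    """Ground-truth parameters for one synthetic session.

    Probabilities are per-trial Bernoulli rates; latency families are
    log-normal (location/scale of log seconds) except well time, which is
    gamma (shape, scale in seconds). ``seed`` fully determines the output.
    """

    condition: str = "control"
    n_blocks: int = 4
    trials_per_block: int = 60
    free_choice_fraction: float = 1.0 / 3.0
    led_fraction: float = 0.5
    p_initiate: float = 0.93
    lo_latency_params: tuple = (0.10, 0.45)
    p_complete_given_initiated: float = 0.95
    ddm_params_by_blocktype: dict = field(default_factory=_default_ddm_params)
    well_time_params: tuple = (4.0, 0.4)
    well_time_large_bonus: float = 0.8
    initiation_window: float = 5.0
    completion_window: float = 3.0
    seed: int = 0
    # forced-choice accuracy: P(correct) = sigmoid(base + value_sign *
    # (value_gain + phase_gain * within-block progress))
    forced_acc_base: float = 1.5
    forced_acc_value: float = 0.5
    forced_acc_phase: float = 1.0
    # within-block learning ramp of the free-choice drift
    learning_ramp_trials: int = 20
    ramp_start_original: float = 0.2
    ramp_start_reversal: float = -0.5
    # movement time log-normal
    mt_params: tuple = (-0.8, 0.25)
    # event-time model: inter-trial pause log-normal, plus occasional
    # off-task disengagement pauses (probability per trial, mean seconds)
    iti_params: tuple = (2.4849, 0.6)
    pause_prob: float = 0.045
    pause_mean: float = 170.0
    session_time_budget: float = 7200.0
    # optional per-trial illumination effect: DDM parameters used on LED-on
    # trials when set (None = session-wide effects only)
    led_ddm_params_by_blocktype: dict | None = None

    def validate(self) -> None:
        for name in (
            "free_choice_fraction",
            "led_fraction",
            "p_initiate",
            "p_complete_given_initiated",
            "pause_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.trials_per_block < 1:
            raise ValueError(f"trials_per_block must be >= 1, got {self.trials_per_block}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.condition not in ("control", "inhibition"):
            raise ValueError(f"condition must be 'control' or 'inhibition', got {self.condition}")
        for key in ("delay", "size"):
            if key not in self.ddm_params_by_blocktype:
                raise ValueError(f"ddm_params_by_blocktype missing block type {key!r}")
        for name in ("lo_latency_params", "well_time_params", "mt_params", "iti_params"):
            pair = getattr(self, name)
            if len(pair) != 2 or pair[1] <= 0:
                raise ValueError(f"{name} must be a (location, positive scale) pair, got {pair}")

    def replace(self, **kw) -> "GenerativeConfig":
        return dataclasses.replace(self, **kw)


def assign_block_contingencies(block_index: int, initial_short_side: str) -> str:
    """High-value side for a block given the session's initial short side.

    Blocks 1 and 3 carry the original contingency; blocks 2 and 4 the
    reversal (opposite side).
    """
    if block_index not in (1, 2, 3, 4):
        raise ValueError(f"block_index must be in 1..4, got {block_index}")
    if initial_short_side not in ("left", "right"):
        raise ValueError(f"initial_short_side must be 'left' or 'right', got {initial_short_side}")
    other = "right" if initial_short_side == "left" else "left"
    return initial_short_side if block_index in (1, 3) else other


def adaptive_delay_schedule(free_choice_delayed_flags) -> np.ndarray:
    """Long-delay value (s) in effect at each free-choice trial.

    Starts at 1 s, increases by 1 s after every free-choice trial on which
    the delayed side was chosen, and never exceeds 7 s. Forced-choice trials
    are yoked to the current value.
    """
    flags = np.asarray(free_choice_delayed_flags, dtype=bool)
    out = np.empty(flags.size, dtype=float)
    cur = LONG_DELAY_START
    for i, f in enumerate(flags):
        out[i] = cur
        if f:
            cur = min(cur + 1.0, LONG_DELAY_CAP)
    return out


def _block_odor_sequence(rng, n_trials: int, free_fraction: float) -> np.ndarray:
    """Pseudorandom odor sequence with balanced forced-left/right counts."""
    n_free = int(round(n_trials * free_fraction))
    n_forced = n_trials - n_free
    n_left = n_forced // 2 + (rng.random() < 0.5) * (n_forced % 2)
    n_right = n_forced - n_left
    odors = np.array(
        ["free"] * n_free + ["forced_left"] * int(n_left) + ["forced_right"] * int(n_right)
    )
    rng.shuffle(odors)
    return odors


def _truncated_lognormal(rng, loc: float, scale: float, upper: float) -> float:
    """Draw from LogNormal(loc, scale) conditioned on being <= upper."""
    dist = sps.lognorm(s=scale, scale=np.exp(loc))
    u = rng.uniform(0.0, dist.cdf(upper))
    return float(dist.ppf(max(u, 1e-12)))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_session(config: GenerativeConfig, session_id: str | None = None) -> pd.DataFrame:
    """Simulate one session; returns a trial log (one row per presented trial)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if session_id is None:
        session_id = f"{config.condition}_{config.seed}"

    initial_short_side = str(rng.choice(["left", "right"]))
    rows = []
    elapsed = 0.0
    out_of_time = False

    for block_index in range(1, config.n_blocks + 1):
        if out_of_time:
            break
        block_type = "delay" if block_index <= 2 else "size"
        discrimination = "original" if block_index % 2 == 1 else "reversal"
        other_side = "right" if initial_short_side == "left" else "left"
        high_value_side = initial_short_side if block_index % 2 == 1 else other_side
        odors = _block_odor_sequence(rng, config.trials_per_block, config.free_choice_fraction)
        base = config.ddm_params_by_blocktype[block_type]
        ramp_start = (
            config.ramp_start_original if discrimination == "original" else config.ramp_start_reversal
        )
        long_delay = LONG_DELAY_START  # adaptive schedule resets per delay block

        for i, odor in enumerate(odors, start=1):
            if elapsed > config.session_time_budget:
                out_of_time = True
                break
            current_long_delay = long_delay if block_type == "delay" else SHORT_DELAY
            led_on = bool(rng.random() < config.led_fraction)
            row = {
                "session_id": session_id,
                "condition": config.condition,
                "block_index": block_index,
                "block_type": block_type,
                "discrimination": discrimination,
                "trial_index_in_block": i,
                "odor": odor,
                "led_on": led_on,
                "high_value_side": high_value_side,
                "initiated": False,
                "completed": False,
                "choice_side": "none",
                "correct": pd.NA,
                "rewarded": False,
                "lo_latency": np.nan,
                "rt": np.nan,
                "mt": np.nan,
                "well_time": np.nan,
                "current_long_delay": current_long_delay,
            }
            # inter-trial interval, with occasional off-task disengagement
            elapsed += rng.lognormal(*config.iti_params)
            if rng.random() < config.pause_prob:
                elapsed += rng.exponential(config.pause_mean)

            if rng.random() >= config.p_initiate:
                # houselights time out (5 s) then a 2 s dark interval
                elapsed += config.initiation_window + 2.0
                rows.append(row)
                continue
            row["initiated"] = True
            lo = _truncated_lognormal(rng, *config.lo_latency_params, config.initiation_window)
            row["lo_latency"] = lo
            elapsed += lo + HOLD_DURATION

            if rng.random() >= config.p_complete_given_initiated:
                elapsed += config.completion_window
                rows.append(row)
                continue

            params = base
            if led_on and config.led_ddm_params_by_blocktype is not None:
                params = config.led_ddm_params_by_blocktype[block_type]

            # learning ramp on the drift toward the high-value side
            progress = min(1.0, (i - 1) / config.learning_ramp_trials)
            delta_eff = params.delta * (ramp_start + (1.0 - ramp_start) * progress)
            trial_params = DDMParams(params.alpha, params.tau, params.beta, delta_eff)
            ddm_seed = int(rng.integers(2**31))
            choice_arr, rt_arr = simulate_trials(trial_params, 1, seed=ddm_seed)
            rt = float(rt_arr[0])
            if rt > config.completion_window:
                # response window elapsed before a well entry
                elapsed += config.completion_window
                rows.append(row)
                continue
            row["completed"] = True
            row["rt"] = rt
            mt = rng.lognormal(*config.mt_params)
            row["mt"] = mt
            elapsed += rt + mt

            phase_progress = (i - 1) / max(config.trials_per_block - 1, 1)
            if odor == "free":
                chose_high = bool(choice_arr[0] == 1)
                row["choice_side"] = (
                    high_value_side
                    if chose_high
                    else ("right" if high_value_side == "left" else "left")
                )
                row["rewarded"] = True  # both wells pay on free-choice trials
            else:
                cued = "left" if odor == "forced_left" else "right"
                value_sign = 1.0 if cued == high_value_side else -1.0
                p_correct = _sigmoid(
                    config.forced_acc_base
                    + value_sign * (config.forced_acc_value + config.forced_acc_phase * phase_progress)
                )
                correct = bool(rng.random() < p_correct)
                row["correct"] = correct
                row["choice_side"] = (
                    cued if correct else ("right" if cued == "left" else "left")
                )
                row["rewarded"] = correct

            chose_high_side = row["choice_side"] == high_value_side
            if row["rewarded"]:
                if block_type == "delay":
                    delay = SHORT_DELAY if chose_high_side else long_delay
                    n_boli = 1
                else:
                    delay = SHORT_DELAY
                    n_boli = 2 if chose_high_side else 1
                well = rng.gamma(*config.well_time_params)
                if n_boli == 2:
                    well += config.well_time_large_bonus
                row["well_time"] = well
                elapsed += delay + well
            else:
                elapsed += 1.0  # brief visit to the dry well

            # adaptive long delay: +1 s per free choice of the delayed side
            if block_type == "delay" and odor == "free" and not chose_high_side:
                long_delay = min(long_delay + 1.0, LONG_DELAY_CAP)
            rows.append(row)

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["correct"] = df["correct"].astype("boolean")
    for c in _BOOL_COLS:
        df[c] = df[c].astype(bool)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    return df


def write_trial_log(records: pd.DataFrame, path) -> None:
    """Write trial logs as CSV with the fixed schema; NA as empty field."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    records[TRIAL_COLUMNS].to_csv(path, index=False, na_rep="")


def read_trial_log(path) -> pd.DataFrame:
    """Read a trial-log CSV, validating the schema and restoring dtypes."""
    df = pd.read_csv(path, dtype={"session_id": str})
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing or extra:
        raise ValueError(f"trial log schema mismatch: missing={missing} extra={extra}")
    for c in _BOOL_COLS:
        bad = ~df[c].isin([True, False])
        if bad.any():
            raise ValueError(f"column {c!r} has unparseable boolean values")
        df[c] = df[c].astype(bool)
    df["correct"] = df["correct"].map(
        {True: True, False: False, "True": True, "False": False}
    ).astype("boolean")
    for c in _FLOAT_COLS:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        except (ValueError, TypeError) as e:
            raise ValueError(f"column {c!r} has unparseable numeric values") from e
    df = df[TRIAL_COLUMNS]
    return df
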