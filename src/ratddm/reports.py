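"""Posterior contrasts and the parameter-recovery harness.

The directional contrasts mirror the study's hypothesis tests: during
inhibition, larger boundary separation (positive shift), reduced drift rate
(negative shift), and reduced bias toward the better option (negative
shift). For each parameter and block type, P is the posterior probability
that the inhibition-minus-control group-mean difference lies in the
hypothesized direction, computed over paired draws (same chain and
iteration, since both conditions live in one joint posterior). P > 0.95 is
a significant effect in the hypothesized direction, P < 0.05 a significant
effect in the opposite direction, anything else no effect.

The recovery harness closes the loop: simulate sessions from known group
parameters with the task generator, prepare the free-choice data, fit the
hierarchical model, and compare posterior intervals with the ground truth.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .hier import MCMCConfig, fit_hierarchical_ddm, prepare_fit_data
from .presets import BLOCK_TYPES, EffectSizes, GroupTruth, default_group_truth, sample_session_config
from .task import generate_session

__all__ = [
    "HYPOTHESIZED_DIRECTIONS",
    "posterior_shift_probability",
    "classify",
    "contrast_report",
    "simulate_study",
    "recovery_experiment",
    "RECOVERY_SESSION_KW",
]

#: Hypothesized inhibition-minus-control shift directions (study hypotheses).
HYPOTHESIZED_DIRECTIONS = {"alpha": "positive", "delta": "negative", "beta": "negative"}

#: Session-config overrides used by the recovery design: a generous
#: free-choice fraction and near-perfect task engagement, yielding roughly 80
#: post-learning free-choice trials per session, with the time budget off.
RECOVERY_SESSION_KW = dict(
    free_choice_fraction=0.55,
    p_initiate=0.95,
    p_complete_given_initiated=0.97,
    session_time_budget=np.inf,
)


def posterior_shift_probability(
    draws, parameter: str, block_type: str, direction: str
) -> float:
    """P that the inhibition-control group-mean shift has the given sign.

    Paired by draw: the difference is taken within each (chain, iteration).
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    inh = draws.group_mean(parameter, block_type, "inhibition")
    ctl = draws.group_mean(parameter, block_type, "control")
    diff = inh - ctl
    if direction == "positive":
        return float((diff > 0).mean())
    return float((diff < 0).mean())


def classify(p: float) -> str:
    """Verdict for a shift probability: the >0.95 / <0.05 rule."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"P must be in [0, 1], got {p}")
    if p > 0.95:
        return "significant_hypothesized"
    if p < 0.05:
        return "significant_opposite"
    return "none"


def contrast_report(draws, directions: dict | None = None) -> pd.DataFrame:
    """Directional contrast per (parameter, block type).

    ``directions`` maps parameter name to hypothesized direction; defaults
    to the study hypotheses (boundary up, drift down, bias down).
    """
    directions = HYPOTHESIZED_DIRECTIONS if directions is None else directions
    rows = []
    for param, direction in directions.items():
        for bt in BLOCK_TYPES:
            p = posterior_shift_probability(draws, param, bt, direction)
            rows.append(
                {
                    "parameter": param,
                    "block_type": bt,
                    "direction": direction,
                    "P": p,
                    "verdict": classify(p),
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    n_sessions: int,
    seed: int,
    effects: EffectSizes | None = None,
    truth: GroupTruth | None = None,
    **session_kw,
) -> pd.DataFrame:
    """Simulate a balanced study (half control, half inhibition sessions)."""
    effects = EffectSizes() if effects is None else effects
    if truth is None:
        truth = default_group_truth(effects)
    rng = np.random.default_rng(seed)
    logs = []
    for i in range(n_sessions):
        cond = "control" if i % 2 == 0 else "inhibition"
        cfg = sample_session_config(cond, rng, effects=effects, truth=truth, **session_kw)
        logs.append(generate_session(cfg, session_id=f"{cond}_{i:03d}"))
    return pd.concat(logs, ignore_index=True)


def recovery_experiment(
    n_sessions: int = 20,
    seed: int = 0,
    effects: EffectSizes | None = None,
    truth: GroupTruth | None = None,
    mcmc_config: MCMCConfig | None = None,
    ci_level: float = 0.95,
    **session_kw,
) -> dict:
    """Simulate -> prepare -> fit -> compare against the generating truth.

    Reports, for each of the 32 group-level quantities, the true value,
    posterior mean, central credible interval and whether it covers the
    truth; aggregate bias/RMSE; the directional contrasts; and the maximum
    split-chain R-hat. Deterministic under ``seed`` (the sampler included).
    """
    effects = EffectSizes() if effects is None else effects
    if truth is None:
        truth = default_group_truth(effects)
    kw = {**RECOVERY_SESSION_KW, **session_kw}
    logs = simulate_study(n_sessions, seed, effects=effects, truth=truth, **kw)
    data = prepare_fit_data(logs)
    post = fit_hierarchical_ddm(data, mcmc_config=mcmc_config, seed=seed)

    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    true_values = truth.as_dict()
    group_level = {}
    errors = []
    for name, true in true_values.items():
        arr = post[name].ravel()
        lo, hi = np.quantile(arr, [lo_q, hi_q])
        group_level[name] = {
            "true": float(true),
            "post_mean": float(arr.mean()),
            "ci_lo": float(lo),
            "ci_hi": float(hi),
            "covered": bool(lo <= true <= hi),
        }
        errors.append(arr.mean() - true)
    errors = np.asarray(errors)
    rh = post.rhat()
    contrasts = contrast_report(post)
    return {
        "n_sessions": int(n_sessions),
        "n_trials": int(data.n_trials),
        "n_units": int(data.n_units),
        "seed": int(seed),
        "effects": asdict(effects),
        "group_level": group_level,
        "n_covered": int(sum(v["covered"] for v in group_level.values())),
        "n_quantities": len(group_level),
        "bias": float(errors.mean()),
        "rmse": float(np.sqrt((errors**2).mean())),
        "max_rhat": float(rh.max()),
        "contrasts": contrasts.to_dict(orient="records"),
    }
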