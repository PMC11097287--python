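"""Study-condition presets: default generative parameters and effect sizes.

The defaults encode the task conditions the package emulates: alternating
control/inhibition sessions of four 60-trial blocks, LED illumination on 50%
of trials, and a drift-diffusion agent whose parameters differ by block type
and condition. Inhibition effects are applied session-wide (both LED-on and
LED-off trials): reduced initiation and completion rates, slower light-on
latencies, longer off-task pauses, a reduced drift rate (strongly in delay
blocks, mildly in size blocks), and an increased starting bias in size
blocks.

Group-level ground truth lives on the unconstrained scale used by the
hierarchical model (log alpha, log tau, logit beta, identity delta) so that
parameter-recovery runs compare like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddm import DDMParams
from .task import GenerativeConfig

__all__ = [
    "PARAM_NAMES",
    "BLOCK_TYPES",
    "CONDITIONS",
    "EffectSizes",
    "GroupTruth",
    "default_group_truth",
    "constrain",
    "unconstrain",
    "default_config",
    "sample_session_config",
]

PARAM_NAMES = ("alpha", "tau", "beta", "delta")
BLOCK_TYPES = ("delay", "size")
CONDITIONS = ("control", "inhibition")


def constrain(u: np.ndarray) -> DDMParams:
    """Map an unconstrained 4-vector (log a, log t, logit b, d) to DDMParams."""
    u = np.asarray(u, dtype=float)
    return DDMParams(
        alpha=float(np.exp(u[0])),
        tau=float(np.exp(u[1])),
        beta=float(1.0 / (1.0 + np.exp(-u[2]))),
        delta=float(u[3]),
    )


def unconstrain(p: DDMParams) -> np.ndarray:
    """Inverse of :func:`constrain`."""
    return np.array(
        [np.log(p.alpha), np.log(p.tau), np.log(p.beta / (1.0 - p.beta)), p.delta]
    )


@dataclass(frozen=True)
class EffectSizes:
    """Inhibition-minus-control shifts applied session-wide.

    DDM shifts are on the unconstrained scale (log / logit / identity);
    behavioral shifts are on the natural scale.
    """

    drift_shift_delay: float = -0.8
    drift_shift_size: float = -0.3
    bias_shift_logit_size: float = 0.25
    bias_shift_logit_delay: float = 0.0
    boundary_shift_log: float = 0.0
    tau_shift_log: float = 0.0
    p_initiate_shift: float = -0.07
    lo_latency_loc_shift: float = 0.25
    p_complete_shift: float = -0.05
    pause_mean_scale: float = 1.3

    @classmethod
    def zero(cls) -> "EffectSizes":
        """Null effects: both conditions generatively identical."""
        return cls(
            drift_shift_delay=0.0,
            drift_shift_size=0.0,
            bias_shift_logit_size=0.0,
            bias_shift_logit_delay=0.0,
            boundary_shift_log=0.0,
            tau_shift_log=0.0,
            p_initiate_shift=0.0,
            lo_latency_loc_shift=0.0,
            p_complete_shift=0.0,
            pause_mean_scale=1.0,
        )

    def ddm_shift(self, block_type: str) -> np.ndarray:
        if block_type == "delay":
            return np.array(
                [self.boundary_shift_log, self.tau_shift_log,
                 self.bias_shift_logit_delay, self.drift_shift_delay]
            )
        return np.array(
            [self.boundary_shift_log, self.tau_shift_log,
             self.bias_shift_logit_size, self.drift_shift_size]
        )


_CONTROL_MU = {
    # unconstrained group means: [log alpha, log tau, logit beta, delta]
    "delay": np.array([np.log(1.6), np.log(0.35), np.log(0.55 / 0.45), 1.2]),
    "size": np.array([np.log(1.5), np.log(0.30), np.log(0.55 / 0.45), 1.4]),
}
_GROUP_SIGMA = np.array([0.15, 0.10, 0.25, 0.30])  # between-session SDs


@dataclass(frozen=True)
class GroupTruth:
    """Unconstrained group means/SDs per (block type, condition)."""

    mu: dict = field(default_factory=dict)  # (block_type, condition) -> (4,)
    sigma: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        """Flat {name: value} over all 32 group-level quantities."""
        out = {}
        for (bt, cond), m in self.mu.items():
            s = self.sigma[(bt, cond)]
            for k, p in enumerate(PARAM_NAMES):
                out[f"mu_{p}[{bt},{cond}]"] = float(m[k])
                out[f"sigma_{p}[{bt},{cond}]"] = float(s[k])
        return out


def default_group_truth(effects: EffectSizes | None = None) -> GroupTruth:
    """Ground-truth group parameters under the given effect sizes."""
    effects = EffectSizes() if effects is None else effects
    mu, sigma = {}, {}
    for bt in BLOCK_TYPES:
        mu[(bt, "control")] = _CONTROL_MU[bt].copy()
        mu[(bt, "inhibition")] = _CONTROL_MU[bt] + effects.ddm_shift(bt)
        for cond in CONDITIONS:
            sigma[(bt, cond)] = _GROUP_SIGMA.copy()
    return GroupTruth(mu=mu, sigma=sigma)


def _behavioral_overrides(condition: str, effects: EffectSizes) -> dict:
    base = GenerativeConfig()
    if condition == "control":
        return {}
    return {
        "p_initiate": base.p_initiate + effects.p_initiate_shift,
        "lo_latency_params": (
            base.lo_latency_params[0] + effects.lo_latency_loc_shift,
            base.lo_latency_params[1],
        ),
        "p_complete_given_initiated": (
            base.p_complete_given_initiated + effects.p_complete_shift
        ),
        "pause_mean": base.pause_mean * effects.pause_mean_scale,
    }


def default_config(
    condition: str, seed: int = 0, effects: EffectSizes | None = None, **overrides
) -> GenerativeConfig:
    """Session config at the group-mean DDM parameters for ``condition``."""
    effects = EffectSizes() if effects is None else effects
    truth = default_group_truth(effects)
    ddm = {bt: constrain(truth.mu[(bt, condition)]) for bt in BLOCK_TYPES}
    kw = {
        "condition": condition,
        "seed": seed,
        "ddm_params_by_blocktype": ddm,
        **_behavioral_overrides(condition, effects),
    }
    kw.update(overrides)
    return GenerativeConfig(**kw)


def sample_session_config(
    condition: str,
    rng: np.random.Generator,
    effects: EffectSizes | None = None,
    truth: GroupTruth | None = None,
    attention_sd: float = 0.7,
    **overrides,
) -> GenerativeConfig:
    """Draw one session's config from the hierarchical ground truth.

    Session-level DDM parameters are drawn per block type from
    Normal(mu, sigma) on the unconstrained scale. A latent per-session
    attention factor couples faster light-on latencies with higher
    forced-choice accuracy (sessions with shorter latencies are more
    accurate), producing the negative latency-accuracy correlation the
    analysis stage measures.
    """
    effects = EffectSizes() if effects is None else effects
    if truth is None:
        truth = default_group_truth(effects)
    ddm = {}
    for bt in BLOCK_TYPES:
        u = rng.normal(truth.mu[(bt, condition)], truth.sigma[(bt, condition)])
        ddm[bt] = constrain(u)
    base = GenerativeConfig()
    attention = float(rng.normal(0.0, 1.0))
    kw = {
        "condition": condition,
        "seed": int(rng.integers(2**31)),
        "ddm_params_by_blocktype": ddm,
        **_behavioral_overrides(condition, effects),
    }
    lo_loc = kw.get("lo_latency_params", base.lo_latency_params)[0]
    kw["lo_latency_params"] = (
        lo_loc - 0.3 * attention_sd * attention,
        base.lo_latency_params[1],
    )
    kw["forced_acc_base"] = base.forced_acc_base + attention_sd * attention
    kw.update(overrides)
    return GenerativeConfig(**kw)
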