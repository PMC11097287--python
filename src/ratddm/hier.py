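"""Hierarchical Bayesian drift-diffusion model over sessions.

Each session contributes one set of DDM parameters per block type (delay or
size); session-level parameters are partially pooled under group-level
means and SDs defined per block type x condition (4 groups x 4 parameters x
{mean, SD} = 32 group-level quantities). Parameters live on an unconstrained
scale — log boundary separation, log nondecision time, logit starting bias,
identity drift — where the group-level priors are Normal(0, 20) for the
means and half-Normal(0, 20) for the SDs of boundary, bias and drift, and
Normal(0, 1) / half-Normal(0, 1) for nondecision time.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme on the
centered parameterization:

* session-level parameters: vectorized random-walk Metropolis, one
  coordinate at a time across all session x block-type units simultaneously
  (their likelihoods are conditionally independent given the group level),
  with per-coordinate proposal scales adapted during warmup to a 0.44
  acceptance rate;
* group means: exact conjugate Gibbs draws;
* group SDs: univariate slice sampling with stepping-out.

Chains are initialized overdispersed around data-driven starting values, and
convergence is checked with the split-chain potential-scale-reduction
statistic (R-hat) for every parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import _wfpt_logpdf_fast
from .presets import BLOCK_TYPES, CONDITIONS, PARAM_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FitData",
    "MCMCConfig",
    "PosteriorDraws",
    "prepare_fit_data",
    "fit_hierarchical_ddm",
    "compute_rhat",
]

GROUPS = [(bt, cond) for bt in BLOCK_TYPES for cond in CONDITIONS]
_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}

# prior scales on the unconstrained scale, per parameter
# (alpha, tau, beta, delta): N(0, 20) except tau, N(0, 1)
_PRIOR_SCALE = np.array([20.0, 1.0, 20.0, 20.0])
_TAU_FRACTION = 0.95  # tau bounded above by this fraction of the unit's min rt


@dataclass
class FitData:
    """Prepared per-unit (session x block type) choice/RT data."""

    rt: np.ndarray  # (N,) response times, s
    choice: np.ndarray  # (N,) 1 = upper boundary (high-value side)
    unit_index: np.ndarray  # (N,) -> unit
    unit_session: list  # (U,) session ids
    unit_block_type: list  # (U,)
    unit_condition: list  # (U,)
    unit_group: np.ndarray  # (U,) -> group index into GROUPS

    @property
    def n_units(self) -> int:
        return len(self.unit_session)

    @property
    def n_trials(self) -> int:
        return self.rt.size

    @classmethod
    def empty(cls) -> "FitData":
        """No data: posterior equals the prior (useful for prior checks)."""
        return cls(
            rt=np.empty(0),
            choice=np.empty(0, dtype=int),
            unit_index=np.empty(0, dtype=int),
            unit_session=[],
            unit_block_type=[],
            unit_condition=[],
            unit_group=np.empty(0, dtype=int),
        )


def prepare_fit_data(
    logs: pd.DataFrame,
    exclude_first: int = 20,
    min_trials: int = 10,
    rt_max: float = 10.0,
    coding: str = "accuracy",
    completed_only: bool = True,
    n_blocks: int = 4,
    trials_per_block: int = 60,
) -> FitData:
    """Extract post-learning free-choice (choice, rt) sets per session.

    Keeps completed free-choice trials with ``trial_index_in_block >
    exclude_first``; the choice is coded so the upper boundary is the
    block's high-value side (``coding="accuracy"``) or the right side
    (``coding="stimulus"``). Sessions lacking ``min_trials`` usable trials
    in either block type are excluded, as are incomplete sessions when
    ``completed_only``; exclusion counts are logged.
    """
    if coding not in ("accuracy", "stimulus"):
        raise ValueError(f"coding must be 'accuracy' or 'stimulus', got {coding!r}")
    rows = logs[
        (logs["odor"] == "free")
        & logs["completed"]
        & (logs["trial_index_in_block"] > exclude_first)
    ].copy()
    n_rt_dropped = int(((rows["rt"] <= 0) | (rows["rt"] > rt_max)).sum())
    if n_rt_dropped:
        logger.info("dropped %d trials with rt outside (0, %.1f]", n_rt_dropped, rt_max)
    rows = rows[(rows["rt"] > 0) & (rows["rt"] <= rt_max)]

    rt, choice, unit_index = [], [], []
    unit_session, unit_block_type, unit_condition, unit_group = [], [], [], []
    n_excluded = 0
    for sid, g in logs.groupby("session_id", sort=False):
        if completed_only and len(g) != n_blocks * trials_per_block:
            n_excluded += 1
            logger.info("session %s excluded: incomplete", sid)
            continue
        sess_rows = rows[rows["session_id"] == sid]
        per_bt = {bt: sess_rows[sess_rows["block_type"] == bt] for bt in BLOCK_TYPES}
        if any(len(b) < min_trials for b in per_bt.values()):
            n_excluded += 1
            logger.info("session %s excluded: fewer than %d usable trials", sid, min_trials)
            continue
        cond = g["condition"].iloc[0]
        for bt in BLOCK_TYPES:
            b = per_bt[bt]
            u = len(unit_session)
            if coding == "accuracy":
                c = (b["choice_side"] == b["high_value_side"]).to_numpy().astype(int)
            else:
                c = (b["choice_side"] == "right").to_numpy().astype(int)
            rt.append(b["rt"].to_numpy(dtype=float))
            choice.append(c)
            unit_index.append(np.full(len(b), u))
            unit_session.append(sid)
            unit_block_type.append(bt)
            unit_condition.append(cond)
            unit_group.append(_GROUP_INDEX[(bt, cond)])
    if not unit_session:
        raise ValueError(f"no usable sessions ({n_excluded} excluded)")
    if n_excluded:
        logger.info("excluded %d sessions in total", n_excluded)
    return FitData(
        rt=np.concatenate(rt),
        choice=np.concatenate(choice),
        unit_index=np.concatenate(unit_index),
        unit_session=unit_session,
        unit_block_type=unit_block_type,
        unit_condition=unit_condition,
        unit_group=np.asarray(unit_group, dtype=int),
    )


@dataclass
class MCMCConfig:
    """Sampler configuration (defaults: 4 chains, 1000 warmup, 3000 draws)."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 3000
    sweeps_per_draw: int = 8
    init_jitter: float = 0.3
    rhat_warn: float = 1.02
    # prior scales per parameter (alpha, tau, beta, delta) on the
    # unconstrained scale; None = the default N(0,20)/N(0,1) scheme
    mean_prior_scales: tuple | None = None
    sd_prior_scales: tuple | None = None


@dataclass
class PosteriorDraws:
    """Labeled MCMC draws: group level (unconstrained mu/sigma) and session
    level (natural scale), each of shape (n_chains, n_samples)."""

    draws: dict
    n_chains: int
    n_warmup: int
    n_samples: int
    unit_session: list = field(default_factory=list)
    unit_block_type: list = field(default_factory=list)
    unit_condition: list = field(default_factory=list)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def parameter_names(self) -> list:
        return list(self.draws)

    def group_mean(self, param: str, block_type: str, condition: str) -> np.ndarray:
        """Unconstrained group-mean draws, shape (n_chains, n_samples)."""
        return self.draws[f"mu_{param}[{block_type},{condition}]"]

    def rhat(self) -> pd.Series:
        """Split-chain R-hat for every stored parameter."""
        return pd.Series({k: compute_rhat(v) for k, v in self.draws.items()})

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.draws.items():
            c, s = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "iteration": s.ravel(),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PosteriorDraws":
        draws = {}
        for name, g in df.groupby("parameter", sort=False):
            piv = g.pivot(index="chain", columns="iteration", values="value")
            draws[name] = piv.to_numpy()
        any_arr = next(iter(draws.values()))
        return cls(draws=draws, n_chains=any_arr.shape[0], n_warmup=0, n_samples=any_arr.shape[1])


def compute_rhat(chains: np.ndarray) -> float:
    """Split-chain potential-scale-reduction statistic.

    ``chains`` has shape (n_chains, n_draws) with n_chains >= 2 and at least
    4 draws per chain; each chain is split in half before the classic
    between/within variance comparison. Returns NaN (with a warning) for
    zero-variance chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains (shape (n_chains, n_draws))")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined")
        return np.nan
    b = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# --------------------------------------------------------------------------
# sampler internals


def _unit_loglik(data: FitData, theta: np.ndarray, tau_cap: np.ndarray) -> np.ndarray:
    """Log likelihood per unit given unconstrained theta (U, 4)."""
    if data.n_units == 0:
        return np.empty(0)
    idx = data.unit_index
    alpha = np.exp(theta[idx, 0])
    tau = np.exp(theta[idx, 1])
    beta = 1.0 / (1.0 + np.exp(-theta[idx, 2]))
    delta = np.ascontiguousarray(theta[idx, 3])
    lp = _wfpt_logpdf_fast(
        data.rt, data.choice == 1, alpha, tau, beta, delta, np.empty(data.rt.size)
    )
    ll = np.bincount(idx, weights=np.where(np.isfinite(lp), lp, -1e300), minlength=data.n_units)
    # nondecision time capped below each unit's minimum rt
    ll = np.where(np.exp(theta[:, 1]) < tau_cap, ll, -1e300)
    return ll


def _slice_sample_sigma(lp, x0: float, rng, width: float = 0.5, max_steps: int = 50) -> float:
    """One slice-sampling update for a positive scalar with target ``lp``."""
    y = lp(x0) + np.log(rng.uniform(1e-300, 1.0))
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if lo <= 0.0 or lp(lo) < y:
            break
        lo -= width
    lo = max(lo, 1e-8)
    for _ in range(max_steps):
        if lp(hi) < y:
            break
        hi += width
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if lp(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _init_state(data: FitData, rng, jitter: float):
    """Data-driven overdispersed initial state for one chain."""
    U = data.n_units
    theta = np.zeros((U, 4))
    for u in range(U):
        m = data.unit_index == u
        rts = data.rt[m]
        acc = data.choice[m].mean()
        tau0 = 0.6 * rts.min()
        theta[u] = [
            np.log(1.5),
            np.log(tau0),
            0.0,
            4.0 * (acc - 0.5),
        ]
    theta += jitter * rng.standard_normal(theta.shape) * np.array([1, 0.3, 1, 1])
    mu = np.zeros((4, 4))
    sigma = np.full((4, 4), 0.3)
    for g in range(4):
        sel = data.unit_group == g
        if sel.any():
            mu[g] = theta[sel].mean(axis=0)
    mu += jitter * rng.standard_normal(mu.shape) * np.array([1, 0.3, 1, 1]) * 0.5
    sigma *= np.exp(jitter * rng.standard_normal(sigma.shape) * 0.5)
    return theta, mu, sigma


def _run_chain(data: FitData, cfg: MCMCConfig, seed: int):
    rng = np.random.default_rng(seed)
    mean_scales = np.asarray(
        _PRIOR_SCALE if cfg.mean_prior_scales is None else cfg.mean_prior_scales, dtype=float
    )
    sd_scales = np.asarray(
        _PRIOR_SCALE if cfg.sd_prior_scales is None else cfg.sd_prior_scales, dtype=float
    )
    U = data.n_units
    theta, mu, sigma = _init_state(data, rng, cfg.init_jitter) if U else (
        np.zeros((0, 4)),
        np.zeros((4, 4)),
        np.full((4, 4), 1.0),
    )
    tau_cap = np.empty(U)
    for u in range(U):
        tau_cap[u] = _TAU_FRACTION * data.rt[data.unit_index == u].min()
    # clamp initial tau under its cap
    if U:
        theta[:, 1] = np.minimum(theta[:, 1], np.log(tau_cap) - 0.1)
        ll = _unit_loglik(data, theta, tau_cap)
        if not np.all(ll > -1e299):
            raise RuntimeError("sampler initialization failed: non-finite likelihood")
    else:
        ll = np.empty(0)

    step = np.full((U, 4), 0.15)
    n_iter = cfg.n_warmup + cfg.n_samples
    out_mu = np.empty((cfg.n_samples, 4, 4))
    out_sigma = np.empty((cfg.n_samples, 4, 4))
    out_theta = np.empty((cfg.n_samples, U, 4))
    groups_with_units = [g for g in range(4) if U and (data.unit_group == g).any()]
    group_sel = {g: data.unit_group == g for g in groups_with_units}
    t_adapt = 0

    for it in range(n_iter):
        for _ in range(cfg.sweeps_per_draw):
            t_adapt += 1
            # --- session-level parameters: vectorized RW Metropolis per
            # coordinate across all units
            for k in range(4):
                if U == 0:
                    break
                prop = theta.copy()
                prop[:, k] = theta[:, k] + step[:, k] * rng.standard_normal(U)
                ll_prop = _unit_loglik(data, prop, tau_cap)
                mu_u = mu[data.unit_group, k]
                sd_u = sigma[data.unit_group, k]
                lpr = -0.5 * ((prop[:, k] - mu_u) ** 2 - (theta[:, k] - mu_u) ** 2) / sd_u**2
                accept = np.log(rng.uniform(size=U)) < (ll_prop - ll + lpr)
                theta[accept, k] = prop[accept, k]
                ll = np.where(accept, ll_prop, ll)
                if it < cfg.n_warmup:
                    gam = min(0.25, t_adapt**-0.6)
                    step[:, k] *= np.exp(gam * (accept.astype(float) - 0.44))
            # --- group means: conjugate Gibbs
            for g in range(4):
                for k in range(4):
                    s0 = mean_scales[k]
                    if U and (data.unit_group == g).any():
                        th = theta[group_sel[g], k] if g in group_sel else theta[:0, k]
                        n_g = th.size
                        prec = 1.0 / s0**2 + n_g / sigma[g, k] ** 2
                        mean = (th.sum() / sigma[g, k] ** 2) / prec
                        mu[g, k] = mean + rng.standard_normal() / np.sqrt(prec)
                    else:
                        mu[g, k] = s0 * rng.standard_normal()
            # --- group SDs: slice sampling
            for g in range(4):
                for k in range(4):
                    s0 = sd_scales[k]
                    if U and g in group_sel:
                        th = theta[group_sel[g], k]
                        n_g = th.size
                        ssq = float(((th - mu[g, k]) ** 2).sum())

                        def lp(s, n_g=n_g, ssq=ssq, s0=s0):
                            if s <= 0:
                                return -np.inf
                            return -(s**2) / (2 * s0**2) - n_g * np.log(s) - ssq / (2 * s**2)

                        sigma[g, k] = _slice_sample_sigma(lp, sigma[g, k], rng)
                    else:
                        sigma[g, k] = abs(s0 * rng.standard_normal())
        if it >= cfg.n_warmup:
            j = it - cfg.n_warmup
            out_mu[j] = mu
            out_sigma[j] = sigma
            out_theta[j] = theta
    return out_mu, out_sigma, out_theta


def fit_hierarchical_ddm(
    data: FitData,
    mcmc_config: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the joint posterior of the multilevel DDM.

    Returns labeled draws for all 32 group-level quantities (unconstrained
    scale) and all session-level parameters (natural scale); warns when any
    split-chain R-hat is at or above the configured threshold (default 1.02).
    """
    cfg = MCMCConfig() if mcmc_config is None else mcmc_config
    if cfg.n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if data.n_units == 0:
        logger.info("fitting with no data: posterior equals the prior")
    for u in range(data.n_units):
        m = data.unit_index == u
        if np.ptp(data.rt[m]) == 0.0 or len(set(data.choice[m])) < 2:
            warnings.warn(
                f"degenerate data for unit {data.unit_session[u]}/{data.unit_block_type[u]}"
                " (constant rt or one-sided choices); parameters may be non-identifiable"
            )
    chains = []
    for c in range(cfg.n_chains):
        chains.append(_run_chain(data, cfg, seed=(int(seed) * 1000003 + c) % (2**31)))

    draws = {}
    for gi, (bt, cond) in enumerate(GROUPS):
        for k, p in enumerate(PARAM_NAMES):
            draws[f"mu_{p}[{bt},{cond}]"] = np.stack([ch[0][:, gi, k] for ch in chains])
            draws[f"sigma_{p}[{bt},{cond}]"] = np.stack([ch[1][:, gi, k] for ch in chains])
    transforms = (np.exp, np.exp, lambda x: 1.0 / (1.0 + np.exp(-x)), lambda x: x)
    for u in range(data.n_units):
        sid = data.unit_session[u]
        bt = data.unit_block_type[u]
        for k, p in enumerate(PARAM_NAMES):
            draws[f"{p}[{sid},{bt}]"] = transforms[k](
                np.stack([ch[2][:, u, k] for ch in chains])
            )
    post = PosteriorDraws(
        draws=draws,
        n_chains=cfg.n_chains,
        n_warmup=cfg.n_warmup,
        n_samples=cfg.n_samples,
        unit_session=list(data.unit_session),
        unit_block_type=list(data.unit_block_type),
        unit_condition=list(data.unit_condition),
    )
    if data.n_units:
        rh = post.rhat()
        if (rh >= cfg.rhat_warn).any():
            worst = rh.idxmax()
            warnings.warn(
                f"convergence warning: max R-hat {rh.max():.3f} ({worst}) >= {cfg.rhat_warn}"
            )
    return post
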