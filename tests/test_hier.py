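"""Data preparation, R-hat, and the hierarchical sampler."""

import numpy as np
import pandas as pd
import pytest

from ratddm.ddm import DDMParams, simulate_trials
from ratddm.hier import (
    FitData,
    MCMCConfig,
    PosteriorDraws,
    compute_rhat,
    fit_hierarchical_ddm,
    prepare_fit_data,
)
from ratddm.presets import default_config
from ratddm.task import generate_session

FAST_MCMC = MCMCConfig(n_chains=2, n_warmup=150, n_samples=250, sweeps_per_draw=4)


def _constructed_log(n_free_per_block=30, sid="s1"):
    """A fully completed 4x60 session with free-choice trials at known
    indices (the last n_free positions of each block)."""
    rows = []
    for block in (1, 2, 3, 4):
        bt = "delay" if block <= 2 else "size"
        for i in range(1, 61):
            free = i > 60 - n_free_per_block
            rows.append(
                {
                    "session_id": sid,
                    "condition": "control",
                    "block_index": block,
                    "block_type": bt,
                    "discrimination": "original" if block % 2 else "reversal",
                    "trial_index_in_block": i,
                    "odor": "free" if free else "forced_left",
                    "led_on": False,
                    "high_value_side": "left",
                    "initiated": True,
                    "completed": True,
                    "choice_side": "left",
                    "correct": pd.NA if free else True,
                    "rewarded": True,
                    "lo_latency": 1.0,
                    "rt": 0.7,
                    "mt": 0.4,
                    "well_time": 1.2,
                    "current_long_delay": 1.0,
                }
            )
    df = pd.DataFrame(rows)
    df["correct"] = df["correct"].astype("boolean")
    return df


class TestPrepareFitData:
    def test_exact_retained_count_on_constructed_log(self):
        """Free-choice trials occupy indices 31..60; only those past index
        20 are eligible, i.e. all 30 per block, 60 per block type."""
        data = prepare_fit_data(_constructed_log())
        assert data.n_units == 2
        assert data.n_trials == 120
        counts = np.bincount(data.unit_index)
        assert counts.tolist() == [60, 60]

    def test_boundary_of_exclusion_rule(self):
        """A free-choice trial at index 20 is excluded; index 21 included."""
        df = _constructed_log(n_free_per_block=41)  # free from index 20 on
        data = prepare_fit_data(df)
        # index 20 dropped, 21..60 kept: 40 per block, 80 per block type
        assert np.bincount(data.unit_index).tolist() == [80, 80]

    def test_all_forced_session_rejected(self):
        df = _constructed_log()
        df["odor"] = "forced_left"
        with pytest.raises(ValueError, match="no usable sessions"):
            prepare_fit_data(df)

    def test_incomplete_session_excluded(self):
        df = _constructed_log()
        both = pd.concat([df, _constructed_log(sid="s2").iloc[:150]], ignore_index=True)
        data = prepare_fit_data(both)
        assert set(data.unit_session) == {"s1"}

    def test_min_trials_threshold(self):
        df = _constructed_log(n_free_per_block=4)  # 8 usable per block type
        with pytest.raises(ValueError):
            prepare_fit_data(df, min_trials=10)
        data = prepare_fit_data(df, min_trials=8)
        assert data.n_units == 2

    def test_accuracy_coding_maps_high_value_to_upper(self, control_session):
        data = prepare_fit_data(control_session, completed_only=False)
        rows = control_session[
            (control_session.odor == "free")
            & control_session.completed
            & (control_session.trial_index_in_block > 20)
        ]
        expected = (rows.choice_side == rows.high_value_side).mean()
        assert data.choice.mean() == pytest.approx(expected)

    def test_stimulus_coding_option(self, control_session):
        data = prepare_fit_data(control_session, completed_only=False, coding="stimulus")
        rows = control_session[
            (control_session.odor == "free")
            & control_session.completed
            & (control_session.trial_index_in_block > 20)
        ]
        assert data.choice.mean() == pytest.approx((rows.choice_side == "right").mean())


class TestComputeRhat:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 3000))
        assert compute_rhat(chains) < 1.01

    def test_offset_chains_detected(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500))
        chains[1] += 5.0
        assert compute_rhat(chains) > 1.5

    def test_within_chain_drift_detected_by_split(self):
        """A strong trend inside each chain inflates split R-hat."""
        base = np.linspace(0, 5, 400)
        chains = np.stack([base, base + 0.01])
        assert compute_rhat(chains) > 1.2

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            compute_rhat(np.zeros((1, 100)))

    def test_zero_variance_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(compute_rhat(np.ones((2, 100))))

    def test_matches_arviz_split_rhat(self):
        """Cross-check against the reference diagnostic implementation."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 800)) + rng.normal(size=(4, 1)) * 0.05
        mine = compute_rhat(chains)
        ref = float(az.rhat(az.convert_to_dataset(chains), method="split")["x"].values)
        assert mine == pytest.approx(ref, abs=1e-3)


def _synthetic_fit_data(n_per_cell=2, n_trials=120, seed=0, params=None):
    """FitData assembled directly from DDM simulations (no task layer)."""
    params = params or DDMParams(1.6, 0.3, 0.55, 1.2)
    rt, ch, idx = [], [], []
    unit_session, unit_bt, unit_cond, unit_group = [], [], [], []
    u = 0
    g = 0
    for bt in ("delay", "size"):
        for cond in ("control", "inhibition"):
            for s in range(n_per_cell):
                c, r = simulate_trials(params, n_trials, seed=seed * 971 + u)
                rt.append(r)
                ch.append(c)
                idx.append(np.full(n_trials, u))
                unit_session.append(f"{cond}_{s}")
                unit_bt.append(bt)
                unit_cond.append(cond)
                unit_group.append(g)
                u += 1
            g += 1
    return FitData(
        rt=np.concatenate(rt),
        choice=np.concatenate(ch).astype(int),
        unit_index=np.concatenate(idx),
        unit_session=unit_session,
        unit_block_type=unit_bt,
        unit_condition=unit_cond,
        unit_group=np.array(unit_group),
    )


class TestFitHierarchicalDDM:
    def test_reproducible_under_fixed_seed(self):
        data = _synthetic_fit_data(n_per_cell=1, n_trials=60)
        a = fit_hierarchical_ddm(data, FAST_MCMC, seed=7)
        b = fit_hierarchical_ddm(data, FAST_MCMC, seed=7)
        for name in a.parameter_names():
            np.testing.assert_array_equal(a[name], b[name])

    def test_draw_shapes_and_labels(self):
        data = _synthetic_fit_data(n_per_cell=1, n_trials=60)
        post = fit_hierarchical_ddm(data, FAST_MCMC, seed=1)
        assert post["mu_delta[delay,control]"].shape == (2, 250)
        group_names = [n for n in post.parameter_names() if n.startswith(("mu_", "sigma_"))]
        assert len(group_names) == 32
        assert post["alpha[control_0,delay]"].min() > 0
        assert (post["beta[control_0,size]"].ravel() < 1).all()

    def test_session_posterior_tracks_generating_parameters(self):
        """With plenty of trials, session-level posteriors land near the
        simulating DDM parameters."""
        true = DDMParams(1.6, 0.3, 0.55, 1.2)
        data = _synthetic_fit_data(n_per_cell=2, n_trials=250, seed=3, params=true)
        post = fit_hierarchical_ddm(
            data, MCMCConfig(n_chains=2, n_warmup=250, n_samples=400, sweeps_per_draw=6), seed=2
        )
        for sid, bt in [("control_0", "delay"), ("inhibition_0", "size")]:
            assert abs(np.mean(post[f"alpha[{sid},{bt}]"]) - true.alpha) < 0.35
            assert abs(np.mean(post[f"tau[{sid},{bt}]"]) - true.tau) < 0.08
            assert abs(np.mean(post[f"delta[{sid},{bt}]"]) - true.delta) < 0.6

    def test_pooling_limit_collapses_sessions_to_group_mean(self):
        """With the group-SD prior forced to ~0, all sessions in a group
        collapse onto the group mean."""
        data = _synthetic_fit_data(n_per_cell=3, n_trials=40, seed=5)
        cfg = MCMCConfig(
            n_chains=2, n_warmup=150, n_samples=200, sweeps_per_draw=4,
            sd_prior_scales=(1e-4, 1e-4, 1e-4, 1e-4),
        )
        post = fit_hierarchical_ddm(data, cfg, seed=3)
        mu = post["mu_delta[delay,control]"]
        spread = [
            np.abs(np.log(post[f"alpha[control_{s},delay]"])
                   - post["mu_alpha[delay,control]"]).mean()
            for s in range(3)
        ]
        assert max(spread) < 0.01
        deltas = np.stack([post[f"delta[control_{s},delay]"] for s in range(3)])
        assert np.abs(deltas - mu).max() < 0.01

    def test_prior_only_fit_reproduces_prior_quantiles(self):
        """Fitting with no data returns the prior: N(0,20) group means for
        boundary/bias/drift, N(0,1) for nondecision, half-normal SDs."""
        cfg = MCMCConfig(n_chains=2, n_warmup=100, n_samples=4000, sweeps_per_draw=1)
        post = fit_hierarchical_ddm(FitData.empty(), cfg, seed=11)
        mu_d = post["mu_delta[delay,control]"].ravel()
        assert abs(mu_d.mean()) < 1.0
        assert mu_d.std() == pytest.approx(20.0, rel=0.08)
        mu_t = post["mu_tau[size,inhibition]"].ravel()
        assert mu_t.std() == pytest.approx(1.0, rel=0.08)
        sig = post["sigma_alpha[delay,control]"].ravel()
        assert (sig > 0).all()
        # half-normal(20) median = 20 * Phi^-1(0.75) ~ 13.49
        assert np.median(sig) == pytest.approx(13.49, rel=0.1)

    def test_precision_monotonicity_with_more_data(self):
        """A group observing 8x more trials gets a narrower posterior on its
        group mean than a sparse group."""
        big = _synthetic_fit_data(n_per_cell=4, n_trials=160, seed=8)
        # thin the inhibition/size group to 1/8 of its trials
        rt, ch, idx = [], [], []
        for u in range(big.n_units):
            m = big.unit_index == u
            r, c = big.rt[m], big.choice[m]
            if big.unit_block_type[u] == "size" and big.unit_condition[u] == "inhibition":
                r, c = r[:20], c[:20]
            rt.append(r)
            ch.append(c)
            idx.append(np.full(r.size, u))
        data = FitData(
            rt=np.concatenate(rt), choice=np.concatenate(ch),
            unit_index=np.concatenate(idx), unit_session=big.unit_session,
            unit_block_type=big.unit_block_type, unit_condition=big.unit_condition,
            unit_group=big.unit_group,
        )
        post = fit_hierarchical_ddm(
            data, MCMCConfig(n_chains=2, n_warmup=200, n_samples=300, sweeps_per_draw=5), seed=4
        )
        wide = np.subtract(*np.quantile(post["mu_delta[size,inhibition]"], [0.975, 0.025]))
        narrow = np.subtract(*np.quantile(post["mu_delta[size,control]"], [0.975, 0.025]))
        assert narrow < wide

    def test_degenerate_data_surfaces_warning(self):
        """All-equal rts (non-identifiable) are flagged, not fit silently."""
        data = _synthetic_fit_data(n_per_cell=1, n_trials=30)
        data.rt[:] = 0.8
        with pytest.warns(UserWarning, match="degenerate"):
            fit_hierarchical_ddm(
                data, MCMCConfig(n_chains=2, n_warmup=30, n_samples=40, sweeps_per_draw=1), seed=2
            )

    def test_single_chain_config_rejected(self):
        with pytest.raises(ValueError):
            fit_hierarchical_ddm(
                _synthetic_fit_data(n_per_cell=1, n_trials=30), MCMCConfig(n_chains=1), seed=0
            )

    def test_draws_round_trip_through_long_dataframe(self):
        data = _synthetic_fit_data(n_per_cell=1, n_trials=40)
        post = fit_hierarchical_ddm(
            data, MCMCConfig(n_chains=2, n_warmup=50, n_samples=60, sweeps_per_draw=2), seed=9
        )
        df = post.to_dataframe()
        back = PosteriorDraws.from_dataframe(df)
        for name in post.parameter_names():
            np.testing.assert_allclose(back[name], post[name])
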