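import math

import numpy as np
import pytest

from chromstate.engine import (
    RateModifiers,
    SimulationConfig,
    apply_knob,
    draw_move,
    recruitment_step,
    replicate,
    run,
)
from chromstate.rules import Enzyme


class TestConfig:
    def test_defaults(self):
        cfg = SimulationConfig()
        assert cfg.n == 20
        assert cfg.beta == 0.1
        assert cfg.prdub_direct == 0.15
        assert cfg.duration == 50_000
        assert cfg.generation_time == 20

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 3},
            {"n": 0},
            {"beta": -0.1},
            {"duration": -1},
            {"sample_interval": 0},
            {"initial_condition": "bogus"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_negative_multiplier(self):
        with pytest.raises(ValueError):
            RateModifiers(prc1=-1)

    def test_dict_roundtrip(self):
        cfg = SimulationConfig(beta=0.2, multipliers=RateModifiers(prc2=0.5))
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestKnobs:
    def test_nurd_sets_both_channels(self):
        cfg = apply_knob(SimulationConfig(), "nurd", 0.5)
        assert cfg.nurd_direct == 0.5
        assert cfg.multipliers.prc2_kdm_nurd == 0.5

    def test_prdub_sets_direct_rate(self):
        cfg = apply_knob(SimulationConfig(), "prdub", 0.3)
        assert cfg.prdub_direct == 0.3

    def test_enzyme_knobs(self):
        cfg = SimulationConfig()
        assert apply_knob(cfg, "utx", 2.0).multipliers.trxg_utx == 2.0
        assert apply_knob(cfg, "cbp", 0.5).multipliers.trxg_cbp == 0.5
        assert apply_knob(cfg, "kdm", 0.0).multipliers.prc2_kdm == 0.0

    def test_plain_field(self):
        assert apply_knob(SimulationConfig(), "beta", 0.7).beta == 0.7

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            apply_knob(SimulationConfig(), "nurdd", 1.0)


class TestDrawMove:
    def test_half_uniforms(self, stub_rng_factory):
        rng = stub_rng_factory(uniforms=[0.5, 0.5, 0.5, 0.5])
        draw = draw_move(rng, beta=0.1, dn=0.25, dp=0.15)
        ln2 = math.log(2.0)
        assert draw.t1 == pytest.approx(ln2)
        assert draw.t2 == pytest.approx(ln2 / 0.1)
        assert draw.t3 == pytest.approx(ln2 / 0.25)
        assert draw.t4 == pytest.approx(ln2 / 0.15)
        assert draw.chosen == 0
        assert draw.dt == pytest.approx(ln2)

    def test_zero_rates_give_recruitment(self, stub_rng_factory):
        rng = stub_rng_factory(uniforms=[0.9, 0.9, 0.9, 0.9])
        draw = draw_move(rng, beta=0.0, dn=0.0, dp=0.0)
        assert draw.chosen == 0
        assert math.isinf(draw.t2) and math.isinf(draw.t3) and math.isinf(draw.t4)

    def test_minimum_wins(self, stub_rng_factory):
        # brute-force oracle: t1=-ln(0.99), t2=-ln(0.01)/1.0, ...
        rng = stub_rng_factory(uniforms=[0.99, 0.01, 0.99, 0.99])
        draw = draw_move(rng, beta=1.0, dn=1.0, dp=1.0)
        ts = [-math.log(0.99), -math.log(0.01), -math.log(0.99), -math.log(0.99)]
        assert draw.chosen == int(np.argmin(ts)) == 0
        assert draw.dt == pytest.approx(min(ts))


class TestRecruitmentStep:
    def test_all_unmodified_never_changes(self, stub_rng_factory):
        array = np.full(4, 8, dtype=np.int8)
        rng = stub_rng_factory(integers=[2])
        assert recruitment_step(array, rng, RateModifiers()) is None
        assert (array == 8).all()

    def test_prc1_ubiquitinates(self, stub_rng_factory):
        # recruiter at 0 (state 12), enzyme PRC1 (slot 0 of its 4 recruiters),
        # target draw 0 -> position 1 (state 8): gains ub -> state 7
        array = np.array([12, 8], dtype=np.int8)
        rng = stub_rng_factory(integers=[0, 0, 0])
        result = recruitment_step(array, rng, RateModifiers())
        assert result == (1, 7, Enzyme.PRC1)
        assert array[1] == 7

    def test_h2aub_blocks_trxg(self, stub_rng_factory):
        # recruiter state 4 recruits TRXG (slot 0); target state 7 carries
        # H2Aub so TRXG cannot write
        array = np.array([4, 7], dtype=np.int8)
        rng = stub_rng_factory(integers=[0, 0, 0])
        assert recruitment_step(array, rng, RateModifiers()) is None
        assert array[1] == 7

    def test_target_excludes_self(self, stub_rng_factory):
        # with n=2 and recruiter index 1, the single target draw 0 must map
        # to position 0
        array = np.array([8, 12], dtype=np.int8)
        rng = stub_rng_factory(integers=[1, 0, 0])
        result = recruitment_step(array, rng, RateModifiers())
        assert result is not None and result[0] == 0

    def test_multiplier_rejection(self, stub_rng_factory):
        array = np.array([12, 8], dtype=np.int8)
        mult = RateModifiers(prc1=0.5)
        # acceptance uniform 0.9 >= 0.5 -> rejected
        rng = stub_rng_factory(integers=[0, 0, 0], uniforms=[0.9])
        assert recruitment_step(array, rng, mult) is None
        # acceptance uniform 0.1 < 0.5 -> accepted
        rng = stub_rng_factory(integers=[0, 0, 0], uniforms=[0.1])
        assert recruitment_step(array, rng, mult) is not None

    def test_zero_multiplier_never_accepts(self, stub_rng_factory):
        array = np.array([12, 8], dtype=np.int8)
        mult = RateModifiers(prc1=0.0)
        rng = stub_rng_factory(integers=[0, 0, 0], uniforms=[0.0])
        assert recruitment_step(array, rng, mult) is None


class TestReplicate:
    def test_all_reset(self, stub_rng_factory):
        array = np.array([1, 11, 12, 2], dtype=np.int8)
        rng = stub_rng_factory(uniforms=[0.1] * 4)
        replicate(array, rng)
        assert (array == 8).all()

    def test_none_reset(self, stub_rng_factory):
        array = np.array([1, 11, 12, 2], dtype=np.int8)
        rng = stub_rng_factory(uniforms=[0.9] * 4)
        replicate(array, rng)
        assert list(array) == [1, 11, 12, 2]

    def test_mean_reset_fraction(self):
        rng = np.random.default_rng(42)
        resets = []
        for _ in range(500):
            array = np.full(20, 1, dtype=np.int8)
            replicate(array, rng)
            resets.append((array == 8).mean())
        assert np.mean(resets) == pytest.approx(0.5, abs=0.02)


class TestRun:
    def test_zero_duration(self, warm_kernel):
        traj = run(SimulationConfig(duration=0.0))
        assert traj.n_samples == 1
        assert (traj.states[0] == 8).all()

    def test_determinism(self, warm_kernel):
        a = run(SimulationConfig(duration=200, seed=5))
        b = run(SimulationConfig(duration=200, seed=5))
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.times, b.times)

    def test_seed_sensitivity(self, warm_kernel):
        a = run(SimulationConfig(duration=200, seed=5))
        b = run(SimulationConfig(duration=200, seed=6))
        assert not np.array_equal(a.states, b.states)

    def test_sampling_schedule(self, short_run):
        assert short_run.n_samples == 2001
        assert np.allclose(np.diff(short_run.times), 1.0)

    def test_initial_conditions(self, warm_kernel):
        for ic, value in (("all_active", 1), ("all_silent", 11)):
            traj = run(SimulationConfig(duration=0, initial_condition=ic))
            assert (traj.states[0] == value).all()
        traj = run(SimulationConfig(duration=0, initial_condition="uniform_random"))
        assert ((traj.states[0] >= 1) & (traj.states[0] <= 12)).all()

    def test_states_always_valid(self, short_run):
        assert ((short_run.states >= 1) & (short_run.states <= 12)).all()

    def test_replication_events(self, warm_kernel):
        traj = run(SimulationConfig(duration=400, seed=2, replication_on=True))
        times = traj.replication_times
        # events every ~20 plotted units
        assert len(times) == pytest.approx(20, abs=2)
        assert np.all(np.diff(times) >= 20.0)
        # each event fires at the first step crossing its boundary, so events
        # sit at ~multiples of 20 with only a small cumulative overshoot
        expected = 20.0 * np.arange(1, len(times) + 1)
        assert np.all(np.abs(times - expected) < 2.0)
        assert traj.stats["replications"] == len(times)

    def test_no_replication_by_default(self, short_run):
        assert len(short_run.replication_times) == 0

    def test_recruitment_off_stationary_state8(self, warm_kernel):
        # With recruitment disabled the per-site direct chain has the product
        # stationary law: 1/2 unmarked K27 x 1/2 K4/36 x 1/2 H2A = 1/8 for
        # state 8 (loose check here; the 3-sigma check is in acceptance).
        cfg = SimulationConfig(
            beta=1.0,
            nurd_direct=0.0,
            prdub_direct=0.0,
            multipliers=RateModifiers(0, 0, 0, 0, 0, 0, 0),
            duration=5000,
            seed=9,
        )
        traj = run(cfg)
        frac8 = (traj.states == 8).mean()
        assert frac8 == pytest.approx(1 / 8, abs=0.02)

    def test_monostable_active_without_pcg(self, warm_kernel):
        # with all PcG channels off, the system reaches and holds category-1
        # dominance
        from chromstate.analysis import classify_regime

        cfg = SimulationConfig(
            beta=0.02,
            nurd_direct=0.0,
            multipliers=RateModifiers(prc1=0, prc2=0, prc2_kdm=0, prc2_kdm_nurd=0),
            duration=3000,
            seed=3,
        )
        call = classify_regime(run(cfg))
        assert call.regime == "active"
        assert call.avg_cat1 > 0.8
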