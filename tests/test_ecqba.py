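import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oberisk.ecqba import (
    BatState,
    SwarmConfig,
    accept_candidate,
    adapt_parameters,
    binarize,
    global_move,
    init_swarm,
    quantum_local_search,
    random_walk_local_search,
    run_ecqba,
    swarm_entropy,
    _encode_mask,
)


def _bat(d=3, **kw):
    defaults = dict(
        position_real=np.zeros(d),
        position_bin=np.zeros(d, np.int8),
        velocity=np.zeros(d),
        frequency=0.0,
        loudness=1.0,
        pulse_rate=0.5,
        fitness=0.5,
    )
    defaults.update(kw)
    return BatState(**defaults)


class TestInitSwarm:
    def test_positions_inside_box_and_initial_parameters(self):
        cfg = SwarmConfig(n_bats=10, b_min=-2.0, b_max=3.0, seed=1)
        bats = init_swarm(cfg, d=5)
        for b in bats:
            assert np.all((b.position_real >= -2.0) & (b.position_real <= 3.0))
            assert np.all(b.velocity == 0)
            assert b.loudness == cfg.loudness_init
            assert b.pulse_rate == cfg.pulse_rate_init
        assert any(b.position_bin.any() for b in bats)

    def test_degenerate_bounds_collapse(self):
        cfg = SwarmConfig(n_bats=4, b_min=0.7, b_max=0.7, seed=0)
        for b in init_swarm(cfg, d=3):
            assert np.all(b.position_real == 0.7)

    def test_fixed_seed_reproducible(self):
        cfg = SwarmConfig(n_bats=6, seed=11)
        a = init_swarm(cfg, d=4)
        b = init_swarm(cfg, d=4)
        for x, y in zip(a, b):
            assert np.array_equal(x.position_real, y.position_real)
            assert np.array_equal(x.position_bin, y.position_bin)


class TestSwarmEntropy:
    def test_uniform_fitnesses_maximal_entropy(self):
        for n in (2, 5, 30):
            ent = swarm_entropy(np.full(n, 0.37))
            assert np.allclose(ent.probs, 1.0 / n)
            assert ent.H_norm == pytest.approx(1.0)

    def test_degenerate_distribution_zero_entropy(self):
        ent = swarm_entropy(np.array([0.0, 60.0, 60.0, 60.0]))
        assert ent.H == pytest.approx(0.0, abs=1e-9)
        assert ent.H_norm == pytest.approx(0.0, abs=1e-9)

    def test_hand_softmax_entropy(self):
        # fitnesses (0, ln 3) -> probs (0.75, 0.25) -> H = 0.811278... bits
        ent = swarm_entropy(np.array([0.0, math.log(3)]))
        assert np.allclose(ent.probs, [0.75, 0.25])
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert ent.H == pytest.approx(expected, abs=1e-9)
        assert ent.H_norm == pytest.approx(expected, abs=1e-9)  # log2(2)=1

    def test_single_bat_warns_and_zero(self):
        with pytest.warns(UserWarning, match="single-bat"):
            ent = swarm_entropy(np.array([0.2]))
        assert ent.H_norm == 0.0

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_invariants(self, fitnesses):
        ent = swarm_entropy(np.array(fitnesses))
        assert ent.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert -1e-12 <= ent.H_norm <= 1.0 + 1e-12
        assert 0 <= ent.H <= math.log2(len(fitnesses)) + 1e-9


class TestAdaptParameters:
    def _ent(self, h):
        return swarm_entropy(np.zeros(2))._replace_hnorm(h) if False else type(
            "E", (), {"H_norm": h, "H": h, "probs": None}
        )()

    def test_collapsed_swarm_endpoint(self):
        bat = _bat(loudness=0.8)
        adapt_parameters(bat, self._ent(0.0), t=1, cfg=SwarmConfig())
        assert bat.frequency == SwarmConfig().f_min
        assert bat.loudness == 0.8  # unchanged

    def test_diverse_swarm_endpoint(self):
        bat = _bat(loudness=0.8)
        cfg = SwarmConfig()
        adapt_parameters(bat, self._ent(1.0), t=1, cfg=cfg)
        assert bat.frequency == cfg.f_max
        assert bat.loudness == 0.0

    def test_hand_arithmetic(self):
        bat = _bat(loudness=0.8, pulse_rate=0.5)
        cfg = SwarmConfig(gamma=0.9)
        adapt_parameters(bat, self._ent(0.5), t=2, cfg=cfg)
        assert bat.loudness == pytest.approx(0.4)
        assert bat.pulse_rate == pytest.approx(0.5 * (1 - math.exp(-0.9)), abs=1e-4)

    def test_classic_variant_uses_alpha_decay(self):
        bat = _bat(loudness=1.0)
        cfg = SwarmConfig(entropy_control=False, alpha=0.9)
        adapt_parameters(bat, self._ent(0.5), t=1, cfg=cfg,
                         rng=np.random.default_rng(0))
        assert bat.loudness == pytest.approx(0.9)
        assert cfg.f_min <= bat.frequency <= cfg.f_max


class TestMoves:
    def test_global_move_at_best_is_inertial(self):
        bat = _bat(position_real=np.array([1.0, 1.0]),
                   velocity=np.array([0.5, -0.5]), frequency=2.0)
        cand = global_move(bat, best_position=np.array([1.0, 1.0]))
        assert np.allclose(bat.velocity, [0.5, -0.5])  # unchanged
        assert np.allclose(cand, [1.5, 0.5])

    def test_global_move_hand_arithmetic(self):
        bat = _bat(d=1, position_real=np.array([1.0]), frequency=2.0)
        cand = global_move(bat, best_position=np.array([0.0]))
        assert bat.velocity[0] == pytest.approx(2.0)
        assert cand[0] == pytest.approx(3.0)

    def test_zero_frequency_pure_inertia(self):
        bat = _bat(d=1, position_real=np.array([4.0]),
                   velocity=np.array([1.0]), frequency=0.0)
        assert global_move(bat, np.array([0.0]))[0] == pytest.approx(5.0)

    def test_quantum_collapse_at_u_one(self):
        cfg = SwarmConfig(theta=0.5)
        out = quantum_local_search(np.array([1.0]), np.array([0.5]), cfg, u=1.0)
        assert out[0] == pytest.approx(0.5)

    def test_quantum_hand_arithmetic(self):
        cfg = SwarmConfig(theta=0.5)
        out = quantum_local_search(np.array([1.0]), np.array([0.5]), cfg,
                                   u=math.exp(-1))
        assert out[0] == pytest.approx(0.75)

    def test_quantum_zero_difference(self):
        cfg = SwarmConfig(theta=0.75)
        x = np.array([0.3, 0.3])
        for u in (0.01, 0.5, 0.99):
            assert np.allclose(quantum_local_search(x, x, cfg, u), x)

    def test_random_walk(self):
        cfg = SwarmConfig(epsilon_walk=1.0)
        assert random_walk_local_search(np.array([1.0]), 0.0, cfg, eps=1.0)[0] == 1.0
        assert random_walk_local_search(np.array([1.0]), 0.5, cfg, eps=1.0)[0] == 1.5
        plus = random_walk_local_search(np.array([1.0]), 0.5, cfg, eps=1.0)
        minus = random_walk_local_search(np.array([1.0]), 0.5, cfg, eps=-1.0)
        assert plus[0] - 1.0 == pytest.approx(1.0 - minus[0])


class TestBinarize:
    def test_sigmoid_limits(self):
        rng = np.random.default_rng(0)
        assert binarize(np.full(50, 40.0), rng).all()
        assert not binarize(np.full(50, -40.0), rng).any()

    def test_zero_gives_half_probability(self):
        rng = np.random.default_rng(1)
        bits = np.concatenate([binarize(np.zeros(100), rng) for _ in range(50)])
        assert abs(bits.mean() - 0.5) < 0.05

    def test_encode_roundtrip(self):
        mask = np.array([1, 0, 1, 1, 0], np.int8)
        enc = _encode_mask(mask, 2.5)
        assert np.all(enc == np.where(mask == 1, 2.5, -2.5))


class TestAcceptCandidate:
    def test_rules(self):
        class R:
            def __init__(self, v):
                self.v = v

            def random(self):
                return self.v

        assert accept_candidate(0.1, 0.3, loudness=0.5, rng=R(0.2))
        assert not accept_candidate(0.1, 0.3, loudness=0.5, rng=R(0.9))
        assert not accept_candidate(0.3, 0.3, loudness=0.5, rng=R(0.0))  # strict


class TestRunEcqba:
    def test_finds_enumerated_optimum_small_d(self):
        """d=3: exhaustive table with a unique optimum; the swarm must find it."""
        target = np.array([1, 0, 1], np.int8)

        def fitness(mask):
            mask = np.asarray(mask)
            if not mask.any():
                return 0.99
            return 0.05 + 0.1 * np.sum(mask != target)

        res = run_ecqba(fitness, 3, SwarmConfig(n_bats=10, t_max=50, seed=0))
        assert np.array_equal(res.best_mask, target)
        assert res.best_fitness == pytest.approx(0.05)

    def test_single_bat_runs(self):
        res = run_ecqba(lambda m: 0.5, 3, SwarmConfig(n_bats=1, t_max=3, seed=0))
        assert res.best_fitness == 0.5

    def test_tmax_zero_returns_initial_best(self):
        res = run_ecqba(lambda m: float(np.sum(m)) / 4 if np.any(m) else 0.99,
                        4, SwarmConfig(n_bats=8, t_max=0, seed=3))
        assert len(res.history) == 1
        assert res.n_evaluations == 8

    def test_deterministic_under_seed(self, cached_fitness_table):
        table = cached_fitness_table
        fn = lambda m: table[bytes(np.asarray(m, np.int8))]
        d = 10
        a = run_ecqba(fn, d, SwarmConfig(seed=5))
        b = run_ecqba(fn, d, SwarmConfig(seed=5))
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.best_fitness == b.best_fitness
        assert a.history == b.history

    def test_elitism_and_trace_invariants(self, cached_fitness_table):
        table = cached_fitness_table
        fn = lambda m: table[bytes(np.asarray(m, np.int8))]
        res = run_ecqba(fn, 10, SwarmConfig(seed=2))
        best = [h["best_fitness"] for h in res.history]
        assert all(b <= a + 1e-15 for a, b in zip(best, best[1:]))
        assert all(0.0 <= h["H_norm"] <= 1.0 for h in res.history)
        loud = [h["mean_loudness"] for h in res.history]
        assert all(b <= a + 1e-12 for a, b in zip(loud, loud[1:]))

    def test_fitness_failure_names_bat(self):
        def broken(mask):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="bat 0"):
            run_ecqba(broken, 3, SwarmConfig(n_bats=2, t_max=1, seed=0))


def _reference_plain_bba(fitness_fn, d, cfg):
    """Independent plain binary BA sharing run_ecqba's RNG protocol."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_bats + 1)
    rngs = [np.random.default_rng(c) for c in children[: cfg.n_bats]]

    def binz(v, rng):
        s = 1 / (1 + np.exp(-np.clip(v, -60, 60)))
        return (rng.random(d) < s).astype(np.int8)

    pos, vel, masks, fits = [], [], [], []
    A = [cfg.loudness_init] * cfg.n_bats
    r = [cfg.pulse_rate_init] * cfg.n_bats
    for i in range(cfg.n_bats):
        lam = rngs[i].random(d)
        pos.append(cfg.b_min + lam * (cfg.b_max - cfg.b_min))
        vel.append(np.zeros(d))
        masks.append(binz(pos[i], rngs[i]))
    while not any(m.any() for m in masks):
        masks = [binz(pos[i], rngs[i]) for i in range(cfg.n_bats)]
    fits = [float(fitness_fn(m)) for m in masks]
    pos = [cfg.saturation * (2 * m.astype(float) - 1) for m in masks]
    ib = int(np.argmin(fits))
    bmask, bfit = masks[ib].copy(), fits[ib]
    bpos = cfg.saturation * (2 * bmask.astype(float) - 1)
    trace = [bfit]
    for t in range(1, cfg.t_max + 1):
        mean_A = float(np.mean(A))
        for i in range(cfg.n_bats):
            rng = rngs[i]
            f = cfg.f_min + (cfg.f_max - cfg.f_min) * rng.random()
            vel[i] = np.clip(vel[i] + (pos[i] - bpos) * f, -cfg.v_max, cfg.v_max)
            flown = pos[i] + vel[i]
            cand = flown
            if rng.random() > r[i]:
                cand = flown + cfg.epsilon_walk * rng.uniform(-1, 1) * mean_A
            cm = binz(cand, rng)
            cf = float(fitness_fn(cm))
            acc = rng.random() < A[i] and cf < bfit
            masks[i], fits[i] = cm, cf
            pos[i] = cfg.saturation * (2 * cm.astype(float) - 1)
            if acc:
                A[i] *= cfg.alpha
                r[i] = max(
                    cfg.pulse_rate_init * (1 - math.exp(-cfg.gamma * t)), cfg.r_min
                )
            if cf < bfit:
                bfit, bmask = cf, cm.copy()
                bpos = cfg.saturation * (2 * bmask.astype(float) - 1)
        trace.append(bfit)
    return bmask, bfit, trace


def test_plain_bba_flags_match_reference_step_for_step(cached_fitness_table):
    """With both flags off the trajectory equals an independent plain BBA."""
    table = cached_fitness_table
    fn = lambda m: table[bytes(np.asarray(m, np.int8))]
    cfg = SwarmConfig(entropy_control=False, quantum_update=False,
                      n_bats=12, t_max=25, seed=9)
    res = run_ecqba(fn, 10, cfg)
    ref_mask, ref_fit, ref_trace = _reference_plain_bba(fn, 10, cfg)
    assert np.array_equal(res.best_mask, ref_mask)
    assert res.best_fitness == ref_fit
    assert [h["best_fitness"] for h in res.history] == ref_trace
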