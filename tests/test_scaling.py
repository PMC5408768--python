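import numpy as np
import pytest

from porecall import (
    EventSequence,
    ModelSet,
    ScalingParams,
    SimConfig,
    TrainingConfig,
    em_round,
    mom_init,
    simulate_events,
    simulate_pore_model,
    simulate_sequence,
    train_read,
)
from porecall.scaling import training_chains
from porecall.transitions import TransitionModel


def model_mean_events(model, order=None):
    means = model.level_mean if order is None else model.level_mean[order]
    n = len(means)
    return EventSequence(np.arange(n) * 0.01, np.full(n, 0.01), means, np.full(n, 2.0))


def simulated_strand(seed, model, params, length=1500, p_skip=0.3, inflation=1.0):
    cfg = SimConfig(seed=seed, K=model.K, length=length, p_stay=0.1, p_skip=p_skip,
                    params=params, noise_inflation=inflation, homopolymer_len=0)
    rng = np.random.default_rng(seed)
    seq = simulate_sequence(rng, length, 0)
    ev, _, _ = simulate_events(seq, model, cfg, rng)
    return ev


class TestMomInit:
    def test_identity_on_model_means(self, k6_model):
        p = mom_init(model_mean_events(k6_model), k6_model)
        assert p.scale == pytest.approx(1.0, abs=1e-9)
        assert p.shift == pytest.approx(0.0, abs=1e-9)

    def test_recovers_affine_transform(self, k6_model):
        ev = model_mean_events(k6_model)
        ev = EventSequence(ev.start, ev.length, 1.2 * ev.mean + 10.0, ev.stdv)
        p = mom_init(ev, k6_model)
        assert p.scale == pytest.approx(1.2, abs=1e-6)
        assert p.shift == pytest.approx(10.0, abs=1e-6)

    def test_order_invariant(self, k6_model):
        order = np.random.default_rng(0).permutation(k6_model.n_states)
        a = mom_init(model_mean_events(k6_model), k6_model)
        b = mom_init(model_mean_events(k6_model, order), k6_model)
        assert (a.shift, a.scale) == (b.shift, b.scale)

    def test_zero_variance_fallback(self, k6_model):
        ev = EventSequence([0, 0.01], [0.01, 0.01], [75.0, 75.0], [2.0, 2.0])
        p = mom_init(ev, k6_model)
        assert p.scale == 1.0
        assert p.shift == pytest.approx(75.0 - k6_model.level_mean.mean())


class TestEmRound:
    def test_neutral_is_near_fixed_point(self, k6_model):
        ev = simulated_strand(5, k6_model, ScalingParams(), length=600)
        chains = training_chains(ev, 100)
        trans = TransitionModel(0.1, 0.3, 6)
        p, ll, masses = em_round(chains, k6_model, trans, ScalingParams())
        assert p.shift == pytest.approx(0.0, abs=1.0)
        assert p.scale == pytest.approx(1.0, abs=0.05)
        assert p.drift == pytest.approx(0.0, abs=0.02)
        assert p.var == pytest.approx(1.0, abs=0.3)
        assert p.scale_sd == pytest.approx(1.0, abs=0.1)
        assert np.isfinite(ll) and masses.sum() == pytest.approx(len(chains[0]) + len(chains[1]) - 2)

    def test_loglik_nondecreasing_over_rounds(self, k6_model):
        true = ScalingParams(shift=6.0, scale=1.08, var=1.2)
        ev = simulated_strand(6, k6_model, true, length=900)
        chains = training_chains(ev, 100)
        trans = TransitionModel(0.1, 0.3, 6)
        params = mom_init(ev, k6_model)
        lls = []
        for _ in range(6):
            params, ll, _ = em_round(chains, k6_model, trans, params)
            lls.append(ll)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_improves_on_mom_toward_truth(self, k6_model):
        true = ScalingParams(shift=8.0, scale=1.1, var=1.2)
        ev = simulated_strand(7, k6_model, true, length=1500)
        trans = TransitionModel(0.1, 0.3, 6)
        params = mom_init(ev, k6_model)
        chains = training_chains(ev, 100)
        for _ in range(5):
            params, _, _ = em_round(chains, k6_model, trans, params)
        assert params.scale == pytest.approx(1.1, rel=0.05)
        assert params.var == pytest.approx(1.2, rel=0.25)


class TestTrainingChains:
    def test_short_strand_is_one_chain(self, k6_model):
        ev = simulated_strand(1, k6_model, ScalingParams(), length=200)
        assert len(training_chains(ev, 100)) == 1

    def test_long_strand_gives_start_and_end(self, k6_model):
        ev = simulated_strand(1, k6_model, ScalingParams(), length=1500)
        chains = training_chains(ev, 100)
        assert [len(c) for c in chains] == [100, 100]
        assert chains[0].start[0] == ev.start[0]
        assert chains[1].start[-1] == ev.start[-1]


class TestTrainRead:
    def test_no_train_returns_mom_exactly(self, k6_model):
        ev = simulated_strand(2, k6_model, ScalingParams(shift=5), length=800)
        res = train_read({"template": ev}, ModelSet(template=k6_model),
                         TrainingConfig(no_train=True))
        assert res.rounds == 0
        assert res.fits["template"][0].params == mom_init(ev, k6_model)

    def test_double_strand_params_shared_bitwise(self, k6_model):
        comp = simulate_pore_model(12, 6, "complement_1")
        true = ScalingParams(shift=4.0, scale=1.05, var=1.2)
        tpl = simulated_strand(3, k6_model, true, length=900)
        cev = simulated_strand(4, comp, true, length=900)
        res = train_read({"template": tpl, "complement": cev},
                         ModelSet(template=k6_model, complements=[comp]),
                         TrainingConfig(mode="double_strand", train_transitions=False, max_rounds=3))
        p_t = res.fits["template"][0].params
        p_c = res.fits["complement"][0].params
        assert p_t == p_c  # one shared ScalingParams per read

    def test_single_strand_estimates_differ(self, k6_model):
        comp = simulate_pore_model(12, 6, "complement_1")
        true = ScalingParams(shift=4.0, scale=1.05, var=1.2)
        tpl = simulated_strand(3, k6_model, true, length=900)
        cev = simulated_strand(4, comp, true, length=900)
        res = train_read({"template": tpl, "complement": cev},
                         ModelSet(template=k6_model, complements=[comp]),
                         TrainingConfig(mode="single_strand", train_transitions=False, max_rounds=3))
        p_t = res.fits["template"][0].params
        p_c = res.fits["complement"][0].params
        assert p_t != p_c

    def test_complement_model_selected_by_margin(self, k6_model):
        # at low noise every event discriminates sharply between candidate
        # models, so the true complement model clears the 20-nat selection
        # margin during training and the decoy session is dropped
        comp_true = simulate_pore_model(12, 6, "complement_1")
        comp_decoy = simulate_pore_model(99, 6, "complement_2")
        true = ScalingParams(shift=2.0, scale=1.02)
        tpl = simulated_strand(3, k6_model, true, length=900, inflation=0.25)
        cev = simulated_strand(4, comp_true, true, length=900, inflation=0.25)
        res = train_read({"template": tpl, "complement": cev},
                         ModelSet(template=k6_model, complements=[comp_true, comp_decoy]),
                         TrainingConfig(mode="double_strand", train_transitions=False, max_rounds=3))
        assert res.selected_complement == 0
        assert len(res.fits["complement"]) == 1

    def test_empty_strand_warns_and_is_skipped(self, k6_model):
        tpl = simulated_strand(3, k6_model, ScalingParams(), length=600)
        empty = EventSequence([], [], [], [])
        with pytest.warns(UserWarning, match="empty"):
            res = train_read({"template": tpl, "complement": empty},
                             ModelSet(template=k6_model, complements=[k6_model]),
                             TrainingConfig(max_rounds=1, train_transitions=False))
        assert "complement" not in res.fits

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(num_events=0)
        with pytest.raises(ValueError):
            TrainingConfig(mode="triple")
        assert TrainingConfig(mode="single_strand").effective_max_rounds == 10
        assert TrainingConfig(mode="double_strand").effective_max_rounds == 20
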