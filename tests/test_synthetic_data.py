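"""Ground-truth structure and reproducibility of the synthetic generators."""

import numpy as np
import pytest

from neuroloop.realtime_decoding import train_pairwise_classifiers
from neuroloop.synthetic_data import (
    MORPH_STEPS,
    OBJECTS,
    TRAINED_PAIR,
    UNTRAINED_PAIR,
    ScheduleError,
    SyntheticConfig,
    AgentProfile,
    implant_integration,
    make_recognition_schedule,
    make_templates,
    simulate_agent_evidence,
    simulate_behaviour,
    simulate_recognition_session,
)


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestTemplates:
    def test_component_gram_matrix_is_identity(self, templates):
        g = templates.component_matrix() @ templates.component_matrix().T
        assert np.allclose(g, np.eye(6), atol=1e-8)

    def test_zero_unique_scale_makes_pair_templates_identical(self):
        cfg = SyntheticConfig(n_voxels=30, unique_scale=0.0, seed=1)
        tpl = make_templates(cfg)
        np.testing.assert_allclose(tpl.template("presented"), tpl.template("competitor"))

    def test_zero_shared_scale_makes_pair_templates_orthogonal(self):
        cfg = SyntheticConfig(n_voxels=30, shared_scale=0.0, seed=1)
        tpl = make_templates(cfg)
        assert abs(cosine(tpl.template("presented"), tpl.template("competitor"))) < 1e-8

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="n_voxels"):
            SyntheticConfig(n_voxels=5)

    def test_templates_reproducible_per_seed(self, small_config):
        a = make_templates(small_config).template("presented")
        b = make_templates(small_config).template("presented")
        np.testing.assert_array_equal(a, b)


class TestImplantIntegration:
    def test_identity_parameters_leave_templates_unchanged(self, templates):
        out = implant_integration(templates, unique_shrink=1.0, shared_gain=1.0)
        for obj in OBJECTS:
            np.testing.assert_allclose(out.template(obj), templates.template(obj))

    def test_full_shrink_makes_trained_pair_collinear(self, templates):
        out = implant_integration(templates, unique_shrink=0.0)
        c = cosine(out.template("presented"), out.template("competitor"))
        assert c == pytest.approx(1.0, abs=1e-8)

    def test_partial_shrink_increases_trained_cosine_only(self, templates):
        out = implant_integration(templates, unique_shrink=0.5)
        before = cosine(templates.template(TRAINED_PAIR[0]), templates.template(TRAINED_PAIR[1]))
        after = cosine(out.template(TRAINED_PAIR[0]), out.template(TRAINED_PAIR[1]))
        assert after > before
        for obj in UNTRAINED_PAIR:
            np.testing.assert_allclose(out.template(obj), templates.template(obj))

    def test_ground_truth_cosine_ordering(self, templates):
        """trained session5 > trained session1 == untrained (both sessions)."""
        s5 = implant_integration(templates, unique_shrink=0.6)
        tr1 = cosine(templates.template("presented"), templates.template("competitor"))
        tr5 = cosine(s5.template("presented"), s5.template("competitor"))
        un1 = cosine(templates.template("control1"), templates.template("control2"))
        un5 = cosine(s5.template("control1"), s5.template("control2"))
        assert tr5 > tr1
        assert tr1 == pytest.approx(un1, abs=1e-12)
        assert un1 == pytest.approx(un5, abs=1e-12)

    def test_invalid_shrink_rejected(self, templates):
        with pytest.raises(ValueError):
            implant_integration(templates, unique_shrink=1.5)


class TestSchedule:
    def test_default_design_repetition_counts(self):
        cfg = SyntheticConfig()
        sched = make_recognition_schedule(cfg, seed=0)
        objs = np.array(sched.objects)
        assert len(sched) == 48
        for obj in OBJECTS:
            assert int(np.sum(objs == obj)) == 12

    def test_each_quarter_balanced(self):
        cfg = SyntheticConfig()
        sched = make_recognition_schedule(cfg, seed=3)
        objs = np.array(sched.objects)
        quarters = np.array(sched.quarters)
        for q in range(4):
            for obj in OBJECTS:
                assert int(np.sum(objs[quarters == q] == obj)) == 3

    def test_invariants_hold_over_many_seeds(self):
        cfg = SyntheticConfig()
        for seed in range(1000):
            sched = make_recognition_schedule(cfg, seed=seed)
            objs = np.array(sched.objects)
            assert not np.any(objs[1:] == objs[:-1]), f"adjacent repeat at seed {seed}"
            counts = {obj: int(np.sum(objs == obj)) for obj in OBJECTS}
            assert set(counts.values()) == {12}

    def test_reproducible_per_seed(self):
        cfg = SyntheticConfig()
        assert make_recognition_schedule(cfg, seed=5) == make_recognition_schedule(cfg, seed=5)

    def test_unsatisfiable_design_rejected(self):
        cfg = SyntheticConfig(trials_per_run=24)  # not divisible by 4*4
        with pytest.raises(ScheduleError):
            make_recognition_schedule(cfg, seed=0)


class TestRecognitionPatterns:
    def test_zero_noise_reproduces_templates(self, noisefree_dataset, templates):
        for i in range(noisefree_dataset.n_trials):
            np.testing.assert_allclose(
                noisefree_dataset.data[i], templates.template(noisefree_dataset.labels[i])
            )

    def test_trial_count_conserved(self, small_dataset, small_config):
        assert small_dataset.n_trials == (
            small_config.n_runs_per_session * small_config.trials_per_run
        )

    def test_bit_reproducible(self, small_config, templates):
        sched = [make_recognition_schedule(small_config, seed=1)]
        a = simulate_recognition_session(templates, sched, 1.0, seed=9)
        b = simulate_recognition_session(templates, sched, 1.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_decoding_degrades_monotonically_with_noise(self):
        """Held-out pairwise accuracy falls as trial noise rises."""
        cfg = SyntheticConfig(n_voxels=30, n_runs_per_session=2, trials_per_run=16)
        mean_acc = {}
        for noise in (0.5, 2.0, 8.0):
            accs = []
            for seed in range(20):
                c = SyntheticConfig(
                    n_voxels=30, n_runs_per_session=2, trials_per_run=16, seed=seed
                )
                tpl = make_templates(c)
                scheds = [make_recognition_schedule(c, seed=seed * 10 + r) for r in range(2)]
                ds = simulate_recognition_session(tpl, scheds, noise, seed=seed)
                train = ds.runs == 0
                bank = train_pairwise_classifiers(ds.data[train], ds.labels[train])
                pair = ("presented", "control1")
                test = np.isin(ds.labels, pair) & ~train
                correct = [
                    bank.prob_of(ds.data[i], ds.labels[i], pair[0] if ds.labels[i] == pair[1] else pair[1]) > 0.5
                    for i in np.where(test)[0]
                ]
                accs.append(np.mean(correct))
            mean_acc[noise] = float(np.mean(accs))
        assert mean_acc[0.5] > mean_acc[2.0] > mean_acc[8.0]


class TestAgentEvidence:
    def test_values_clipped_to_unit_interval(self):
        ev = simulate_agent_evidence(AgentProfile(baseline=0.9, gain=0.3, noise_sd=0.5, seed=1))
        assert np.all(ev >= 0.0) and np.all(ev <= 1.0)

    def test_zero_gain_gives_flat_session_means(self):
        ev = simulate_agent_evidence(AgentProfile(gain=0.0, seed=2), n_sessions=3)
        comp = ev[..., 0].reshape(3, -1).mean(axis=1)
        assert np.ptp(comp) < 0.01

    def test_positive_gain_yields_positive_trend_almost_always(self):
        hits = 0
        for seed in range(100):
            ev = simulate_agent_evidence(AgentProfile(gain=0.1, seed=seed), n_sessions=3)
            comp = ev[..., 0].reshape(3, -1).mean(axis=1)
            slope = np.polyfit([1, 2, 3], comp, 1)[0]
            hits += slope > 0
        assert hits >= 95


class TestBehaviour:
    def test_trial_count_matches_design(self):
        ds = simulate_behaviour(50.0, 0.2, reps_per_step=12, seed=0)
        assert len(ds.frame) == 13 * 12 == 156
        assert sorted(ds.frame["morph"].unique()) == sorted(MORPH_STEPS)

    def test_steep_slope_limit_is_a_step_function(self):
        ds = simulate_behaviour(50.0, 1e6, reps_per_step=5, seed=0)
        f = ds.frame
        assert (f.loc[f.morph > 50, "response"] == 1).all()
        assert (f.loc[f.morph < 50, "response"] == 0).all()

    def test_response_rate_at_mu_is_near_half(self):
        rate = []
        for seed in range(30):
            ds = simulate_behaviour(50.0, 0.2, reps_per_step=12, seed=seed)
            f = ds.frame
            rate.append(f.loc[f.morph == 50, "response"].mean())
        # binomial CI around 0.5 at n = 30 * 12 draws
        assert abs(np.mean(rate) - 0.5) < 3 * np.sqrt(0.25 / (30 * 12))
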