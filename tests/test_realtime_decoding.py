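"""Causal normalization, pattern extraction, classifier bank and evidence."""

import numpy as np
import pytest

from neuroloop.realtime_decoding import (
    EvidenceScore,
    ExtractionError,
    TrainingError,
    coactivation_index,
    extract_trial_pattern,
    full_run_zscore,
    object_evidence,
    running_zscore,
    train_pairwise_classifiers,
)
from neuroloop.representational_change import roc_auc
from neuroloop.synthetic_data import (
    OBJECTS,
    SyntheticConfig,
    make_recognition_schedule,
    make_templates,
    simulate_recognition_session,
)


class TestRunningZscore:
    def test_constant_series_maps_to_zero(self):
        out = running_zscore(np.array([5.0, 5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(out, np.zeros((4, 1)))

    def test_third_tr_uses_prior_two_only(self):
        out = running_zscore(np.array([1.0, 2.0, 3.0]))
        expected = (3.0 - 1.5) / np.std([1.0, 2.0], ddof=1)
        assert out[2, 0] == pytest.approx(expected)

    def test_first_two_trs_emit_zero(self):
        out = running_zscore(np.array([3.0, 7.0, 1.0, 4.0]))
        assert out[0, 0] == 0.0 and out[1, 0] == 0.0

    def test_causality_under_future_edits(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=(30, 5))
        base = running_zscore(series)
        for t in (5, 12, 25):
            edited = series.copy()
            edited[t:] = rng.normal(size=edited[t:].shape) * 100
            np.testing.assert_array_equal(running_zscore(edited)[:t], base[:t])

    def test_full_run_zscore_standardizes_columns(self):
        rng = np.random.default_rng(1)
        z = full_run_zscore(rng.normal(3.0, 2.0, size=(50, 4)))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestExtractTrialPattern:
    def test_lagged_index_arithmetic(self):
        series = np.arange(60).reshape(20, 3)
        np.testing.assert_array_equal(extract_trial_pattern(series, 10, 2), series[12])
        np.testing.assert_array_equal(extract_trial_pattern(series, 10, 0), series[10])

    def test_onset_at_run_end_raises(self):
        series = np.zeros((20, 3))
        with pytest.raises(ExtractionError):
            extract_trial_pattern(series, 19, 2)


class TestTimeseriesPath:
    def test_lagged_extraction_recovers_templates_from_run_timeseries(self, small_config, templates):
        from neuroloop.synthetic_data import make_recognition_schedule, simulate_run_timeseries

        sched = make_recognition_schedule(small_config, seed=4)
        series = simulate_run_timeseries(templates, sched, noise_sd=0.0, seed=0, n_trs=60)
        for obj, onset in zip(sched.objects, sched.onsets):
            np.testing.assert_allclose(
                extract_trial_pattern(series, onset, lag_trs=2), templates.template(obj)
            )

    def test_causal_normalization_of_run_timeseries(self, small_config, templates):
        from neuroloop.synthetic_data import make_recognition_schedule, simulate_run_timeseries

        sched = make_recognition_schedule(small_config, seed=4)
        series = simulate_run_timeseries(templates, sched, noise_sd=1.0, seed=1, n_trs=60)
        z = running_zscore(series)
        assert np.all(np.isfinite(z))
        # normalization at TR t is unchanged by editing later trials
        edited = series.copy()
        edited[30:] *= 10
        np.testing.assert_array_equal(running_zscore(edited)[:30], z[:30])


class TestPairwiseBank:
    def test_bank_contains_six_models(self, small_dataset):
        bank = train_pairwise_classifiers(small_dataset.data, small_dataset.labels)
        assert len(bank.models) == 6

    def test_missing_object_rejected(self, small_dataset):
        mask = small_dataset.labels != "competitor"
        with pytest.raises(TrainingError, match="competitor"):
            train_pairwise_classifiers(small_dataset.data[mask], small_dataset.labels[mask])

    def test_noisefree_patterns_classified_perfectly(self, noisefree_dataset):
        train = noisefree_dataset.runs < 2
        bank = train_pairwise_classifiers(
            noisefree_dataset.data[train], noisefree_dataset.labels[train]
        )
        test_idx = np.where(~train)[0]
        for a in OBJECTS:
            for b in OBJECTS:
                if a >= b:
                    continue
                for i in test_idx:
                    if noisefree_dataset.labels[i] not in (a, b):
                        continue
                    p = bank.prob_of(noisefree_dataset.data[i], noisefree_dataset.labels[i],
                                     a if noisefree_dataset.labels[i] == b else b)
                    assert p > 0.5

    def test_permuted_labels_give_chance_auc(self):
        """Shuffling labels destroys decodability: mean held-out AUC ~ 0.5."""
        aucs = []
        for seed in range(50):
            cfg = SyntheticConfig(n_voxels=30, n_runs_per_session=2, trials_per_run=16, seed=seed)
            tpl = make_templates(cfg)
            scheds = [make_recognition_schedule(cfg, seed=seed * 7 + r) for r in range(2)]
            ds = simulate_recognition_session(tpl, scheds, noise_sd=1.0, seed=seed)
            rng = np.random.default_rng(seed)
            # shuffle labels within each run: balance kept, mapping destroyed
            labels = ds.labels.copy()
            for run in ds.run_ids:
                m = ds.runs == run
                labels[m] = rng.permutation(labels[m])
            train = ds.runs == 0
            bank = train_pairwise_classifiers(ds.data[train], labels[train])
            pair = ("presented", "competitor")
            mask = ~train & np.isin(labels, pair)
            scores = [bank.prob_of(ds.data[i], pair[0], pair[1]) for i in np.where(mask)[0]]
            aucs.append(roc_auc(scores, (labels[mask] == pair[0]).astype(int)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestEvidence:
    def test_evidence_is_mean_of_constituents(self, small_dataset):
        bank = train_pairwise_classifiers(small_dataset.data, small_dataset.labels)
        score = object_evidence(
            small_dataset.data[0], bank, "competitor", ("control1", "control2")
        )
        assert isinstance(score, EvidenceScore)
        assert score.value == pytest.approx(np.mean(score.constituents))
        assert 0.0 <= score.value <= 1.0

    def test_target_in_controls_rejected(self, small_dataset):
        bank = train_pairwise_classifiers(small_dataset.data, small_dataset.labels)
        with pytest.raises(ValueError):
            object_evidence(small_dataset.data[0], bank, "control1", ("control1", "control2"))

    def test_noisefree_target_pattern_scores_above_half(self, noisefree_dataset, templates):
        bank = train_pairwise_classifiers(noisefree_dataset.data, noisefree_dataset.labels)
        score = object_evidence(
            templates.template("competitor"), bank, "competitor", ("control1", "control2")
        )
        assert score.value > 0.5

    def test_presented_and_competitor_evidence_exchangeable_without_integration(self):
        """With symmetric ground truth, relabelling objects must not favour
        the presented over the competitor evidence."""
        diffs = []
        for seed in range(15):
            cfg = SyntheticConfig(
                n_voxels=30, n_runs_per_session=2, trials_per_run=16, seed=seed, unique_shrink=1.0
            )
            tpl = make_templates(cfg)
            scheds = [make_recognition_schedule(cfg, seed=seed * 3 + r) for r in range(2)]
            ds = simulate_recognition_session(tpl, scheds, noise_sd=1.0, seed=seed)
            bank = train_pairwise_classifiers(ds.data, ds.labels)
            probe = np.zeros(cfg.n_voxels)
            e_pres = object_evidence(probe, bank, "presented", ("control1", "control2")).value
            e_comp = object_evidence(probe, bank, "competitor", ("control1", "control2")).value
            diffs.append(e_pres - e_comp)
        assert abs(np.mean(diffs)) < 0.1


class TestCoactivation:
    @pytest.mark.parametrize(
        "pres, comp, expected", [(1.0, 1.0, 1.0), (0.5, 0.0, 0.0), (0.6, 0.5, 0.3)]
    )
    def test_product_values(self, pres, comp, expected):
        assert coactivation_index(pres, comp) == pytest.approx(expected)

    def test_monotone_in_competitor_evidence(self):
        values = [coactivation_index(0.7, c) for c in np.linspace(0.1, 0.9, 9)]
        assert np.all(np.diff(values) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            coactivation_index(1.2, 0.5)
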