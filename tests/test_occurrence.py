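import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import cohen_kappa_score

from streamcom import occurrence
from streamcom.occurrence import (
    ThresholdStats,
    build_training_sets,
    decision_threshold,
    filter_assemblage,
    threshold_mean,
    threshold_robust,
    train_occurrence_model,
    validation_metrics,
)
from streamcom.species import (
    DistributionTable,
    StreamCovariates,
    SurveyRecord,
)


def make_survey(site, huc, caught, seed=0):
    rng = np.random.default_rng(seed + hash(site) % 1000)
    return SurveyRecord(
        site_id=site,
        huc8_id=huc,
        covariates=StreamCovariates(
            float(rng.uniform(1, 1000)), float(rng.uniform(0, 800)),
            float(rng.uniform(0, 5)), float(rng.uniform(0, 1)),
            float(rng.uniform(0, 1)),
        ),
        caught=frozenset(caught),
    )


class TestBuildTrainingSets:
    def test_minimum_capture_rule(self):
        db = DistributionTable([("a", "h1"), ("b", "h1")])
        surveys = [
            make_survey(f"s{i}", "h1", {"a"} if i < 24 else {"a", "b"})
            for i in range(30)
        ]
        # a caught 30 times, b only 6
        sets = build_training_sets(surveys, db, min_captures=25)
        assert "a" in sets.tables
        assert sets.excluded == {"b": 6}

    def test_boundary_of_capture_rule(self):
        db = DistributionTable([("a", "h1")])
        surveys = [
            make_survey(f"s{i}", "h1", {"a"} if i < 25 else set())
            for i in range(50)
        ]
        sets = build_training_sets(surveys, db, min_captures=25)
        assert sets.tables["a"].n_present == 25

    def test_caught_everywhere_is_degenerate(self):
        db = DistributionTable([("a", "h1")])
        surveys = [make_survey(f"s{i}", "h1", {"a"}) for i in range(30)]
        sets = build_training_sets(surveys, db)
        assert sets.tables["a"].degenerate

    def test_negatives_only_from_in_range_hucs(self):
        """Sites outside a species' recorded range contribute no
        absences; sites inside it do."""
        db = DistributionTable([("a", "h1")])
        surveys = [
            make_survey(f"in{i}", "h1", {"a"} if i % 2 else set())
            for i in range(60)
        ] + [make_survey(f"out{i}", "h2", set()) for i in range(40)]
        sets = build_training_sets(surveys, db)
        table = sets.tables["a"]
        assert table.n_present == 30
        assert table.n_absent == 30  # the 40 out-of-range sites are ignored

    def test_label_counts_match_generator(self, recovery):
        fx = recovery["fixture"]
        sets = build_training_sets(fx.surveys, fx.distribution)
        for sid, table in sets.tables.items():
            n_caught = sum(sid in s.caught for s in fx.surveys)
            in_range = fx.grid_truth.ranges[sid]
            n_range_sites = sum(s.huc8_id in in_range for s in fx.surveys)
            assert table.n_present == n_caught
            assert table.n_present + table.n_absent == n_range_sites


class TestTraining:
    def test_single_class_rejected(self):
        db = DistributionTable([("a", "h1")])
        surveys = [make_survey(f"s{i}", "h1", {"a"}) for i in range(30)]
        table = build_training_sets(surveys, db).tables["a"]
        with pytest.raises(ValueError, match="degenerate"):
            train_occurrence_model(table)

    def test_same_seed_reproduces_predictions(self, recovery):
        sid, table = next(iter(recovery["training_sets"].tables.items()))
        m1 = train_occurrence_model(table, seed=7)
        m2 = train_occurrence_model(table, seed=7)
        p1 = m1.predict_probability(table.X)
        p2 = m2.predict_probability(table.X)
        assert np.array_equal(p1, p2)
        assert m1.threshold_stats == m2.threshold_stats

    def test_predictions_are_probabilities(self, recovery):
        for model in recovery["models"].values():
            prob = model.predict_probability(
                recovery["training_sets"].tables[model.species_id].X
            )
            assert ((prob >= 0) & (prob <= 1)).all()

    def test_permuted_labels_yield_chance_kappa(self, recovery):
        """With labels shuffled the model has nothing to learn:
        holdout agreement collapses to chance."""
        table = max(
            recovery["training_sets"].tables.values(),
            key=lambda t: min(t.n_present, t.n_absent),
        )
        rng = np.random.default_rng(3)
        y = rng.permutation(table.y)
        n = len(y)
        split = int(0.75 * n)
        idx = rng.permutation(n)
        fit_idx, hold_idx = idx[:split], idx[split:]
        shuffled = occurrence.TrainingTable(
            species_id="perm",
            X=table.X.iloc[fit_idx].reset_index(drop=True),
            y=y[fit_idx],
            n_present=int(y[fit_idx].sum()),
            n_absent=int((1 - y[fit_idx]).sum()),
        )
        model = train_occurrence_model(shuffled, seed=3)
        pred = model.predict_probability(table.X.iloc[hold_idx]) >= 0.5
        kappa = cohen_kappa_score(y[hold_idx], pred)
        assert abs(kappa) < 0.15

    def test_recovers_logistic_structure(self, recovery):
        """Pooled holdout kappa beats 0.5 on surveys generated from a
        strong logistic occurrence function, and the predicted
        probabilities rank-correlate with the generator's truth."""
        fx, models = recovery["fixture"], recovery["models"]
        tp, fp, fn, tn = occurrence.pooled_confusion(
            models, recovery["test"], fx.distribution, "mean"
        )
        summary = validation_metrics(tp, fp, fn, tn)
        assert summary.kappa > 0.5

        # rank correlation against the true probabilities, pooled over
        # all modelled species at every survey site
        import pandas as pd

        cov = pd.DataFrame(
            [s.covariates.as_tuple() for s in fx.surveys],
            columns=occurrence.COVARIATE_COLUMNS,
        )
        sid_index = {s: j for j, s in enumerate(fx.survey_truth.species_ids)}
        predicted, truth = [], []
        for sid, model in models.items():
            predicted.append(model.predict_probability(cov))
            truth.append(fx.survey_truth.probabilities[:, sid_index[sid]])
        rho = spearmanr(np.concatenate(predicted), np.concatenate(truth)).statistic
        assert rho > 0.5


class TestThresholds:
    def test_mean_rule_worked_example(self):
        stats = ThresholdStats(p1_mean=0.55, p0_mean=0.23, p1_sd=0.1)
        assert threshold_mean(stats) == pytest.approx(0.39, abs=1e-12)

    def test_mean_rule_degenerate_cases(self):
        assert threshold_mean(ThresholdStats(0.4, 0.4, 0.0)) == 0.4
        assert threshold_mean(ThresholdStats(1.0, 0.0, 0.0)) == 0.5

    @pytest.mark.parametrize(
        "p1, sd, p0, expected",
        [
            (0.55, 0.40, 0.23, 0.23),  # max(0.23, 0.15)
            (0.55, 0.0, 0.23, 0.55),   # zero spread falls back to P1
        ],
    )
    def test_robust_rule(self, p1, sd, p0, expected):
        stats = ThresholdStats(p1_mean=p1, p0_mean=p0, p1_sd=sd)
        assert threshold_robust(stats) == pytest.approx(expected)

    def test_robust_below_mean_when_spread_large(self):
        stats = ThresholdStats(p1_mean=0.6, p0_mean=0.2, p1_sd=0.3)
        # SD(P1) > (P1-P0)/2 so the robust cutoff is the lower one
        assert threshold_robust(stats) < threshold_mean(stats)

    def test_robust_never_exceeds_max_of_means(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p1, p0, sd = rng.uniform(0, 1, 3)
            stats = ThresholdStats(p1_mean=p1, p0_mean=p0, p1_sd=sd)
            assert threshold_robust(stats) <= max(p0, p1) + 1e-12

    def test_fixed_and_unknown_rules(self):
        stats = ThresholdStats(0.5, 0.2, 0.1)
        assert decision_threshold(stats, 0.42) == 0.42
        with pytest.raises(ValueError):
            decision_threshold(stats, "median")
        with pytest.raises(ValueError):
            decision_threshold(stats, 1.5)

    def test_lowering_threshold_trades_specificity_for_sensitivity(self, recovery):
        """Sweeping the cutoff downward never decreases sensitivity
        and never increases specificity."""
        fx = recovery["fixture"]
        sid, model = next(iter(recovery["models"].items()))
        tables = occurrence.build_training_sets(
            recovery["test"], fx.distribution
        ).tables
        if sid not in tables:
            pytest.skip("species not represented in holdout")
        table = tables[sid]
        prob = model.predict_probability(table.X)
        sens, spec = [], []
        for cutoff in np.linspace(0.9, 0.1, 17):
            pred = prob >= cutoff
            actual = table.y == 1
            tp = int((pred & actual).sum()); fn = int((~pred & actual).sum())
            tn = int((~pred & ~actual).sum()); fp = int((pred & ~actual).sum())
            sens.append(tp / (tp + fn))
            spec.append(tn / (tn + fp))
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(spec, spec[1:]))


class _StubModel:
    """Duck-typed stand-in returning a fixed probability."""

    def __init__(self, prob, stats=ThresholdStats(0.6, 0.2, 0.1)):
        self._prob = prob
        self.threshold_stats = stats

    def predict_probability(self, covariates):
        return np.array([self._prob])


COV = StreamCovariates(100.0, 300.0, 1.0, 0.6, 0.5)


class TestFilterAssemblage:
    def test_probability_at_threshold_is_retained(self):
        stats = ThresholdStats(p1_mean=0.6, p0_mean=0.2, p1_sd=0.1)
        models = {"a": _StubModel(threshold_mean(stats), stats)}
        assert filter_assemblage(["a"], COV, models, "mean") == [
            ("a", threshold_mean(stats))
        ]

    def test_below_threshold_dropped(self):
        models = {"a": _StubModel(0.1)}
        assert filter_assemblage(["a"], COV, models, "mean") == []

    def test_manual_overrides_win(self):
        models = {"a": _StubModel(0.1), "b": _StubModel(0.9)}
        kept = filter_assemblage(
            ["a", "b"], COV, models, "mean", include=["a"], exclude=["b"]
        )
        assert [sid for sid, _ in kept] == ["a"]

    def test_unmodelled_species_pass_through(self):
        assert filter_assemblage(["rare"], COV, {}, "mean") == [("rare", None)]

    def test_empty_assemblage(self):
        assert filter_assemblage([], COV, {}, "mean") == []


class TestValidationMetrics:
    def test_published_confusion_matrices(self):
        left = validation_metrics(27333, 40778, 15985, 235264)
        assert round(left.kappa, 2) == 0.39
        assert round(left.accuracy * 100) == 82
        assert round(left.sensitivity * 100) == 63
        assert round(left.specificity * 100) == 85
        right = validation_metrics(32244, 67394, 11074, 208648)
        assert round(right.kappa, 2) == 0.32
        assert round(right.accuracy * 100) == 75

    def test_perfect_and_chance_agreement(self):
        assert validation_metrics(50, 0, 0, 50).kappa == 1.0
        assert validation_metrics(25, 25, 25, 25).kappa == 0.0

    def test_agrees_with_per_record_tally(self, rng):
        actual = rng.integers(0, 2, 500)
        predicted = rng.integers(0, 2, 500)
        tp = int(((predicted == 1) & (actual == 1)).sum())
        fp = int(((predicted == 1) & (actual == 0)).sum())
        fn = int(((predicted == 0) & (actual == 1)).sum())
        tn = int(((predicted == 0) & (actual == 0)).sum())
        summary = validation_metrics(tp, fp, fn, tn)
        assert summary.kappa == pytest.approx(
            cohen_kappa_score(actual, predicted)
        )
        assert summary.accuracy == pytest.approx((actual == predicted).mean())

    def test_undefined_rates_reported_as_none(self):
        summary = validation_metrics(0, 5, 0, 95)  # no actual positives
        assert summary.sensitivity is None
        assert summary.specificity is not None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            validation_metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            validation_metrics(-1, 0, 0, 10)
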