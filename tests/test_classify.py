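import itertools
import math

import numpy as np
import pytest

from connspeech.classify import (CONTROL, PD, GaussianPatternClassifier,
                                 SubjectRecord, classify_subject, fit_qda,
                                 index_test, loso_accuracy,
                                 search_best_subset)
from connspeech.stats import binomial_above_chance_p, bonferroni_threshold

from conftest import cohort_records


def recs_1d(mu0, mu1, n, sigma0=1.0, sigma1=1.0, seed=0, key="f"):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(SubjectRecord(f"c{i}", CONTROL,
                                 {key: mu0 + sigma0 * rng.standard_normal()}))
        out.append(SubjectRecord(f"p{i}", PD,
                                 {key: mu1 + sigma1 * rng.standard_normal()}))
    return out


class TestQdaModel:
    def test_decision_boundary_between_separated_classes(self):
        records = recs_1d(0.0, 10.0, 200)
        model = fit_qda(records, ["f"])
        # equal variances and priors: Bayes boundary at the midpoint
        xs = np.linspace(0, 10, 2001).reshape(-1, 1)
        pred = model.predict(xs)
        boundary = xs[np.argmax(pred == PD)][0]
        assert boundary == pytest.approx(5.0, abs=0.5)

    def test_unequal_variance_quadratic_boundary(self):
        # N(0,1) vs N(0,9): QDA accepts the wide class outside +-x*,
        # where x* solves the closed-form density equality
        records = recs_1d(0.0, 0.0, 500, sigma0=1.0, sigma1=3.0, seed=1)
        model = fit_qda(records, ["f"])
        i0 = list(model.classes_).index(CONTROL)
        i1 = list(model.classes_).index(PD)
        m0, m1 = model.means_[i0][0], model.means_[i1][0]
        s0 = float(model.covariances_[i0][0, 0])
        s1 = float(model.covariances_[i1][0, 0])
        p0, p1 = model.priors_[i0], model.priors_[i1]
        # analytic QDA boundary: solve the log-density-difference quadratic
        a = 0.5 * (1 / s0 - 1 / s1)
        b = m1 / s1 - m0 / s0
        c = (0.5 * (m0 ** 2 / s0 - m1 ** 2 / s1)
             - 0.5 * math.log(s1 / s0) - math.log(p0 / p1))
        roots = np.roots([a, b, c])
        x_star = max(r.real for r in roots if abs(r.imag) < 1e-12)
        assert x_star == pytest.approx(math.sqrt(
            2 * math.log(math.sqrt(s1 / s0)) / (1 / s0 - 1 / s1)), rel=0.15)
        xs = np.linspace(0, 8, 8001).reshape(-1, 1)
        pred = model.predict(xs)
        flip = xs[np.argmax(pred == PD)][0]
        assert flip == pytest.approx(x_star, abs=0.05)

    def test_chance_level_for_identical_classes(self):
        records = recs_1d(0.0, 0.0, 30, seed=2)
        acc, _, _ = loso_accuracy(records, ["f"])
        assert 0.2 <= acc <= 0.8

    def test_posterior_matches_log_density_oracle(self):
        records = recs_1d(0.0, 3.0, 100, seed=3)
        model = fit_qda(records, ["f"])
        x = np.array([[1.234]])
        post = model.predict_proba(x)[0]
        dens = []
        for k, c in enumerate(model.classes_):
            mu = model.means_[k][0]
            s2 = model.covariances_[k][0, 0]
            dens.append(model.priors_[k] *
                        math.exp(-0.5 * (x[0, 0] - mu) ** 2 / s2)
                        / math.sqrt(2 * math.pi * s2))
        dens = np.array(dens) / sum(dens)
        assert np.allclose(post, dens, atol=1e-9)

    def test_tie_broken_toward_control(self):
        # perfectly symmetric classes: a record at the midpoint ties
        records = []
        for i, v in enumerate([-2.0, -1.0, 1.0, 2.0]):
            records.append(SubjectRecord(f"c{i}", CONTROL, {"f": v}))
            records.append(SubjectRecord(f"p{i}", PD, {"f": -v}))
        model = fit_qda(records, ["f"])
        assert model.predict(np.array([[0.0]]))[0] == CONTROL

    def test_record_at_class_mean_assigned_there(self):
        records = recs_1d(0.0, 10.0, 50, seed=4)
        model = fit_qda(records, ["f"])
        label, post = classify_subject(
            model, SubjectRecord("x", "heldout", {"f": 10.0}), ["f"])
        assert label == PD
        assert post[PD] > 0.5

    def test_missing_feature_imputed_not_crashing(self):
        records = recs_1d(0.0, 5.0, 30, seed=5)
        records[0].features["f"] = math.nan
        model = fit_qda(records, ["f"])
        label, _ = classify_subject(
            model, SubjectRecord("x", "heldout", {"f": math.nan}), ["f"])
        assert label in (PD, CONTROL)


class TestLoso:
    def test_perfect_separation_gives_unit_accuracy(self):
        records = recs_1d(0.0, 50.0, 20, seed=6)
        acc, sens, spec = loso_accuracy(records, ["f"])
        assert acc == 1.0 and sens == 1.0 and spec == 1.0

    def test_no_leakage_from_heldout_subject(self):
        records = recs_1d(0.0, 3.0, 15, seed=7)
        fold_train = records[1:]
        m1 = fit_qda(fold_train, ["f"])
        records[0].features["f"] = 999.0  # perturb the held-out subject
        m2 = fit_qda(records[1:], ["f"])
        assert np.array_equal(m1.means_, m2.means_)
        assert np.array_equal(m1.covariances_, m2.covariances_)

    def test_permutation_null_is_chance(self):
        rng_master = np.random.default_rng(8)
        accs = []
        for _ in range(10):
            records = recs_1d(0.0, 4.0, 30, seed=int(rng_master.integers(1e6)))
            labels = [r.group for r in records]
            rng_master.shuffle(labels)
            permuted = [SubjectRecord(r.subject_id, g, r.features)
                        for r, g in zip(records, labels)]
            acc, _, _ = loso_accuracy(permuted, ["f"])
            accs.append(acc)
        assert 0.35 <= np.mean(accs) <= 0.65


class TestSubsetSearch:
    def test_exhaustive_equals_brute_force(self):
        rng = np.random.default_rng(9)
        records = []
        for i in range(20):
            records.append(SubjectRecord(f"c{i}", CONTROL,
                                         {"a": rng.normal(),
                                          "b": rng.normal(),
                                          "c": rng.normal(0, 1)}))
            records.append(SubjectRecord(f"p{i}", PD,
                                         {"a": rng.normal(2.5),
                                          "b": rng.normal(),
                                          "c": rng.normal(1.0)}))
        subset, acc, _, _ = search_best_subset(records, ["a", "b", "c"],
                                               strategy="exhaustive")
        best = max(
            ((loso_accuracy(records, list(s))[0], s)
             for r in range(1, 4)
             for s in itertools.combinations(["a", "b", "c"], r)),
            key=lambda t: (t[0], -len(t[1])))
        assert acc == pytest.approx(best[0])

    def test_identical_copies_collapse_to_single_feature(self):
        rng = np.random.default_rng(10)
        records = []
        for i in range(20):
            v0, v1 = rng.normal(), rng.normal(3.0)
            records.append(SubjectRecord(f"c{i}", CONTROL,
                                         {"a": v0, "b": v0, "c": v0}))
            records.append(SubjectRecord(f"p{i}", PD,
                                         {"a": v1, "b": v1, "c": v1}))
        subset, _, _, _ = search_best_subset(records, ["a", "b", "c"],
                                             strategy="exhaustive")
        assert subset == ["a"]

    def test_forward_search_finds_planted_signal(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            records = []
            for i in range(25):
                fc = {"signal": rng.normal(0.0)}
                fp = {"signal": rng.normal(3.0)}
                for j in range(9):
                    fc[f"noise{j}"] = rng.normal()
                    fp[f"noise{j}"] = rng.normal()
                records.append(SubjectRecord(f"c{i}", CONTROL, fc))
                records.append(SubjectRecord(f"p{i}", PD, fp))
            subset, _, _, _ = search_best_subset(
                records, sorted(records[0].features), strategy="forward")
            if "signal" in subset and len(subset) <= 3:
                hits += 1
        assert hits >= 8


class TestIndexTest:
    def test_updrs_cutoff_boundary(self):
        train = recs_1d(0.0, 20.0, 10, seed=11)
        held = [SubjectRecord("h0", "heldout", {"f": 0.0}, updrs3_star=3),
                SubjectRecord("h1", "heldout", {"f": 20.0}, updrs3_star=4)]
        res = index_test(train, held, subset=["f"])
        calls = dict((sid, (motor, speech)) for sid, motor, speech in res.calls)
        assert calls["h0"][0] == CONTROL  # UPDRS III* = 3 is motor negative
        assert calls["h1"][0] == PD
        assert res.accuracy == 1.0

    def test_empty_heldout_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            index_test(recs_1d(0, 1, 5), [], subset=["f"])

    def test_missing_updrs_listed(self):
        train = recs_1d(0.0, 5.0, 5, seed=12)
        held = [SubjectRecord("mystery", "heldout", {"f": 1.0})]
        with pytest.raises(ValueError, match="mystery"):
            index_test(train, held, subset=["f"])

    def test_transfer_on_synthetic_cohort_above_chance(self):
        train = cohort_records(seed=21, n_per_group=15)
        held = cohort_records(seed=21, n_per_group=10, heldout=True)
        keys = sorted(train[0].features)
        res = index_test(train, held, candidate_keys=keys, strategy="forward")
        n_correct = round(res.accuracy * len(held))
        assert binomial_above_chance_p(n_correct, len(held)) < 0.01


class TestStatsHelpers:
    def test_bonferroni_for_twelve_tests(self):
        assert bonferroni_threshold(0.05, 12) == 0.0042

    def test_bonferroni_unrounded(self):
        assert bonferroni_threshold(0.05, 12, digits=None) == \
            pytest.approx(0.05 / 12)
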