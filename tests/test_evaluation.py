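"""Bayes oracle and evaluation arithmetic: closed-form posterior against
independent density oracles, confusion matrices, clinical concordance."""

import numpy as np
import pytest
from scipy import stats

from rccnet import (
    BayesClassifier,
    CohortCounts,
    GenerativeParams,
    bayes_labels,
    bayes_posterior,
    cohort_metrics,
    confusion_matrix,
    default_params,
    expected_confusion,
    sample_cohort,
)
from rccnet.clinical import CLINICAL_COUNTS


# -- Bayes posterior ------------------------------------------------------

def test_class_mean_is_classified_as_its_class(params):
    """Shared spherical SD + equal priors: the rule is nearest-mean, so
    each class mean maps to its own label."""
    for s in range(4):
        bp = bayes_posterior(params.mean[s], params)
        assert int(bp.label) == s
        assert bp.posterior.argmax() == s
        assert bp.posterior.sum() == pytest.approx(1.0, abs=1e-12)


def test_identical_classes_give_uniform_posterior(params):
    p = GenerativeParams(
        mean=np.tile(params.mean[0], (4, 1)), sd=np.tile(params.sd[0], (4, 1))
    )
    bp = bayes_posterior(np.array([40.0, 80.0, 90.0, 60.0]), p)
    assert np.allclose(bp.posterior, 0.25, atol=1e-12)
    assert bp.label == 0  # tie broken toward PPC


def test_posterior_matches_direct_density_ratio(rng, params):
    """Two-class reduction: posterior must equal the direct normalized
    product of scipy normal densities to 1e-12."""
    p = GenerativeParams(
        mean=params.mean,
        sd=params.sd,
        priors=np.array([0.3, 0.7, 0.0, 0.0]),
    )
    for _ in range(20):
        x = rng.normal(60, 50, size=4)
        dens = np.array(
            [
                prior * np.prod(stats.norm.pdf(x, loc=p.mean[s], scale=p.sd[s]))
                for s, prior in enumerate(p.priors)
            ]
        )
        expected = dens / dens.sum()
        assert np.allclose(bayes_posterior(x, p).posterior, expected, atol=1e-12)


def test_posterior_matches_gaussian_naive_bayes(rng, params):
    """Independent route: sklearn GaussianNB with the exact generative
    moments must reproduce the oracle's posterior and labels."""
    from sklearn.naive_bayes import GaussianNB

    gnb = GaussianNB()
    gnb.classes_ = np.arange(4)
    gnb.theta_ = params.mean.copy()
    gnb.var_ = params.sd.copy() ** 2
    gnb.class_prior_ = params.priors.copy()

    X = rng.normal(60, 50, size=(200, 4))
    ours = np.array([bayes_posterior(x, params).posterior for x in X])
    assert np.allclose(ours, gnb.predict_proba(X), atol=1e-9)
    assert np.array_equal(bayes_labels(X, params), gnb.predict(X))


def test_degenerate_class_point_mass(params):
    sd = params.sd.copy()
    sd[2] = 0.0  # OCC becomes a point mass at its mean
    p = GenerativeParams(mean=params.mean, sd=sd)
    on = bayes_posterior(params.mean[2], p)
    off = bayes_posterior(params.mean[2] + np.array([0.1, 0, 0, 0]), p)
    assert on.label == 2 and on.posterior[2] == pytest.approx(1.0)
    assert off.posterior[2] == 0.0


# -- confusion matrices ---------------------------------------------------

def test_perfect_predictions_are_diagonal():
    y = np.repeat(np.arange(4), 6)
    cm = confusion_matrix(y, y)
    assert np.array_equal(np.diag(cm.percent), [100.0] * 4)
    assert cm.counts.sum() == 24 and np.trace(cm.counts) == 24


def test_hand_computed_single_error_row():
    """Four records per class, one PPC record predicted CPC: the PPC row
    becomes (75, 25, 0, 0)."""
    actual = np.repeat(np.arange(4), 4)
    predicted = actual.copy()
    predicted[0] = 1
    cm = confusion_matrix(predicted, actual)
    assert cm.percent[0].tolist() == [75.0, 25.0, 0.0, 0.0]
    assert np.array_equal(cm.counts[0], [3, 1, 0, 0])
    rounded = np.round(cm.percent, 1)
    assert np.all(np.abs(rounded.sum(axis=1) - 100.0) <= 0.3)


def test_row_percentages_sum_to_100_after_rounding(rng):
    for _ in range(10):
        n = int(rng.integers(8, 400))
        cm = confusion_matrix(rng.integers(0, 4, n), rng.integers(0, 4, n))
        rows = cm.counts.sum(axis=1) > 0
        assert np.all(np.abs(np.round(cm.percent[rows], 1).sum(axis=1) - 100.0) <= 0.3)


def test_permutation_equivariance(rng):
    actual = rng.integers(0, 4, 300)
    predicted = rng.integers(0, 4, 300)
    perm = np.array([2, 0, 3, 1])
    cm = confusion_matrix(predicted, actual)
    cm_perm = confusion_matrix(perm[predicted], perm[actual])
    inv = np.argsort(perm)
    assert np.array_equal(cm_perm.counts, cm.counts[np.ix_(inv, inv)][:, :])


def test_length_mismatch_and_empty_rejected():
    with pytest.raises(ValueError):
        confusion_matrix([0, 1], [0])
    with pytest.raises(ValueError):
        confusion_matrix([], [])


def test_widely_separated_classes_identity(params):
    p = GenerativeParams(mean=params.mean * 40, sd=params.sd)  # >= 20 sd apart
    cm = expected_confusion(p, 500, seed=0, classifier=BayesClassifier(p))
    assert np.all(np.diag(cm.percent) > 99.0)


def test_identical_classes_are_indistinguishable(params):
    """With all four class-conditionals identical no classifier can beat
    chance.  The Bayes rule sees an exactly uniform posterior, so its
    deterministic tie-break sends every record to PPC: rows are identical
    and overall accuracy is exactly 25%.  A label-randomizing classifier
    lands every cell near 25% within binomial error."""
    p = GenerativeParams(
        mean=np.tile(params.mean[0], (4, 1)), sd=np.tile(params.sd[0], (4, 1))
    )
    n_mc = 2000
    cm = expected_confusion(p, n_mc, seed=1, classifier=BayesClassifier(p))
    assert np.all(cm.counts == cm.counts[0])  # no row distinguishable
    assert cm.accuracy == pytest.approx(25.0)

    rng = np.random.default_rng(2)
    cm_rand = expected_confusion(
        p, n_mc, seed=1, classifier=lambda X: rng.integers(0, 4, len(X))
    )
    tol = 3 * np.sqrt(25 * 75 / n_mc)
    assert np.all(np.abs(cm_rand.percent - 25.0) <= tol)


def test_expected_confusion_self_consistent_with_per_record_oracle(params):
    n_mc, seed = 400, 17
    cm = expected_confusion(params, n_mc, seed, classifier=BayesClassifier(params))
    cohort = sample_cohort(params, n_mc, seed)
    labels = np.array([int(bayes_posterior(x, params).label) for x in cohort.X])
    assert np.array_equal(cm.counts, confusion_matrix(labels, cohort.y).counts)


def test_mean_separation_monotonicity(params):
    """Scaling all means away from their centroid (common random numbers)
    never decreases Bayes accuracy."""
    rng = np.random.default_rng(5)
    z = rng.standard_normal((4000, 4))
    y = np.repeat(np.arange(4), 1000)
    centroid = params.mean.mean(axis=0)
    accs = []
    for scale in [0.5, 1.0, 1.5, 2.0, 3.0]:
        mean = centroid + scale * (params.mean - centroid)
        p = GenerativeParams(mean=mean, sd=params.sd)
        X = mean[y] + params.sd[y] * z
        accs.append(np.mean(bayes_labels(X, p) == y))
    assert np.all(np.diff(accs) >= -0.01)  # small MC slack


# -- clinical cohort arithmetic ------------------------------------------

def test_clinical_counts_reproduce_reported_accuracies():
    m = cohort_metrics(CLINICAL_COUNTS)
    assert m.rounded() == {"CCC": 76.0, "PPC": 58.3, "CPC": 60.0, "OCC": 62.5}
    assert m.overall_rounded == 68.0
    assert (m.total_correct, m.total_n) == (34, 50)


def test_all_correct_and_all_wrong():
    perfect = CohortCounts(
        n={"CCC": 3, "PPC": 2}, n_correct={"CCC": 3, "PPC": 2}, misclassified_as={}
    )
    m = cohort_metrics(perfect)
    assert m.overall_concordance == 100.0
    assert all(v == 100.0 for v in m.per_class_accuracy.values())
    hopeless = CohortCounts(
        n={"CCC": 3},
        n_correct={"CCC": 0},
        misclassified_as={"CCC": {"OCC": 3}},
    )
    assert cohort_metrics(hopeless).overall_concordance == 0.0


def test_empty_class_excluded_from_display_not_totals():
    c = CohortCounts(
        n={"CCC": 4, "PPC": 0}, n_correct={"CCC": 2, "PPC": 0},
        misclassified_as={"CCC": {"OCC": 2}},
    )
    m = cohort_metrics(c)
    assert m.per_class_accuracy["PPC"] is None
    assert m.total_n == 4 and m.overall_concordance == 50.0
    assert "undefined" in m.to_text()


def test_concordance_is_count_weighted_mean_of_class_accuracies():
    m = cohort_metrics(CLINICAL_COUNTS)
    weighted = sum(
        CLINICAL_COUNTS.n[s] * m.per_class_accuracy[s] for s in CLINICAL_COUNTS.n
    ) / CLINICAL_COUNTS.total
    assert m.overall_concordance == pytest.approx(weighted, abs=1e-12)


def test_inconsistent_counts_rejected():
    with pytest.raises(ValueError, match="!= n"):
        CohortCounts(n={"CCC": 5}, n_correct={"CCC": 3}, misclassified_as={})
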