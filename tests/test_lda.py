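import math
import warnings

import numpy as np
import pytest

from _oracles import gaussian_posterior_oracle
from conftest import random_training_systems
from tcassign import lda
from tcassign.lda import (
    PRESETS,
    FeatureSubset,
    LDAError,
    LDAModel,
    exclude_classes,
    fit,
    fit_from_statistics,
    fit_subset_family,
    posterior,
    posterior_auto,
)
from tcassign.peaklists import TypeStatisticsTable
from tcassign.spinsys import SpinSystem


def _sys(sid, cls, **features):
    shifts = {k: v for k, v in features.items() if not k.startswith("TC")}
    tcs = {k: v for k, v in features.items() if k.startswith("TC")}
    return SpinSystem(id=sid, res_type=cls, shifts=shifts, tcs=tcs)


def _two_class_1d_model():
    """Hand-built: standardized means +-1, unit variance, uniform priors."""
    return LDAModel(
        classes=("A", "S"),
        means=np.array([[-1.0], [1.0]]),
        pooled_cov=np.array([[1.0]]),
        priors=np.array([0.5, 0.5]),
        center=np.array([0.0]),
        scale=np.array([1.0]),
        lam=0.0,
        n_per_class={"A": 5, "S": 5},
        subset=FeatureSubset("1d", ("CA",)),
    )


def test_subset_presets_cover_the_six_combinations():
    assert PRESETS["i"].features == ("HN", "N", "C", "CA")
    assert PRESETS["ii"].features[4:] == ("TC1_HN", "TC1_N", "TC1_C", "TC1_CA")
    assert len(PRESETS["iii"].features) == 12
    assert PRESETS["iv"].features == ("HN", "N", "C", "CA", "CB")
    assert len(PRESETS["v"].features) == 10 and "TC1_CB" in PRESETS["v"].features
    assert len(PRESETS["vi"].features) == 15 and "TC2_CB" in PRESETS["vi"].features


def test_degenerate_scatter_singular_at_lambda_zero():
    train = [
        _sys("a1", "A", CA=0.0), _sys("a2", "A", CA=0.0),
        _sys("s1", "S", CA=2.0), _sys("s2", "S", CA=2.0),
    ]
    with pytest.raises(LDAError, match="lambda"):
        fit(train, FeatureSubset("1d", ("CA",)), lam=0.0, min_class_size=2)
    model = fit(train, FeatureSubset("1d", ("CA",)), lam=0.1, min_class_size=2)
    assert len(model.classes) == 2


def test_uniform_priors_on_balanced_training():
    systems, classes = random_training_systems(
        np.random.default_rng(0), ("CA", "CB"), n_classes=4, n_per_class=5
    )
    model = fit(systems, FeatureSubset("2d", ("CA", "CB")))
    assert np.allclose(model.priors, 0.25)


def test_sequence_priors_hand_count():
    systems, _ = random_training_systems(
        np.random.default_rng(1), ("CA",), n_classes=3, n_per_class=4
    )  # classes A, C, D
    model = fit(
        systems, FeatureSubset("1d", ("CA",)), priors="sequence",
        sequence="ACCDPPDDGA",  # A:2 C:2 D:3; P and G are not model classes
    )
    assert dict(zip(model.classes, model.priors)) == pytest.approx(
        {"A": 2 / 7, "C": 2 / 7, "D": 3 / 7}
    )


def test_two_class_closed_form_posterior():
    model = _two_class_1d_model()
    mid = posterior(model, SpinSystem(id="q0", shifts={"CA": 0.0}))
    assert mid.posteriors["A"] == pytest.approx(0.5, abs=1e-12)
    at1 = posterior(model, SpinSystem(id="q1", shifts={"CA": 1.0}))
    assert at1.posteriors["S"] == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-12)


def test_posterior_matches_gaussian_oracle_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(30):
        d = int(rng.integers(1, 6))
        feats = ("HN", "N", "C", "CA", "CB", "TC1_HN", "TC1_N", "TC1_C", "TC1_CA", "TC1_CB")[:d]
        systems, classes = random_training_systems(
            rng, feats, n_classes=int(rng.integers(2, 8)), n_per_class=d + 4
        )
        lam = float(rng.choice([0.0, 0.05, 0.3]))
        model = fit(systems, FeatureSubset("r", feats), lam=lam)
        q = SpinSystem(
            id="q",
            shifts={f: float(rng.normal(0, 3)) for f in feats if not f.startswith("TC")},
            tcs={f: float(rng.normal(0, 3)) for f in feats if f.startswith("TC")},
        )
        ours = posterior(model, q).posteriors
        oracle = gaussian_posterior_oracle(model, q)
        for c in model.classes:
            assert ours[c] == pytest.approx(oracle[c], abs=1e-8)


def test_posteriors_sum_to_one_and_ranking_consistent():
    rng = np.random.default_rng(7)
    for _ in range(20):
        feats = ("CA", "CB", "TC1_HN")
        systems, _ = random_training_systems(rng, feats, 5, 6, spread=float(rng.uniform(0, 4)))
        model = fit(systems, FeatureSubset("r", feats))
        q = SpinSystem(id="q", shifts={"CA": 0.1, "CB": -0.3}, tcs={"TC1_HN": 1.0})
        res = posterior(model, q)
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        probs = [res.posteriors[c] for c in res.ranking]
        assert probs == sorted(probs, reverse=True)


def test_affine_invariance_under_feature_rescaling():
    rng = np.random.default_rng(3)
    feats = ("CA", "CB")
    systems, _ = random_training_systems(rng, feats, 4, 8)
    q = SpinSystem(id="q", shifts={"CA": 0.5, "CB": -1.0})
    base = posterior(fit(systems, FeatureSubset("r", feats), lam=0.0), q).posteriors

    scaled = [
        SpinSystem(id=s.id, res_type=s.res_type,
                   shifts={"CA": 40.0 * s.shifts["CA"], "CB": s.shifts["CB"]})
        for s in systems
    ]
    q_scaled = SpinSystem(id="q", shifts={"CA": 40.0 * 0.5, "CB": -1.0})
    rescaled = posterior(fit(scaled, FeatureSubset("r", feats), lam=0.0), q_scaled).posteriors
    for c in base:
        assert rescaled[c] == pytest.approx(base[c], abs=1e-9)


def test_posterior_nondecreasing_in_prior():
    systems, classes = random_training_systems(np.random.default_rng(9), ("CA",), 3, 6)
    q = SpinSystem(id="q", shifts={"CA": 0.2})
    sub = FeatureSubset("1d", ("CA",))
    target = classes[0]
    probs = []
    for w in (0.1, 0.3, 0.6, 0.8):
        pri = {c: (w if c == target else (1 - w) / 2) for c in classes}
        model = fit(systems, sub, priors=pri)
        probs.append(posterior(model, q).posteriors[target])
    assert probs == sorted(probs)


def test_missing_feature_directs_to_posterior_auto():
    systems, _ = random_training_systems(np.random.default_rng(2), ("CA", "CB"), 3, 5)
    model = fit(systems, FeatureSubset("2d", ("CA", "CB")))
    with pytest.raises(LDAError, match="posterior_auto"):
        posterior(model, SpinSystem(id="q", shifts={"CA": 0.0}))


def test_subset_family_refits_and_caches(benchmark):
    cache = fit_subset_family(benchmark.train, "v")
    full = cache.model_for(PRESETS["v"].features)
    assert len(full.subset.features) == 10

    reduced = cache.model_for(("HN", "N", "CA"))
    assert reduced is cache.model_for(("HN", "N", "CA"))  # cache hit
    assert len(reduced.subset.features) == 3

    q_full = benchmark.queries[0]
    assert posterior_auto(cache, q_full).posteriors == posterior(full, q_full).posteriors

    q3 = SpinSystem(id="q3", shifts={n: q_full.shifts[n] for n in ("HN", "N", "CA")})
    res = posterior_auto(cache, q3)
    assert res.subset.features == ("HN", "N", "CA")

    q1 = SpinSystem(id="q1", shifts={"HN": q_full.shifts["HN"]})
    assert posterior_auto(cache, q1).low_information


def test_fit_from_statistics_two_classes_4sd_apart():
    table = TypeStatisticsTable()
    table.add("A", "CA", 52.0, 0.5)
    table.add("S", "CA", 54.0, 0.5)  # 4 sd apart
    model = fit_from_statistics(table, FeatureSubset("1d", ("CA",)))
    at_a = posterior(model, SpinSystem(id="a", shifts={"CA": 52.0}))
    assert at_a.posteriors["A"] == pytest.approx(1 / (1 + math.exp(-8)), rel=1e-9)


def test_fit_from_statistics_drops_classes_without_cells():
    table = TypeStatisticsTable()
    for t, m in (("A", 52.5), ("S", 58.3), ("T", 61.9)):
        table.add(t, "CA", m, 0.5)
    table.add("A", "TC1_HN", -7.0, 0.5)
    table.add("S", "TC1_HN", -6.0, 0.5)
    with pytest.warns(UserWarning, match="T"):
        model = fit_from_statistics(table, FeatureSubset("x", ("CA", "TC1_HN")))
    assert model.classes == ("A", "S")
    assert "T" in model.excluded_classes

    with pytest.raises(LDAError):
        fit_from_statistics(table, FeatureSubset("y", ("CA", "TC1_N")))


def test_fit_from_statistics_equal_means_returns_priors():
    table = TypeStatisticsTable()
    for t in ("A", "S", "T"):
        table.add(t, "CA", 55.0, 0.5)
    pri = {"A": 0.5, "S": 0.3, "T": 0.2}
    model = fit_from_statistics(table, FeatureSubset("1d", ("CA",)), priors=pri)
    res = posterior(model, SpinSystem(id="q", shifts={"CA": 57.0}))
    assert res.posteriors == pytest.approx(pri)


def test_exclude_classes():
    systems, classes = random_training_systems(np.random.default_rng(4), ("CA",), 6, 5)
    model = fit(systems, FeatureSubset("1d", ("CA",)))
    smaller = exclude_classes(model, ["A", "C"])
    assert len(smaller.classes) == 4
    assert sum(smaller.priors) == pytest.approx(1.0)
    assert exclude_classes(model, []) is model
    with pytest.raises(LDAError):
        exclude_classes(model, classes[:-1])
    filtered = exclude_classes(systems, ["A"])
    assert all(s.res_type != "A" for s in filtered)


def test_model_json_round_trip(tmp_path, benchmark):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit(benchmark.train, "v")
    path = tmp_path / "model.json"
    lda.save_model(model, path, provenance={"note": "fixture"})
    back = lda.load_model(path)
    q = benchmark.queries[0]
    a = posterior(model, q).posteriors
    b = posterior(back, q).posteriors
    for c in a:
        assert b[c] == pytest.approx(a[c], abs=1e-12)


def test_predictions_agree_with_reference_lda(benchmark):
    sklearn = pytest.importorskip("sklearn.discriminant_analysis")
    feats = PRESETS["iv"].features
    X = np.array([[s.feature(f) for f in feats] for s in benchmark.train])
    y = np.array([s.res_type for s in benchmark.train])
    ref = sklearn.LinearDiscriminantAnalysis().fit(X, y)
    model = fit(benchmark.train, "iv", priors="training", lam=0.0, min_class_size=2)
    ours = [
        posterior(model, s).ranking[0]
        for s in benchmark.queries
        if all(s.feature(f) is not None for f in feats)
    ]
    theirs = ref.predict(
        np.array([
            [s.feature(f) for f in feats]
            for s in benchmark.queries
            if all(s.feature(f) is not None for f in feats)
        ])
    )
    agreement = np.mean([a == b for a, b in zip(ours, theirs)])
    assert agreement >= 0.95
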