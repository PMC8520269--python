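"""Outlier classification: interval oracle, CI rule, quantile rule, combining."""

import numpy as np
import pytest

from clinekit.outliers import (
    OutlierFlag,
    ci_outlier_flag,
    classify_outliers,
    equal_tailed_interval,
    quantile_outlier_flag,
)
from clinekit.posterior import PosteriorSamples


def _oracle_interval(samples, level):
    """Independent sort-and-interpolate quantile oracle (linear rule)."""
    x = np.sort(np.asarray(samples, float))
    out = []
    for p in ((1 - level) / 2, (1 + level) / 2):
        pos = p * (x.size - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, x.size - 1)
        out.append(x[lo] + (pos - lo) * (x[hi] - x[lo]))
    return tuple(out)


def test_interval_on_small_ordered_sample():
    lo, hi = equal_tailed_interval([1, 2, 3, 4, 5], 0.6)
    assert lo == pytest.approx(1.8, abs=1e-12)
    assert hi == pytest.approx(4.2, abs=1e-12)


def test_interval_of_constant_sample_is_degenerate():
    assert equal_tailed_interval([2.0, 2.0, 2.0], 0.95) == (2.0, 2.0)


def test_interval_symmetry_around_zero():
    x = np.concatenate([np.arange(1, 50.0), -np.arange(1, 50.0)])
    lo, hi = equal_tailed_interval(x, 0.9)
    assert lo == pytest.approx(-hi, abs=1e-12)


def test_interval_matches_independent_oracle_on_random_arrays():
    rng = np.random.default_rng(99)
    for _ in range(100):
        x = rng.normal(size=rng.integers(2, 200))
        level = rng.uniform(0.5, 0.99)
        assert equal_tailed_interval(x, level) == pytest.approx(
            _oracle_interval(x, level), abs=1e-12
        )


def test_interval_rejects_non_finite():
    with pytest.raises(ValueError, match="non-finite"):
        equal_tailed_interval([1.0, np.nan], 0.95)


def test_ci_flags_by_interval_position():
    rng = np.random.default_rng(1)
    assert ci_outlier_flag(rng.normal(5, 0.1, 500), 0.95) is OutlierFlag.OUTLIER_POS
    assert ci_outlier_flag(rng.normal(-5, 0.1, 500), 0.95) is OutlierFlag.OUTLIER_NEG
    assert ci_outlier_flag(rng.normal(0, 1, 10_000), 0.95) is OutlierFlag.NOT_OUTLIER


def test_ci_monotone_in_level():
    # raising the level widens the interval, so outliers can only disappear
    rng = np.random.default_rng(2)
    for _ in range(50):
        x = rng.normal(rng.normal(), 1.0, size=200)
        flags = [ci_outlier_flag(x, lv).is_outlier for lv in (0.5, 0.8, 0.95, 0.99)]
        # once not-outlier, never outlier again at a higher level
        seen_not = False
        for f in flags:
            if not f:
                seen_not = True
            assert not (seen_not and f)


@pytest.mark.parametrize(
    "q,n,expected",
    [
        (0.01, 0.95, OutlierFlag.OUTLIER_NEG),
        (0.5, 0.95, OutlierFlag.NOT_OUTLIER),
        (0.5, 0.5, OutlierFlag.NOT_OUTLIER),
        (0.99, 0.975, OutlierFlag.OUTLIER_POS),  # upper bound (1+n)/2 = 0.9875
        (0.9875, 0.975, OutlierFlag.NOT_OUTLIER),
    ],
)
def test_quantile_rule_thresholds(q, n, expected):
    assert quantile_outlier_flag(q, n) is expected


def test_quantile_rule_rejects_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        quantile_outlier_flag(1.5, 0.95)


def test_quantile_rule_flags_uniform_fraction():
    rng = np.random.default_rng(3)
    q = rng.uniform(0, 1, size=10_000)
    for n in (0.90, 0.95, 0.975):
        frac = np.mean([quantile_outlier_flag(v, n).is_outlier for v in q])
        assert frac == pytest.approx(1 - n, abs=0.01)


# ---------------------------------------------------------- classification

def _posteriors(alpha_mu, beta_mu, sd=0.1, n_draws=500, seed=0, quantiles=True):
    rng = np.random.default_rng(seed)
    n = len(alpha_mu)
    mk = lambda mu: PosteriorSamples(
        "x", rng.normal(np.asarray(mu), sd, size=(n_draws, n)),
        np.zeros(n_draws, int), 0, 1, [n_draws])
    out = {"alpha": mk(alpha_mu), "beta": mk(beta_mu)}
    if quantiles:
        from scipy.stats import norm

        qa = np.clip(norm.cdf(np.asarray(alpha_mu)) +
                     rng.normal(0, 0.01, size=(n_draws, n)), 0, 1)
        qb = np.clip(norm.cdf(np.asarray(beta_mu)) +
                     rng.normal(0, 0.01, size=(n_draws, n)), 0, 1)
        out["gamma_quantile"] = PosteriorSamples("g", qa, np.zeros(n_draws, int), 0, 1, [n_draws])
        out["zeta_quantile"] = PosteriorSamples("z", qb, np.zeros(n_draws, int), 0, 1, [n_draws])
    return out

def test_planted_alpha_outlier_flagged_positive():
    ps = _posteriors([2.0, 0.0], [0.0, 0.0], seed=4)
    cls = classify_outliers(ps, methods=("ci",))
    assert cls[0].alpha_final and cls[0].alpha_ci is OutlierFlag.OUTLIER_POS
    assert not cls[1].alpha_final


def test_combine_all_requires_every_method_to_agree():
    # alpha near the CI edge but prior quantile clearly central:
    # CI flags it, quantile does not -> AND verdict is not-outlier
    ps = _posteriors([0.3], [0.0], sd=0.1, seed=5)
    cls_any = classify_outliers(ps, methods=("ci", "quantile"), combine="any")
    cls_all = classify_outliers(ps, methods=("ci", "quantile"), combine="all")
    assert cls_any[0].alpha_ci.is_outlier
    assert not cls_all[0].alpha_q.is_outlier
    assert cls_any[0].alpha_final
    assert not cls_all[0].alpha_final


def test_quantile_method_without_quantile_posteriors_errors():
    ps = _posteriors([0.0], [0.0], quantiles=False)
    with pytest.raises(ValueError, match="quantile"):
        classify_outliers(ps, methods=("quantile",))


def test_alpha_and_beta_judged_independently():
    ps = _posteriors([2.0], [-2.0], seed=6)
    cls = classify_outliers(ps, methods=("ci",))
    assert cls[0].alpha_ci is OutlierFlag.OUTLIER_POS
    assert cls[0].beta_ci is OutlierFlag.OUTLIER_NEG


def test_null_loci_flag_rate_is_nominal():
    # true-null loci whose posterior center carries the usual estimation
    # noise: the 95% credible interval excludes zero for ~5% of them
    rng = np.random.default_rng(8)
    n_loci, n_draws = 1000, 500
    centers = rng.normal(0.0, 0.2, size=n_loci)
    samples = centers + rng.normal(0.0, 0.2, size=(n_draws, n_loci))
    ps = {
        "alpha": PosteriorSamples("alpha", samples, np.zeros(n_draws, int), 0, 1, [n_draws]),
        "beta": PosteriorSamples("beta", np.zeros((n_draws, n_loci)), np.zeros(n_draws, int), 0, 1, [n_draws]),
    }
    cls = classify_outliers(ps, level=0.95, methods=("ci",))
    rate = np.mean([c.alpha_final for c in cls])
    assert rate == pytest.approx(0.05, abs=0.02)


@pytest.mark.parametrize("param", ["alpha", "beta"])
def test_planted_outlier_recovery(param):
    from clinekit.fixtures import planted_outlier_truth, simulate_bgc_posterior
    from clinekit.posterior import combine_all

    import tempfile

    truth = planted_outlier_truth(n_null=90, n_outlier=10, effect=1.5,
                                  posterior_sd=0.2, seed=31, param=param)
    with tempfile.TemporaryDirectory() as d:
        simulate_bgc_posterior(truth, d, prefix="r")
        ps = combine_all(d, "r", burnin=100, thin=1)
    cls = classify_outliers(ps, level=0.95, methods=("ci",))
    flagged = {j for j, c in enumerate(cls)
               if (c.alpha_final if param == "alpha" else c.beta_final)}
    tp = len(flagged & truth.outlier_set)
    fp = len(flagged - truth.outlier_set)
    assert tp / len(truth.outlier_set) >= 0.9
    assert fp / 90 <= 0.10
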