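"""Survival statistics against closed forms, hand enumeration, and references."""

import numpy as np
import pytest
from scipy import stats

from kronsurv.nn import Tensor
from kronsurv.survival import (SurvivalData, bootstrap_ci, concordance_index,
                               cox_loss, cox_loss_tensor, find_cutpoint,
                               fit_coxph, km_estimate, log_rank_test, partial_lrt)

from conftest import random_survival


# ---------------------------------------------------------------------------
# Cox loss
# ---------------------------------------------------------------------------

def test_cox_loss_two_patient_closed_form():
    surv = SurvivalData([1.0, 2.0], [1, 0])
    assert np.isclose(cox_loss(np.zeros(2), surv), np.log(2))


def test_cox_loss_vanishes_when_event_dominates():
    surv = SurvivalData([1.0, 2.0, 3.0], [1, 0, 0])
    h = np.array([40.0, 0.0, 0.0])
    assert cox_loss(h, surv) < 1e-10


def test_cox_loss_breslow_enumeration_with_ties(rng):
    # oracle: write the Breslow sum out term by term
    t = np.array([3.0, 1.0, 1.0, 2.0, 2.0, 5.0])
    e = np.array([1, 1, 1, 0, 1, 0])
    h = rng.standard_normal(6)
    surv = SurvivalData(t, e)
    terms = []
    for i in range(6):
        if e[i]:
            denom = sum(np.exp(h[j]) for j in range(6) if t[j] >= t[i])
            terms.append(h[i] - np.log(denom))
    assert np.isclose(cox_loss(h, surv), -np.mean(terms))


def test_cox_loss_requires_events():
    with pytest.raises(ValueError):
        cox_loss(np.zeros(3), SurvivalData([1, 2, 3], [0, 0, 0]))


def test_cox_loss_tensor_matches_numpy_and_finite_diff(rng):
    surv = random_survival(rng, 12)
    h = rng.standard_normal(12)
    t = Tensor(h, requires_grad=True)
    loss = cox_loss_tensor(t, surv)
    assert np.isclose(loss.item(), cox_loss(h, surv))
    loss.backward()
    eps = 1e-6
    fd = np.zeros(12)
    for i in range(12):
        hp, hm = h.copy(), h.copy()
        hp[i] += eps
        hm[i] -= eps
        fd[i] = (cox_loss(hp, surv) - cox_loss(hm, surv)) / (2 * eps)
    assert np.max(np.abs(t.grad - fd)) / max(np.max(np.abs(fd)), 1e-12) < 1e-4


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def brute_force_c(h, surv):
    conc = n = 0.0
    for i in range(len(h)):
        for j in range(len(h)):
            if surv.time[i] < surv.time[j] and surv.event[i] == 1:
                n += 1
                if h[i] > h[j]:
                    conc += 1
                elif h[i] == h[j]:
                    conc += 0.5
    return conc / n


def test_concordance_perfect_and_ties():
    surv = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
    assert concordance_index([3.0, 2.0, 1.0], surv) == 1.0
    assert concordance_index([1.0, 1.0, 1.0], surv) == 0.5


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_concordance_equals_pair_enumeration(seed):
    rng = np.random.default_rng(seed)
    surv = random_survival(rng, 50)
    h = np.round(rng.standard_normal(50), 1)  # rounding induces prediction ties
    assert concordance_index(h, surv) == pytest.approx(brute_force_c(h, surv))


def test_concordance_no_comparable_pairs():
    with pytest.raises(ValueError):
        concordance_index([1.0, 2.0], SurvivalData([5.0, 1.0], [0, 0]))


def test_concordance_matches_sksurv_on_tie_free_data(rng):
    sksurv = pytest.importorskip("sksurv.metrics")
    surv = random_survival(rng, 100)
    h = rng.standard_normal(100)
    ref = sksurv.concordance_index_censored(surv.event.astype(bool), surv.time, h)[0]
    assert concordance_index(h, surv) == pytest.approx(ref)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_defaults_and_determinism(rng):
    surv = random_survival(rng, 40)
    h = rng.standard_normal(40)
    r1 = bootstrap_ci(h, surv, seed=5)
    r2 = bootstrap_ci(h, surv, seed=5)
    assert r1.n_boot == 1000 and r1.level == 0.95
    assert (r1.ci_low, r1.c, r1.ci_high) == (r2.ci_low, r2.c, r2.ci_high)
    assert r1.ci_low <= r1.c <= r1.ci_high


def test_bootstrap_degenerate_interval():
    # perfectly ordered data: C = 1 in every resample with comparable pairs
    surv = SurvivalData(np.arange(1.0, 9.0), np.ones(8, int))
    h = -np.arange(8.0)
    r = bootstrap_ci(h, surv, n_boot=50, seed=1)
    assert r.ci_low == r.c == r.ci_high == 1.0


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def test_km_no_censoring_is_empirical_survival():
    surv = SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    times, s = km_estimate(surv)[0]
    assert np.allclose(times, [0, 1, 2, 3, 4])
    assert np.allclose(s, [1.0, 0.75, 0.5, 0.25, 0.0])


def test_km_all_censored_flat():
    times, s = km_estimate(SurvivalData([1.0, 2.0], [0, 0]))[0]
    assert np.allclose(s, [1.0])


def test_km_mixed_hand_table():
    # classic product-limit: events at 2 (1 of 5 at risk) and 5 (1 of 2)
    surv = SurvivalData([2.0, 3.0, 4.0, 5.0, 6.0], [1, 0, 0, 1, 0])
    times, s = km_estimate(surv)[0]
    assert np.allclose(times, [0, 2, 5])
    assert np.allclose(s, [1.0, 0.8, 0.8 * 0.5])


def test_log_rank_identical_groups_null():
    surv = SurvivalData([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
    chi2, p = log_rank_test(surv, [0, 0, 0, 1, 1, 1])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_log_rank_separated_groups():
    surv = SurvivalData(np.r_[np.arange(1, 11), np.arange(100, 110)],
                        np.ones(20, int))
    chi2, p = log_rank_test(surv, np.r_[np.zeros(10, int), np.ones(10, int)])
    assert chi2 > 10 and p < 1e-3


def test_log_rank_hand_computation():
    # ten patients, O/E/V accumulated over event times by explicit loop
    t = np.array([1, 2, 3, 4, 5, 2, 4, 6, 7, 8.0])
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 0, 1])
    g = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    O = E = V = 0.0
    for ut in np.unique(t[e == 1]):
        at = t >= ut
        n, n1 = at.sum(), (at & (g == 1)).sum()
        d = ((t == ut) & (e == 1)).sum()
        d1 = ((t == ut) & (e == 1) & (g == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2, p = log_rank_test(SurvivalData(t, e), g)
    assert chi2 == pytest.approx((O - E) ** 2 / V)
    assert p == pytest.approx(stats.chi2.sf((O - E) ** 2 / V, 1))


def test_log_rank_matches_lifelines(rng):
    lls = pytest.importorskip("lifelines.statistics")
    surv = random_survival(rng, 60)
    g = rng.integers(0, 2, 60)
    chi2, p = log_rank_test(surv, g)
    ref = lls.logrank_test(surv.time[g == 0], surv.time[g == 1],
                           surv.event[g == 0], surv.event[g == 1])
    assert chi2 == pytest.approx(ref.test_statistic)
    assert p == pytest.approx(ref.p_value)


# ---------------------------------------------------------------------------
# Cutpoint
# ---------------------------------------------------------------------------

def exhaustive_cutpoint(h, surv, minprop=0.1):
    from kronsurv.survival import _logrank_oe
    n = len(h)
    best = None
    for cut in (np.unique(h)[:-1] + np.diff(np.unique(h)) / 2):
        high = (h > cut).astype(int)
        if min(high.sum(), n - high.sum()) < minprop * n:
            continue
        O, E, V = _logrank_oe(surv, high)
        z = abs(O - E) / np.sqrt(V) if V > 0 else 0.0
        if best is None or z > best[1] + 1e-12:
            best = (cut, z)
    return best


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_cutpoint_equals_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    h = rng.standard_normal(80)
    surv = random_survival(rng, 80, hazard=h)
    res = find_cutpoint(h, surv)
    cut, z = exhaustive_cutpoint(h, surv)
    assert res.threshold == pytest.approx(cut)
    assert res.statistic == pytest.approx(z)


def test_cutpoint_bimodal_falls_between_modes(rng):
    h = np.r_[rng.normal(-3, 0.3, 40), rng.normal(3, 0.3, 40)]
    surv = random_survival(rng, 80, hazard=h)
    res = find_cutpoint(h, surv)
    assert -2 < res.threshold < 2
    assert np.array_equal(res.group_labels, (h > res.threshold).astype(int))


def test_cutpoint_rank_invariance(rng):
    h = rng.standard_normal(60)
    surv = random_survival(rng, 60, hazard=h)
    a = find_cutpoint(h, surv)
    b = find_cutpoint(np.exp(h), surv)  # monotone relabeling
    assert np.array_equal(a.group_labels, b.group_labels)


def test_cutpoint_no_admissible_cut():
    surv = SurvivalData(np.arange(1.0, 8.0), np.ones(7, int))
    with pytest.raises(ValueError):
        find_cutpoint(np.arange(7.0), surv, minprop=0.5)  # odd n, no valid split


# ---------------------------------------------------------------------------
# CoxPH fitting and LRT
# ---------------------------------------------------------------------------

def test_fit_coxph_recovers_unit_coefficient():
    from kronsurv.synthetic import CohortConfig, generate_cohort
    co = generate_cohort(CohortConfig(n_patients=2000, n_genes=2, n_cpgs=2,
                                      n_pathways=2, genes_per_pathway=1,
                                      grid_size=2, patch_embed_dim=2, seed=31))
    m = fit_coxph(co.truth.eta, co.survival)
    assert abs(m.beta_hat[0] - 1.0) < 3 * m.se[0]


def test_fit_coxph_constant_covariate_errors(rng):
    surv = random_survival(rng, 20)
    with pytest.raises(ValueError):
        fit_coxph(np.ones(20), surv)


def test_fit_coxph_matches_sksurv(rng):
    sk = pytest.importorskip("sksurv.linear_model")
    X = rng.standard_normal((150, 3))
    surv = random_survival(rng, 150, hazard=X @ [0.5, -0.3, 0.0])
    mine = fit_coxph(X, surv)
    y = np.array(list(zip(surv.event.astype(bool), surv.time)),
                 dtype=[("e", bool), ("t", float)])
    ref = sk.CoxPHSurvivalAnalysis(alpha=0.0).fit(X, y)
    assert np.allclose(mine.beta_hat, ref.coef_, atol=1e-6)


def test_partial_lrt_identical_and_quantile(rng):
    surv = random_survival(rng, 100)
    X = rng.standard_normal((100, 2))
    full = fit_coxph(X, surv)
    assert partial_lrt(full, full_with(full, X, surv)).stat >= 0

    same = fit_coxph(X[:, :1], surv)
    res = partial_lrt(same, same.__class__(beta_hat=same.beta_hat,
                                           loglik=same.loglik,
                                           covariance=same.covariance,
                                           n_params=2, n_samples=same.n_samples))
    assert res.stat == 0.0 and res.p == 1.0
    # chi-square quantile sanity: stat 3.841, df 1 -> p ~ 0.05
    assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)


def full_with(reduced, X, surv):
    import numpy as np
    rng = np.random.default_rng(0)
    X2 = np.column_stack([X, rng.standard_normal(len(X))])
    return fit_coxph(X2, surv)


def test_partial_lrt_rejects_non_nested(rng):
    surv = random_survival(rng, 50)
    X = rng.standard_normal((50, 2))
    full = fit_coxph(X, surv)
    reduced = fit_coxph(X[:, :1], surv)
    with pytest.raises(ValueError):
        partial_lrt(full, reduced)  # reversed order -> df <= 0


def test_partial_lrt_power(rng):
    # adding the true risk score to a noise covariate must reject strongly
    h = rng.standard_normal(200)
    surv = random_survival(rng, 200, hazard=h)
    noise = rng.standard_normal(200)
    reduced = fit_coxph(noise, surv)
    full = fit_coxph(np.column_stack([noise, h]), surv)
    assert partial_lrt(reduced, full).p < 1e-6
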