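"""Right-censored survival statistics.

Implements the evaluation backbone shared by every model in the package: the
negative log Cox partial likelihood (Breslow tie handling throughout, so the
training loss, the fitted proportional-hazards model and the likelihood-ratio
test are mutually consistent), Harrell's concordance index with a percentile
bootstrap, Kaplan-Meier estimation, the two-group log-rank test, log-rank
cutpoint selection for dichotomising predicted hazards, and Newton-Raphson
CoxPH fitting with nested-model partial likelihood ratio testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nn import Tensor

__all__ = [
    "SurvivalData", "CoxModel", "ConcordanceResult", "CutpointResult", "LRTResult",
    "cox_loss", "cox_loss_tensor", "concordance_index", "bootstrap_ci",
    "km_estimate", "log_rank_test", "find_cutpoint", "fit_coxph", "partial_lrt",
]


@dataclass
class SurvivalData:
    """Right-censored outcomes: time in days and an event indicator."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if len(self.time) == 0:
            raise ValueError("empty survival data")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(self.time[idx], self.event[idx])

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class CoxModel:
    beta_hat: np.ndarray
    loglik: float
    covariance: np.ndarray
    n_params: int
    n_samples: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class ConcordanceResult:
    c: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    n_redrawn: int = 0


@dataclass
class CutpointResult:
    threshold: float
    statistic: float
    group_labels: np.ndarray  # 1 = high hazard, 0 = low hazard


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def cox_loss(h: np.ndarray, surv: SurvivalData) -> float:
    """Negative mean log partial likelihood over events (Breslow ties).

    loss = -(1/d) * sum_{i: event} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]
    """
    h = np.asarray(h, dtype=np.float64).ravel()
    if len(h) != len(surv):
        raise ValueError("hazard vector length mismatch")
    if surv.n_events == 0:
        raise ValueError("Cox loss requires at least one event")
    m = h.max()
    order = np.argsort(-surv.time, kind="stable")  # decreasing time
    exp_h = np.exp(h[order] - m)
    cum = np.cumsum(exp_h)  # cum[k] = sum over the k+1 longest survivors
    log_risk = np.log(cum) + m
    # position of each sample in the decreasing-time order; ties share the
    # risk set of the *last* tied entry in that order (all with T_j >= T_i)
    t_sorted = surv.time[order]
    loss_terms = []
    for pos in range(len(h)):
        i = order[pos]
        if surv.event[i] != 1:
            continue
        # include everything with time >= T_i: rightmost tie position
        last = np.searchsorted(-t_sorted, -surv.time[i], side="right") - 1
        loss_terms.append(h[i] - log_risk[last])
    return float(-np.mean(loss_terms))


def cox_loss_tensor(h: Tensor, surv: SurvivalData) -> Tensor:
    """Autodiff version of :func:`cox_loss` for network training."""
    if surv.n_events == 0:
        raise ValueError("Cox loss requires at least one event")
    n = len(surv)
    if h.data.size != n:
        raise ValueError("hazard vector length mismatch")
    h = h.reshape(n)
    terms = []
    for i in range(n):
        if surv.event[i] != 1:
            continue
        at_risk = np.flatnonzero(surv.time >= surv.time[i])
        terms.append(h.take([i]) - h.take(at_risk).logsumexp().reshape(1))
    from .nn import concat
    return -concat(terms).mean()


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance_index(h: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's C: pair (i, j) comparable iff T_i < T_j and event_i = 1;
    concordant when h_i > h_j; tied predictions credit 0.5."""
    h = np.asarray(h, dtype=np.float64).ravel()
    if len(h) != len(surv):
        raise ValueError("hazard vector length mismatch")
    t, e = surv.time, surv.event
    # vectorised over events only
    conc = ties = n_pairs = 0.0
    for i in np.flatnonzero(e == 1):
        later = t > t[i]
        n_pairs += later.sum()
        conc += np.count_nonzero(h[i] > h[later])
        ties += np.count_nonzero(h[i] == h[later])
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return float((conc + 0.5 * ties) / n_pairs)


def bootstrap_ci(h: np.ndarray, surv: SurvivalData, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0) -> ConcordanceResult:
    """Non-parametric percentile bootstrap CI for the concordance index.

    Patients are resampled with replacement; resamples without comparable
    pairs are redrawn (counted in ``n_redrawn``). Deterministic under seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    h = np.asarray(h, dtype=np.float64).ravel()
    c_full = concordance_index(h, surv)
    rng = np.random.default_rng(seed)
    n = len(surv)
    stats_ = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                stats_[b] = concordance_index(h[idx], surv.subset(idx))
                break
            except ValueError:
                n_redrawn += 1
                if n_redrawn > 100 * n_boot:
                    raise ValueError("bootstrap cannot find resamples with comparable pairs")
    alpha = 1.0 - level
    lo, hi = np.percentile(stats_, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(lo, c_full), max(hi, c_full)
    return ConcordanceResult(c=c_full, ci_low=float(lo), ci_high=float(hi),
                             n_boot=n_boot, level=level, n_redrawn=n_redrawn)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(surv: SurvivalData, group_labels: np.ndarray | None = None) -> dict:
    """Product-limit estimator, optionally per group.

    Returns {group: (times, survival)} step functions; survival is 1 at t=0
    and evaluated just after each distinct event time.
    """
    if group_labels is None:
        group_labels = np.zeros(len(surv), dtype=int)
    group_labels = np.asarray(group_labels)
    out = {}
    for g in np.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            raise ValueError("empty group")
        t, e = surv.time[mask], surv.event[mask]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        times = [0.0]
        s_vals = [1.0]
        s = 1.0
        for ut in np.unique(t[e == 1]):
            n_at_risk = np.count_nonzero(t >= ut)
            d = np.count_nonzero((t == ut) & (e == 1))
            s *= 1.0 - d / n_at_risk
            times.append(float(ut))
            s_vals.append(float(s))
        out[g] = (np.array(times), np.array(s_vals))
    return out


def _logrank_oe(surv: SurvivalData, group_labels: np.ndarray) -> tuple[float, float, float]:
    """Observed-minus-expected and variance for group 1 across event times."""
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("log-rank test requires exactly two groups")
    g1 = group_labels == groups[1]
    t, e = surv.time, surv.event
    O = E = V = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = np.count_nonzero((t == ut) & (e == 1))
        d1 = np.count_nonzero((t == ut) & (e == 1) & g1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O, E, V


def log_rank_test(surv: SurvivalData, group_labels: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    if surv.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    O, E, V = _logrank_oe(surv, group_labels)
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def find_cutpoint(h: np.ndarray, surv: SurvivalData, minprop: float = 0.1) -> CutpointResult:
    """Dichotomise hazards at the cut maximising the standardised log-rank
    statistic |O - E| / sqrt(V), scanning midpoints between sorted unique
    values that leave at least ``minprop * n`` samples per side.

    Ties in the statistic resolve to the lower threshold. Rank-preserving
    transformations of ``h`` give identical group labels.
    """
    h = np.asarray(h, dtype=np.float64).ravel()
    if len(h) != len(surv):
        raise ValueError("hazard vector length mismatch")
    n = len(h)
    uniq = np.unique(h)
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        high = h > cut
        if high.sum() < minprop * n or (~high).sum() < minprop * n:
            continue
        O, E, V = _logrank_oe(surv, high.astype(int))
        z = abs(O - E) / np.sqrt(V) if V > 0 else 0.0
        if best is None or z > best[1] + 1e-12:  # strict: ties keep lower cut
            best = (cut, z, high)
    if best is None:
        raise ValueError("no admissible cutpoint under minprop constraint")
    cut, z, high = best
    return CutpointResult(threshold=float(cut), statistic=float(z),
                          group_labels=high.astype(int))


# ---------------------------------------------------------------------------
# CoxPH fitting and the partial likelihood ratio test
# ---------------------------------------------------------------------------

def _breslow_loglik_grad_hess(beta, X, surv: SurvivalData):
    """Log partial likelihood with gradient and Hessian (Breslow ties).

    Risk-set sums are cumulative sums over samples ordered by decreasing
    time; tied event times share the risk set of the last tied entry.
    """
    eta = X @ beta
    m = eta.max()
    w = np.exp(eta - m)
    t = surv.time
    order = np.argsort(-t, kind="stable")
    w_o, X_o, t_o = w[order], X[order], t[order]
    S0 = np.cumsum(w_o)
    S1 = np.cumsum(w_o[:, None] * X_o, axis=0)
    S2 = np.cumsum(w_o[:, None, None] * (X_o[:, :, None] * X_o[:, None, :]), axis=0)
    ev = np.flatnonzero(surv.event == 1)
    # rightmost position in the decreasing order with time >= each event time
    last = np.searchsorted(-t_o, -t[ev], side="right") - 1
    s0 = S0[last]
    xbar = S1[last] / s0[:, None]
    ll = float(eta[ev].sum() - (np.log(s0) + m).sum())
    grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
    hess = -(np.einsum("i,ijk->jk", 1.0 / s0, S2[last])
             - np.einsum("ij,ik->jk", xbar, xbar))
    return ll, grad, hess


def fit_coxph(covariates: np.ndarray, surv: SurvivalData,
              tol: float = 1e-8, max_iter: int = 100) -> CoxModel:
    """Newton-Raphson fit of a Cox proportional-hazards model.

    Iterates to gradient norm < ``tol`` (or ``max_iter``); the covariance is
    the inverse of the observed information. Constant covariates and
    monotone-likelihood separation (diverging coefficients) raise errors.
    """
    X = np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(surv):
        raise ValueError("covariate rows must match survival records")
    if surv.n_events == 0:
        raise ValueError("CoxPH requires at least one event")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate")
    # standardise internally for conditioning; back-transform at the end
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / sd
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik_grad_hess(beta, Z, surv)
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(hess, grad)
        new_beta = beta - step
        # halve the step until the likelihood does not decrease
        for _ in range(30):
            ll_new = _breslow_loglik_grad_hess(new_beta, Z, surv)[0]
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2
        beta = new_beta
        if np.any(np.abs(beta) > 50):
            raise ValueError("separation detected: unbounded coefficient")
    else:
        ll, grad, hess = _breslow_loglik_grad_hess(beta, Z, surv)
        if np.linalg.norm(grad) >= np.sqrt(tol):
            raise ValueError("Newton-Raphson failed to converge")
    ll, _, hess = _breslow_loglik_grad_hess(beta, Z, surv)
    cov_z = np.linalg.inv(-hess)
    beta_x = beta / sd
    cov_x = cov_z / np.outer(sd, sd)
    cov_x = (cov_x + cov_x.T) / 2
    return CoxModel(beta_hat=beta_x, loglik=float(ll), covariance=cov_x,
                    n_params=X.shape[1], n_samples=len(surv))


def partial_lrt(reduced: CoxModel, full: CoxModel) -> LRTResult:
    """Partial likelihood ratio test for nested CoxPH fits on the same samples.

    stat = 2 (loglik_full - loglik_reduced), chi-square with df equal to the
    difference in parameter counts. A p below 0.05 indicates the additional
    covariates improve prognostic capacity.
    """
    if full.n_samples != reduced.n_samples:
        raise ValueError("models must be fit on identical samples")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)
    return LRTResult(stat=float(stat), df=df, p=float(stats.chi2.sf(stat, df=df)))
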