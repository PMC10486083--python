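"""Prognostic signatures: bootstrapped penalized Cox, median-split
Kaplan-Meier evaluation, and the log-rank test.

The signature procedure is a deliberately small, fully specified skeleton:
an L2-penalized Cox partial likelihood (Breslow ties) is maximized by
Newton-Raphson on bootstrap resamples of the cohort; features whose
coefficient sign is consistent in at least ``keep_frac`` of resamples form
the signature, with bootstrap-mean coefficients.  Each patient's score is
the linear predictor over standardized log1p expression; the cohort is
split at the median score (ties to the low group) and the two arms are
compared by Kaplan-Meier curves and the log-rank test.

The L2 penalty is scaled by the cohort size (objective
``loglik - n*lambda*||beta||^2 / 2``) so that the fit is invariant under
duplicating every patient -- the natural equivariance for a score that is
later thresholded at the cohort median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    features: list[str]                     # kept features
    coefficients: dict[str, float]          # bootstrap-mean betas for kept features
    candidate_features: list[str]
    means: dict[str, float]                 # of log1p expression
    sds: dict[str, float]
    sign_consistency: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None          # in-sample median score


def _prepare(df: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    X = np.log1p(df[features].to_numpy(dtype=float))
    if (time <= 0).any():
        raise ValueError("non-positive survival times")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return time, event, X


def fit_cox_ridge(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    lam: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Newton-Raphson fit of the L2-penalized Cox model (Breslow ties).

    ``lam`` multiplies ``n`` inside the penalty (see module docstring).
    Raises on fewer than 2 events or non-convergence (with the iteration
    trace in the message).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if event.sum() < 2:
        raise ValueError(f"need >= 2 events, got {int(event.sum())}")
    order = np.argsort(time, kind="stable")
    t, e, Z = time[order], event[order], X[order]
    pen = lam * n

    # positions of distinct event times and their event-row groups
    ev_idx = np.nonzero(e == 1)[0]
    groups: dict[float, list[int]] = {}
    for i in ev_idx:
        groups.setdefault(t[i], []).append(i)
    first_at = {tt: int(np.searchsorted(t, tt, side="left")) for tt in groups}

    def negloglik_grad_hess(beta: np.ndarray):
        eta = Z @ beta
        eta = eta - eta.max()  # stabilise exp; cancels in ratios, shift ll only
        theta = np.exp(eta)
        # reverse cumulative sums over the ordered cohort
        S0 = np.cumsum(theta[::-1])[::-1]
        S1 = np.cumsum((theta[:, None] * Z)[::-1], axis=0)[::-1]
        outer = theta[:, None, None] * (Z[:, :, None] * Z[:, None, :])
        S2 = np.cumsum(outer[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for tt, rows in groups.items():
            i0 = first_at[tt]
            d = len(rows)
            xbar = S1[i0] / S0[i0]
            ll += eta[rows].sum() - d * np.log(S0[i0])
            grad += Z[rows].sum(axis=0) - d * xbar
            hess += d * (S2[i0] / S0[i0] - np.outer(xbar, xbar))
        ll -= 0.5 * pen * beta @ beta
        grad -= pen * beta
        hess += pen * np.eye(p)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = negloglik_grad_hess(beta)
    trace = [ll]
    for _ in range(max_iter):
        step = np.linalg.solve(hess, grad)
        new = beta + step
        new_ll, new_grad, new_hess = negloglik_grad_hess(new)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step /= 2
            new = beta + step
            new_ll, new_grad, new_hess = negloglik_grad_hess(new)
            halvings += 1
        done = abs(new_ll - ll) < tol * (abs(ll) + 1.0)
        beta, ll, grad, hess = new, new_ll, new_grad, new_hess
        trace.append(ll)
        if done:
            return beta
    raise RuntimeError(f"Cox fit did not converge; penalized loglik trace: {trace}")


def bootstrap_signature(
    df: pd.DataFrame,
    features: list[str],
    n_boot: int = 100,
    keep_frac: float = 0.8,
    lam: float = 0.1,
    seed: int = 0,
    ci_level: float = 0.99,
) -> SignatureModel:
    """Bootstrap the penalized Cox fit and keep sign-consistent features.

    A feature enters the signature when its coefficient carries the same
    sign in at least ``keep_frac`` of resamples *and* its ``ci_level``
    bootstrap percentile interval excludes zero (sign consistency alone
    tracks the full-sample noise sign and admits null features far too
    often); its coefficient is the mean over all resamples.  Deterministic
    under a fixed seed.
    """
    time, event, X = _prepare(df, features)
    means, sds = X.mean(axis=0), X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    rng = np.random.default_rng(seed)
    n = len(df)
    betas = np.zeros((n_boot, len(features)))
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if event[idx].sum() >= 2:
                break
        else:
            raise RuntimeError("could not draw a resample with >= 2 events")
        betas[b] = fit_cox_ridge(time[idx], event[idx], Z[idx], lam=lam)
    frac_pos = (betas > 0).mean(axis=0)
    frac_neg = (betas < 0).mean(axis=0)
    consistency = np.maximum(frac_pos, frac_neg)
    alpha = (1.0 - ci_level) / 2
    lo = np.quantile(betas, alpha, axis=0)
    hi = np.quantile(betas, 1 - alpha, axis=0)
    excludes_zero = (lo > 0) | (hi < 0)
    kept = [f for f, c, ex in zip(features, consistency, excludes_zero)
            if c >= keep_frac and ex]
    coefs = {f: float(betas[:, j].mean()) for j, f in enumerate(features) if f in kept}
    model = SignatureModel(
        features=kept, coefficients=coefs, candidate_features=list(features),
        means={f: float(m) for f, m in zip(features, means)},
        sds={f: float(s) for f, s in zip(features, sds)},
        sign_consistency={f: float(c) for f, c in zip(features, consistency)},
    )
    model.threshold = float(np.median(score_patients(model, df))) if kept else None
    return model


def score_patients(model: SignatureModel, df: pd.DataFrame) -> np.ndarray:
    """Per-patient signature score: sum of beta_i * z_i over kept features."""
    if not model.features:
        return np.zeros(len(df))
    score = np.zeros(len(df))
    for f in model.features:
        z = (np.log1p(df[f].to_numpy(dtype=float)) - model.means[f]) / model.sds[f]
        score += model.coefficients[f] * z
    return score


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a table over distinct event times with columns time, n_risk,
    n_events, survival; subjects censored at t remain at risk for the event
    at t but do not count as events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty sample")
    rows = []
    s = 1.0
    for tt in np.unique(times[events == 1]):
        at_risk = int((times >= tt).sum())
        d = int(((times == tt) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append(dict(time=float(tt), n_risk=at_risk, n_events=d, survival=s))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "survival"])


def median_survival(km: pd.DataFrame) -> float | None:
    """First event time at which S(t) drops to 0.5 or below; None if never."""
    hit = km[km.survival <= 0.5]
    return float(hit.time.iloc[0]) if len(hit) else None


def logrank_test(
    times_a: np.ndarray, events_a: np.ndarray, times_b: np.ndarray, events_b: np.ndarray
) -> tuple[float, float]:
    """Standard two-group log-rank test (O-E over event times, df=1)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("empty group in log-rank test")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_E = 0.0
    V = 0.0
    for tt in event_times:
        n1 = int((ta >= tt).sum())
        n2 = int((tb >= tt).sum())
        d1 = int(((ta == tt) & (ea == 1)).sum())
        d2 = int(((tb == tt) & (eb == 1)).sum())
        n, d = n1 + n2, d1 + d2
        if n1 == 0 or n2 == 0 or n <= 1:
            continue
        O_E += d1 - d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = O_E * O_E / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class SignatureEvaluation:
    scores: np.ndarray
    threshold: float
    high_mask: np.ndarray                   # True = high-score group
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    chi2: float
    p: float
    median_low: float | None
    median_high: float | None


def evaluate_signature(model: SignatureModel, df: pd.DataFrame) -> SignatureEvaluation:
    """Median-split the cohort on the signature score and compare arms.

    Ties at the median go to the low group.  Raises when the signature is
    empty or a group ends up empty.
    """
    if not model.features:
        raise ValueError("empty signature: nothing to evaluate")
    scores = score_patients(model, df)
    thr = float(np.median(scores))
    high = scores > thr
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("degenerate median split (all scores tied)")
    t, e, _ = _prepare(df, model.features)
    km_lo = km_estimate(t[~high], e[~high])
    km_hi = km_estimate(t[high], e[high])
    chi2, p = logrank_test(t[~high], e[~high], t[high], e[high])
    return SignatureEvaluation(
        scores=scores, threshold=thr, high_mask=high, km_low=km_lo, km_high=km_hi,
        chi2=chi2, p=p, median_low=median_survival(km_lo), median_high=median_survival(km_hi),
    )
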