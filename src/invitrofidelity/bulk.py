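"""Replicate-free bulk signature derivation.

With a single bulk expression profile per cell line there is no
within-condition variance to estimate, so ordinary count-model DE is
unavailable. Instead, per-gene count differences between the two rounded
profiles are split by sign, the positive and negative magnitude sets are each
fitted to a negative binomial distribution by bounded maximum likelihood
(L-BFGS-B from a method-of-moments start), and a gene is called a line
signature when its difference magnitude exceeds a high quantile of the fitted
null-ish bucket distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import fmin_l_bfgs_b
from sklearn.base import BaseEstimator

from .containers import DataError, GeneSignature, ParameterError

DEFAULT_BOUNDS = ((1e-3, 1e7), (1e-3, 1e6))


@dataclass
class SignedDifferences:
    """Per-gene signed count differences, partitioned by sign."""

    positive: pd.Series  # gene -> magnitude (>= 1)
    negative: pd.Series  # gene -> magnitude (>= 1)
    zeros: frozenset[str]

    def __post_init__(self):
        self.zeros = frozenset(self.zeros)


@dataclass
class NBFit:
    mu: float
    theta: float
    loglik: float
    converged: bool
    n_obs: int
    init: tuple[float, float]
    bounds: tuple = DEFAULT_BOUNDS

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.theta

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "theta": self.theta,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "init": list(self.init),
            "bounds": [list(b) for b in self.bounds],
        }


@dataclass
class SignatureCallConfig:
    quantile_q: float = 0.99
    min_magnitude: int = 0

    def __post_init__(self):
        if not 0 < self.quantile_q < 1:
            raise ParameterError("quantile_q must lie in (0, 1)")
        if self.min_magnitude < 0:
            raise ParameterError("min_magnitude must be non-negative")


def round_profile(raw: pd.Series) -> pd.Series:
    """Half-up rounding to the nearest integer (x.5 -> x+1)."""
    vals = np.asarray(raw.values, dtype=float)
    if (vals < 0).any():
        raise DataError("bulk profile values must be non-negative")
    return pd.Series(np.floor(vals + 0.5).astype(np.int64), index=raw.index)


def signed_difference(profile_a: pd.Series, profile_b: pd.Series) -> SignedDifferences:
    """d_g = A(g) - B(g) on the intersection of the two gene universes."""
    shared = profile_a.index.intersection(profile_b.index)
    if len(shared) == 0:
        raise DataError("the two profiles share no genes")
    d = profile_a.loc[shared].astype(np.int64) - profile_b.loc[shared].astype(np.int64)
    return SignedDifferences(
        positive=d[d > 0],
        negative=(-d[d < 0]),
        zeros=frozenset(shared[d == 0]),
    )


def nb_loglik(values: np.ndarray, mu: float, theta: float) -> float:
    """Sum of log NB(x; mu, theta) with variance mu + mu^2/theta."""
    x = np.asarray(values, dtype=float)
    return float(
        np.sum(
            special.gammaln(x + theta)
            - special.gammaln(theta)
            - special.gammaln(x + 1)
            + theta * np.log(theta / (theta + mu))
            + x * np.log(mu / (theta + mu))
        )
    )


class NegativeBinomialMLE(BaseEstimator):
    """Bounded maximum-likelihood NB fit on a 1-D count sample.

    Optimizes (mu, theta) with L-BFGS-B inside ``bounds`` starting from the
    moment estimates mu0 = mean and theta0 = mu0^2 / (var - mu0) (theta at its
    upper bound when var <= mu, the Poisson-like case).

    Attributes (after fit): ``mu_``, ``theta_``, ``loglik_``, ``converged_``,
    ``fit_`` (the full NBFit record).
    """

    def __init__(self, bounds=DEFAULT_BOUNDS, max_iter: int = 500):
        self.bounds = bounds
        self.max_iter = max_iter

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10:
            raise ParameterError(
                f"need at least 10 observations for a stable NB fit, got {x.size}; "
                "pool buckets or lower the signature threshold instead"
            )
        if (x < 0).any():
            raise DataError("NB observations must be non-negative")
        (mu_lo, mu_hi), (th_lo, th_hi) = self.bounds
        if mu_lo <= 0 or th_lo <= 0:
            raise ParameterError("bounds must be strictly positive")
        m, v = float(x.mean()), float(x.var())
        mu0 = float(np.clip(m, mu_lo, mu_hi))
        theta0 = float(np.clip(mu0**2 / (v - m), th_lo, th_hi)) if v > m else th_hi
        if v <= m:
            warnings.warn("sample variance <= mean; dispersion pinned at its upper bound")

        def neg_ll(params):
            mu, theta = params
            ll = nb_loglik(x, mu, theta)
            # analytic gradient of the negative log-likelihood
            dmu = np.sum(x / mu - (x + theta) / (theta + mu))
            dth = np.sum(
                special.digamma(x + theta)
                - special.digamma(theta)
                + np.log(theta / (theta + mu))
                + 1.0
                - (x + theta) / (theta + mu)
            )
            return -ll, np.array([-dmu, -dth])

        best, f_best, info = fmin_l_bfgs_b(
            neg_ll,
            x0=np.array([mu0, theta0]),
            bounds=[self.bounds[0], self.bounds[1]],
            maxiter=self.max_iter,
        )
        ll_init = nb_loglik(x, mu0, theta0)
        ll_best = -float(f_best)
        if ll_best < ll_init - 1e-9:  # optimizer moved downhill: keep the init
            best = np.array([mu0, theta0])
            ll_best = ll_init
        self.mu_, self.theta_ = float(best[0]), float(best[1])
        self.loglik_ = ll_best
        self.converged_ = info["warnflag"] == 0
        self.fit_ = NBFit(
            mu=self.mu_,
            theta=self.theta_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_obs=int(x.size),
            init=(mu0, theta0),
            bounds=tuple(tuple(b) for b in self.bounds),
        )
        return self


def nb_mle(values, bounds=DEFAULT_BOUNDS, max_iter: int = 500) -> NBFit:
    """Functional wrapper over :class:`NegativeBinomialMLE`."""
    return NegativeBinomialMLE(bounds=bounds, max_iter=max_iter).fit(values).fit_


def nb_quantile(fit: NBFit, q: float) -> int:
    """Smallest integer k with CDF(k) >= q under the fitted NB."""
    if not 0 < q < 1:
        raise ParameterError("q must lie in (0, 1)")
    p = fit.theta / (fit.theta + fit.mu)
    return int(stats.nbinom.ppf(q, fit.theta, p))


def call_bulk_signatures(
    diffs: SignedDifferences,
    fit_pos: NBFit,
    fit_neg: NBFit,
    cfg: SignatureCallConfig | None = None,
) -> tuple[GeneSignature, GeneSignature]:
    """Call line-A-up and line-B-up signatures by quantile exceedance.

    A gene enters line-A-up when its positive-bucket magnitude strictly
    exceeds the ``quantile_q`` quantile of the positive-bucket NB fit and is
    at least ``min_magnitude`` (symmetric for line B). The two sets are
    disjoint by construction.
    """
    cfg = cfg or SignatureCallConfig()
    out = []
    for name, bucket, fit in [
        ("lineA_up", diffs.positive, fit_pos),
        ("lineB_up", diffs.negative, fit_neg),
    ]:
        if bucket.empty:
            warnings.warn(f"empty {name} bucket; signature is empty")
            genes: frozenset[str] = frozenset()
            thr = 0
        else:
            thr = nb_quantile(fit, cfg.quantile_q)
            sel = bucket[(bucket > thr) & (bucket >= cfg.min_magnitude)]
            genes = frozenset(sel.index)
        out.append(
            GeneSignature(
                name=name,
                genes=genes,
                direction="up",
                source="bulk-line",
                thresholds=(cfg.quantile_q, thr, cfg.min_magnitude),
            )
        )
    return out[0], out[1]


def derive_bulk_signatures(
    raw_a: pd.Series,
    raw_b: pd.Series,
    bounds=DEFAULT_BOUNDS,
    cfg: SignatureCallConfig | None = None,
) -> tuple[GeneSignature, GeneSignature, dict]:
    """End-to-end: round -> signed differences -> two NB fits -> calls.

    Returns the two signatures and a report with both fit records.
    """
    a = round_profile(raw_a)
    b = round_profile(raw_b)
    diffs = signed_difference(a, b)
    fit_pos = nb_mle(diffs.positive.values, bounds=bounds)
    fit_neg = nb_mle(diffs.negative.values, bounds=bounds)
    sig_a, sig_b = call_bulk_signatures(diffs, fit_pos, fit_neg, cfg)
    report = {
        "fit_positive": fit_pos.to_dict(),
        "fit_negative": fit_neg.to_dict(),
        "n_zero_differences": len(diffs.zeros),
    }
    return sig_a, sig_b, report
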