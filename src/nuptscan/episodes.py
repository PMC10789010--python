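"""Episodic-age modeling of NUPT percent identities.

Under a molecular clock, percent identity to the extant plastid is a proxy
for time since integration; discrete bursts of plastid-to-nucleus transfer
appear as components of a univariate Gaussian mixture over identity
values. The mixture is fitted by EM; the number of components is chosen by
a sequential parametric-bootstrap likelihood-ratio test (k vs k+1); NUPTs
are assigned to an episode when their maximum posterior clears a
confidence threshold (default 95%), and are otherwise left unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin

from .records import NuptRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianMixture1D",
    "BootstrapDecision",
    "fit_gmm_em",
    "select_k_bootstrap",
    "assign_episodes",
    "summarize_episodes",
    "episode_percentages",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_HALF_LOG_2PI = 0.5 * _LOG_2PI


@njit(cache=False)
def _em_kernel(x, w, mu, sd, max_iter, tol, variance_floor):
    """One EM run on 1-D data; mutates w/mu/sd in place and returns
    (loglik trace, converged flag, iterations used)."""
    n = x.shape[0]
    k = mu.shape[0]
    trace = np.empty(max_iter)
    buf = np.empty(k)
    c = np.empty(k)
    nkv = np.empty(k)
    sx = np.empty(k)
    sxx = np.empty(k)
    ll_prev = -1e308
    converged = False
    it = 0
    for it in range(max_iter):
        for j in range(k):
            c[j] = math.log(w[j]) - math.log(sd[j]) - _HALF_LOG_2PI
            nkv[j] = 0.0
            sx[j] = 0.0
            sxx[j] = 0.0
        ll = 0.0
        for i in range(n):
            xi = x[i]
            mx = -1e308
            for j in range(k):
                z = (xi - mu[j]) / sd[j]
                v = c[j] - 0.5 * z * z
                buf[j] = v
                if v > mx:
                    mx = v
            s = 0.0
            for j in range(k):
                e = math.exp(buf[j] - mx)
                buf[j] = e
                s += e
            ll += mx + math.log(s)
            inv = 1.0 / s
            for j in range(k):
                r = buf[j] * inv
                nkv[j] += r
                sx[j] += r * xi
                sxx[j] += r * xi * xi
        trace[it] = ll
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        for j in range(k):
            nkj = nkv[j] if nkv[j] > 1e-300 else 1e-300
            w[j] = nkj / n
            mu[j] = sx[j] / nkj
            var = sxx[j] / nkj - mu[j] * mu[j]
            if var < 0.0:
                var = 0.0
            sdj = math.sqrt(var)
            sd[j] = sdj if sdj > variance_floor else variance_floor
    return trace[: it + 1], converged, it + 1


class GaussianMixture1D(DensityMixin, BaseEstimator):
    """Univariate Gaussian mixture fitted by EM, sklearn-estimator style.

    Parameters
    ----------
    n_components : number of Gaussian components k.
    max_iter, tol : EM stops when the log-likelihood improves by less than
        ``tol`` (absolute) or after ``max_iter`` iterations.
    n_restarts : number of EM starts; the first uses deterministic quantile
        anchors (means at quantiles (2i-1)/(2k), sds = sample sd, uniform
        weights), the rest jitter the anchors.
    variance_floor : lower bound on component standard deviations,
        preventing collapse onto duplicated values (ties at 100% identity
        are common in real data).
    random_state : seed or Generator for the restart jitter.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, sds_ : component parameters, sorted by mean.
    loglik_ : total data log-likelihood of the best start.
    loglik_trace_ : per-iteration log-likelihood of the best start
        (non-decreasing by construction of EM).
    converged_, n_iter_, n_ : convergence flag, iterations used, sample size.
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 2000,
        tol: float = 1e-10,
        n_restarts: int = 20,
        variance_floor: float = 1e-3,
        random_state=None,
        init_means=None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.variance_floor = variance_floor
        self.random_state = random_state
        self.init_means = init_means

    # -- internals -----------------------------------------------------

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a 1-D array (or column vector) of values")
        if not np.all(np.isfinite(x)):
            raise ValueError("values must be finite")
        return x

    def _log_resp(self, x, w, mu, sd):
        z = (x[:, None] - mu[None, :]) / sd[None, :]
        log_comp = np.log(w)[None, :] - np.log(sd)[None, :] - 0.5 * (z * z + _LOG_2PI)
        norm = logsumexp(log_comp, axis=1)
        return log_comp - norm[:, None], float(norm.sum())

    def _em_once(self, x, w0, mu0, sd0, max_iter, tol):
        w = np.array(w0, dtype=float)
        mu = np.array(mu0, dtype=float)
        sd = np.array(sd0, dtype=float)
        trace, converged, it = _em_kernel(
            x, w, mu, sd, max_iter, tol, self.variance_floor
        )
        if np.any(np.diff(trace) < -1e-8):
            raise RuntimeError("EM log-likelihood decreased")
        return w, mu, sd, list(trace), converged, it

    # -- sklearn API ---------------------------------------------------

    def fit(self, X, y=None):
        x = self._as_1d(X)
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if len(x) < 5 * k:
            raise ValueError(f"need at least {5 * k} observations to fit k={k}")
        if np.ptp(x) == 0:
            raise ValueError("all values identical: zero-variance input")
        rng = np.random.default_rng(self.random_state) if not isinstance(
            self.random_state, np.random.Generator
        ) else self.random_state

        if k == 1:
            # EM fixed point in closed form
            mu = float(np.mean(x))
            sd = max(float(np.std(x)), self.variance_floor)
            self.weights_ = np.array([1.0])
            self.means_ = np.array([mu])
            self.sds_ = np.array([sd])
            _, ll = self._log_resp(x, self.weights_, self.means_, self.sds_)
            self.loglik_ = ll
            self.loglik_trace_ = [ll]
            self.converged_ = True
            self.n_iter_ = 1
            self.n_ = len(x)
            return self

        anchors = np.quantile(x, (2 * np.arange(k) + 1) / (2 * k))
        spread = max(float(np.std(x)), self.variance_floor)
        starts: list[np.ndarray] = []
        if self.init_means is not None:
            extra = np.asarray(self.init_means, dtype=float)
            if len(extra) != k:
                raise ValueError("init_means must have length n_components")
            starts.append(np.sort(extra))
        starts.append(anchors)
        while len(starts) < max(1, self.n_restarts) + (self.init_means is not None):
            starts.append(np.sort(anchors + rng.normal(0.0, spread / 2.0, size=k)))

        # two-phase search: short scouting runs per start, then polish the
        # best one to full convergence (warm-started, trace concatenated)
        w0 = np.full(k, 1.0 / k)
        sd0 = np.full(k, spread)
        scout_iter = min(self.max_iter, 150)
        scout_tol = max(self.tol, 1e-8)
        best = None
        for mu0 in starts:
            res = self._em_once(x, w0, mu0, sd0, scout_iter, scout_tol)
            if best is None or res[3][-1] > best[3][-1]:
                best = res
        w, mu, sd, trace, converged, it = best
        budget = self.max_iter - it
        if budget > 0 and not (converged and self.tol >= scout_tol):
            w, mu, sd, trace2, converged, it2 = self._em_once(
                x, w, mu, sd, budget, self.tol
            )
            # the first polish iteration re-evaluates the last scout point
            trace = trace + trace2[1:]
            it = it + it2
        order = np.argsort(mu)
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sds_ = sd[order]
        self.loglik_ = trace[-1]
        self.loglik_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = it
        self.n_ = len(x)
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = self._as_1d(X)
        log_r, _ = self._log_resp(x, self.weights_, self.means_, self.sds_)
        return np.exp(log_r)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X) -> np.ndarray:
        x = self._as_1d(X)
        z = (x[:, None] - self.means_[None, :]) / self.sds_[None, :]
        log_comp = (
            np.log(self.weights_)[None, :]
            - np.log(self.sds_)[None, :]
            - 0.5 * (z * z + _LOG_2PI)
        )
        return logsumexp(log_comp, axis=1)

    def score(self, X, y=None) -> float:
        return float(np.mean(self.score_samples(X)))

    def sample(self, n: int, random_state=None) -> np.ndarray:
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        comp = rng.choice(len(self.weights_), size=n, p=self.weights_)
        return rng.normal(self.means_[comp], self.sds_[comp])

    def to_dict(self) -> dict:
        return {
            "k": int(len(self.means_)),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "sds": self.sds_.tolist(),
            "loglik": self.loglik_,
            "n": int(self.n_),
            "converged": bool(self.converged_),
        }


def fit_gmm_em(
    x,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-10,
    n_restarts: int = 20,
    variance_floor: float = 1e-3,
    rng=None,
) -> GaussianMixture1D:
    """Fit a k-component univariate Gaussian mixture by EM (best of restarts)."""
    return GaussianMixture1D(
        n_components=k, max_iter=max_iter, tol=tol, n_restarts=n_restarts,
        variance_floor=variance_floor, random_state=rng,
    ).fit(x)


def _sample_batch(
    model: GaussianMixture1D, B: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """B parametric-bootstrap datasets of size n from a fitted mixture."""
    cumw = np.cumsum(model.weights_)
    idx = np.searchsorted(cumw, rng.random((B, n)))
    idx = np.minimum(idx, len(cumw) - 1)
    return rng.normal(model.means_[idx], model.sds_[idx])


def _loglik_k1(x: np.ndarray, variance_floor: float) -> float:
    """Closed-form maximum log-likelihood of a single Gaussian (EM fixed point)."""
    n = len(x)
    sd = max(float(np.std(x)), variance_floor)
    return -0.5 * n * _LOG_2PI - n * math.log(sd) - 0.5 * n


def _boot_loglik(
    xb: np.ndarray, w0, mu0, sd0, variance_floor: float, max_iter: int, tol: float
) -> float:
    w = np.array(w0, dtype=float)
    mu = np.array(mu0, dtype=float)
    sd = np.array(sd0, dtype=float)
    trace, _, _ = _em_kernel(xb, w, mu, sd, max_iter, tol, variance_floor)
    return float(trace[-1])


@dataclass
class BootstrapDecision:
    """One k vs k+1 parametric-bootstrap likelihood-ratio test."""

    tested_k: int
    lrt_stat: float
    boot_stats: list[float]
    p_value: float
    alpha: float
    B: int

    def to_dict(self) -> dict:
        return {
            "tested_k": self.tested_k,
            "lrt_stat": self.lrt_stat,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "B": self.B,
            "boot_stats": [round(b, 6) for b in self.boot_stats],
        }


def select_k_bootstrap(
    x,
    k_max: int = 9,
    B: int = 1000,
    alpha: float = 0.01,
    rng=None,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-10,
    variance_floor: float = 1e-3,
    boot_max_iter: int = 200,
    boot_tol: float = 1e-6,
) -> tuple[int, list[BootstrapDecision]]:
    """Choose the component count by sequential parametric-bootstrap LRT.

    For k = 1, 2, ...: fit k and k+1, form the statistic 2*(ll_{k+1} -
    ll_k) clipped at zero, simulate B datasets from the k-component fit,
    refit both models on each, and compute p = (1 + #{boot >= observed}) /
    (B + 1). Stop at the first k with p >= alpha, or at k_max. Bootstrap
    refits are warm-started (the k-fit at the generating parameters, the
    (k+1)-fit at a split of the dominant component) with lighter EM
    controls: they only need the null distribution of the statistic, and
    the warm starts keep that null calibrated against fully-optimized
    reference fits.
    """
    x = GaussianMixture1D._as_1d(x)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = len(x)

    def full_fit(data, k):
        return fit_gmm_em(
            data, k, max_iter=max_iter, tol=tol, n_restarts=n_restarts,
            variance_floor=variance_floor, rng=rng,
        )

    def split_init(model: GaussianMixture1D) -> np.ndarray:
        # warm start for the (k+1)-fit on data generated from the k-model:
        # split the dominant component into two half-sd-offset means
        j = int(np.argmax(model.weights_ * model.sds_))
        mu = model.means_
        return np.concatenate(
            [mu[:j], [mu[j] - model.sds_[j] / 2, mu[j] + model.sds_[j] / 2], mu[j + 1:]]
        )

    decisions: list[BootstrapDecision] = []
    fits: dict[int, GaussianMixture1D] = {}
    k = 1
    while k < k_max:
        if alpha >= 1.0:
            # a significance level of 1 never splits: every p "passes"
            break
        if n < 5 * (k + 1):
            logger.warning("sample too small to test k=%d vs %d; stopping", k, k + 1)
            break
        if k not in fits:
            fits[k] = full_fit(x, k)
        fits[k + 1] = full_fit(x, k + 1)
        lrt = max(0.0, 2.0 * (fits[k + 1].loglik_ - fits[k].loglik_))
        warm1 = split_init(fits[k])
        w1 = np.full(k + 1, 1.0 / (k + 1))
        boot_stats: list[float] = []
        Xb = _sample_batch(fits[k], B, n, rng)
        for b in range(B):
            xb = Xb[b]
            if k == 1:
                ll0 = _loglik_k1(xb, variance_floor)
            else:
                ll0 = _boot_loglik(
                    xb, fits[k].weights_, fits[k].means_, fits[k].sds_,
                    variance_floor, boot_max_iter, boot_tol,
                )
            sd_init = np.full(k + 1, max(float(np.std(xb)), variance_floor))
            ll1 = _boot_loglik(
                xb, w1, warm1, sd_init, variance_floor, boot_max_iter, boot_tol
            )
            boot_stats.append(max(0.0, 2.0 * (ll1 - ll0)))
        p = float((1 + sum(b >= lrt for b in boot_stats)) / (B + 1))
        decisions.append(
            BootstrapDecision(
                tested_k=k, lrt_stat=lrt, boot_stats=boot_stats,
                p_value=p, alpha=alpha, B=B,
            )
        )
        logger.info("bootstrap LRT k=%d vs %d: stat=%.2f p=%.4f", k, k + 1, lrt, p)
        if p >= alpha:
            return k, decisions
        k += 1
    return k, decisions


def _component_labels(k: int) -> list[str]:
    if k == 2:
        return ["I", "II"]
    return [f"component_{i + 1}" for i in range(k)]


def assign_episodes(
    records: list[NuptRecord],
    model: GaussianMixture1D,
    threshold: float = 0.95,
) -> list[NuptRecord]:
    """Label each NUPT by its maximum-posterior component.

    A record is assigned only when the maximum posterior reaches
    ``threshold``; otherwise it is labelled ``unassigned``. For a
    two-component model the lower-mean (older) component is episode I and
    the higher-mean (younger) one episode II.
    """
    if not records:
        return records
    labels = _component_labels(len(model.means_))
    post = model.predict_proba([r.pident for r in records])
    argmax = np.argmax(post, axis=1)
    for i, rec in enumerate(records):
        rec.posterior = [float(p) for p in post[i]]
        rec.episode = (
            labels[argmax[i]] if post[i, argmax[i]] >= threshold else "unassigned"
        )
    return records


def episode_percentages(
    counts: dict[str, int], bp: dict[str, int]
) -> pd.DataFrame:
    """Per-episode shares of the total NUPT count and total NUPT bp.

    The denominators are the sums over all classes supplied (including
    ``unassigned``), mirroring how whole-genome episode summaries are
    reported.
    """
    episodes = list(counts)
    total_n = sum(counts.values())
    total_bp = sum(bp.get(e, 0) for e in episodes)
    rows = []
    for e in episodes:
        rows.append(
            {
                "episode": e,
                "n": counts[e],
                "pct_n": 100.0 * counts[e] / total_n if total_n else float("nan"),
                "bp": bp.get(e, 0),
                "pct_bp": 100.0 * bp.get(e, 0) / total_bp if total_bp else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def summarize_episodes(records: list[NuptRecord]) -> pd.DataFrame:
    """Per-episode counts, bp and size/identity ranges over all records."""
    if not records:
        return pd.DataFrame(
            columns=[
                "episode", "n", "pct_n", "bp", "pct_bp", "size_min", "size_max",
                "size_mean", "size_median", "pident_min", "pident_max",
            ]
        )
    df = pd.DataFrame(
        {
            "episode": [r.episode for r in records],
            "size": [r.aln_length for r in records],
            "pident": [r.pident for r in records],
        }
    )
    counts = df.groupby("episode")["size"].count().to_dict()
    bp = df.groupby("episode")["size"].sum().to_dict()
    pct = episode_percentages(counts, {k: int(v) for k, v in bp.items()})
    stats = df.groupby("episode").agg(
        size_min=("size", "min"), size_max=("size", "max"),
        size_mean=("size", "mean"), size_median=("size", "median"),
        pident_min=("pident", "min"), pident_max=("pident", "max"),
    ).reset_index()
    out = pct.merge(stats, on="episode")
    order = {lab: i for i, lab in enumerate(["I", "II"])}
    out["_o"] = out["episode"].map(lambda e: order.get(e, 98 if e != "unassigned" else 99))
    return out.sort_values("_o").drop(columns="_o").reset_index(drop=True)
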