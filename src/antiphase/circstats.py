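"""Circular statistics for call-onset phases.

Descriptive resultant-vector summaries, the Rayleigh test of uniformity,
maximum-likelihood von Mises fitting with bootstrap confidence intervals, the
Mardia-Watson-Wheeler uniform-scores test, and Rao's homogeneity tests for
mean directions and dispersions, plus Bonferroni adjustment and phase
histograms.

Angles are radians in [0, 2*pi).  The mean direction is

    alpha_bar = atan2(sum sin(a_j), sum cos(a_j)),

the resultant length R is the norm of the summed unit vectors, the mean
resultant r_bar = R / n lies in [0, 1], and angular dispersion is n - R.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

TWO_PI = 2 * np.pi
KAPPA_CAP = 500.0


def _as_angles(alpha) -> np.ndarray:
    a = np.asarray(alpha, dtype=np.float64)
    if a.ndim != 1:
        a = a.ravel()
    return np.mod(a, TWO_PI)


@dataclass(frozen=True)
class CircularSummary:
    n: int
    mean_direction: float  # radians; NaN when undefined (R ~ 0)
    resultant_length: float  # R, unnormalized
    mean_resultant: float  # r_bar = R / n in [0, 1]
    angular_dispersion: float  # n - R
    mean_defined: bool


@dataclass(frozen=True)
class VonMisesFit:
    mu: float
    kappa: float
    log_likelihood: float
    kappa_capped: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    mu: np.ndarray  # replicate mean directions
    kappa: np.ndarray  # replicate concentrations
    n_boot: int
    seed: int
    mu_ci: tuple[float, float]
    kappa_ci: tuple[float, float]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: float | None
    n: int
    p_value: float
    p_adjusted: float | None = None
    extra: dict | None = None


def circ_summary(alpha) -> CircularSummary:
    """Resultant-vector summary of a circular sample."""
    a = _as_angles(alpha)
    n = len(a)
    if n == 0:
        raise ValueError("empty sample")
    s, c = np.sin(a).sum(), np.cos(a).sum()
    R = float(np.hypot(s, c))
    defined = R > 1e-9 * n
    mean = float(np.mod(np.arctan2(s, c), TWO_PI)) if defined else float("nan")
    return CircularSummary(
        n=n,
        mean_direction=mean,
        resultant_length=R,
        mean_resultant=R / n,
        angular_dispersion=n - R,
        mean_defined=defined,
    )


def rayleigh_test(alpha) -> TestResult:
    """Rayleigh test of circular uniformity against a unimodal alternative.

    Z = n * r_bar**2; the p-value uses the standard asymptotic series with
    finite-n correction, accurate down to small samples.
    """
    a = _as_angles(alpha)
    n = len(a)
    summ = circ_summary(a)
    R = summ.resultant_length
    z = R**2 / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return TestResult(
        test_name="rayleigh",
        statistic=float(z),
        df=None,
        n=n,
        p_value=float(min(max(p, 0.0), 1.0)),
        extra={"r_bar": summ.mean_resultant},
    )


def _A1(kappa):
    # ratio I1(k)/I0(k), overflow-safe
    return special.i1e(kappa) / special.i0e(kappa)


def _A1inv(r: float) -> float:
    # series / rational initialization for Newton (Fisher 1993)
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def vm_mle(alpha) -> VonMisesFit:
    """Maximum-likelihood von Mises fit: mu = mean direction, A(kappa) = r_bar.

    kappa is found by Newton iteration on A(kappa) = I1/I0 and capped at
    ``KAPPA_CAP`` (flagged) when the sample is (nearly) degenerate.
    """
    a = _as_angles(alpha)
    n = len(a)
    if n < 2:
        raise ValueError("von Mises MLE needs at least 2 observations")
    summ = circ_summary(a)
    r = summ.mean_resultant
    mu = summ.mean_direction if summ.mean_defined else 0.0
    capped = False
    if r <= 1e-12:
        kappa = 0.0
    else:
        kappa = _A1inv(min(r, 1 - 1e-12))
        for _ in range(50):
            A = _A1(kappa)
            dA = 1 - A / kappa - A**2 if kappa > 1e-8 else 0.5
            step = (A - r) / dA
            kappa -= step
            if kappa < 0:
                kappa = 0.0
                break
            if abs(step) < 1e-12 * max(1.0, kappa):
                break
        if not np.isfinite(kappa) or kappa > KAPPA_CAP:
            kappa, capped = KAPPA_CAP, True
    # log-likelihood: sum kappa*cos(a - mu) - n*log(2*pi*I0(kappa))
    log_i0 = np.log(special.i0e(kappa)) + kappa
    ll = float(kappa * np.cos(a - mu).sum() - n * (np.log(TWO_PI) + log_i0))
    return VonMisesFit(mu=float(mu), kappa=float(kappa), log_likelihood=ll,
                       kappa_capped=capped)


def bootstrap_vm(alpha, n_boot: int = 1000, seed: int = 0) -> BootstrapResult:
    """Bootstrap the von Mises MLE: ``n_boot`` resamplings with replacement.

    The 95% CI for mu is taken on replicates recentred around the point
    estimate (wrapped to (-pi, pi]) to avoid artifacts at the 0/2*pi seam.
    """
    a = _as_angles(alpha)
    n = len(a)
    rng = np.random.default_rng(seed)
    point = vm_mle(a)
    mus = np.empty(n_boot)
    kappas = np.empty(n_boot)
    for b in range(n_boot):
        fit = vm_mle(a[rng.integers(0, n, size=n)])
        mus[b] = fit.mu
        kappas[b] = fit.kappa
    centered = np.mod(mus - point.mu + np.pi, TWO_PI) - np.pi
    lo, hi = np.percentile(centered, [2.5, 97.5])
    mu_ci = (float(np.mod(point.mu + lo, TWO_PI)), float(np.mod(point.mu + hi, TWO_PI)))
    k_lo, k_hi = np.percentile(kappas, [2.5, 97.5])
    return BootstrapResult(
        mu=mus, kappa=kappas, n_boot=n_boot, seed=seed,
        mu_ci=mu_ci, kappa_ci=(float(k_lo), float(k_hi)),
    )


def _uniform_scores(samples):
    pooled = np.concatenate([_as_angles(s) for s in samples])
    ranks = stats.rankdata(pooled, method="average")
    beta = TWO_PI * ranks / len(pooled)
    out, i = [], 0
    for s in samples:
        out.append(beta[i : i + len(s)])
        i += len(s)
    return out


def _mww_statistic(score_groups, n_total):
    W = 0.0
    for b in score_groups:
        W += (np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2) / len(b)
    return 2.0 * W


def mww_test(*samples, n_perm: int = 9999, seed: int = 0) -> TestResult:
    """Mardia-Watson-Wheeler uniform-scores test for k circular samples.

    Pooled angles are replaced by their uniform scores (2*pi*rank/N, average
    ranks on ties); the statistic is chi-square with 2(k-1) df asymptotically.
    When any group has fewer than 10 observations, the p-value is computed by
    a seeded permutation of group labels instead.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    groups = [_as_angles(s) for s in samples]
    sizes = [len(g) for g in groups]
    N = sum(sizes)
    scores = _uniform_scores(groups)
    W = _mww_statistic(scores, N)
    df = 2 * (len(groups) - 1)
    if min(sizes) >= 10:
        p = float(stats.chi2.sf(W, df))
        method = "chi2"
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(scores)
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            perm_groups, i = [], 0
            for m in sizes:
                perm_groups.append(pooled[i : i + m])
                i += m
            if _mww_statistic(perm_groups, N) >= W - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = "permutation"
    return TestResult(
        test_name="mardia_watson_wheeler", statistic=float(W), df=df, n=N,
        p_value=p, extra={"method": method, "group_sizes": sizes},
    )


def _group_moments(a):
    n = len(a)
    c, s = np.cos(a), np.sin(a)
    cb, sb = c.mean(), s.mean()
    # variances/covariance of the *means*
    vcc = c.var(ddof=1) / n
    vss = s.var(ddof=1) / n
    vcs = np.cov(c, s, ddof=1)[0, 1] / n
    return n, cb, sb, vcc, vss, vcs


def _weighted_chi2(values, variances):
    w = 1.0 / np.asarray(variances)
    v = np.asarray(values)
    stat = float((w * v**2).sum() - (w * v).sum() ** 2 / w.sum())
    return stat


def rao_homogeneity(*samples) -> tuple[TestResult, TestResult]:
    """Rao's homogeneity tests: equality of mean directions and of dispersions.

    Both are delta-method chi-square tests with k-1 df: the means test
    compares the tangents of the group mean directions (after rotating all
    groups by the pooled mean direction, which makes the statistic exactly
    rotation-invariant); the dispersion test compares the group mean
    resultant lengths.  Returns (means_test, dispersions_test).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    groups = [_as_angles(s) for s in samples]
    N = sum(len(g) for g in groups)
    pooled_mean = circ_summary(np.concatenate(groups)).mean_direction
    if not np.isfinite(pooled_mean):
        pooled_mean = 0.0
    rotated = [np.mod(g - pooled_mean, TWO_PI) for g in groups]

    tangents, t_vars, rbars, r_vars = [], [], [], []
    for g in rotated:
        n, cb, sb, vcc, vss, vcs = _group_moments(g)
        if abs(cb) < 1e-12:
            raise ValueError("group mean direction orthogonal to pooled mean; "
                             "tangent statistic undefined")
        tangents.append(sb / cb)
        t_vars.append((sb**2 * vcc - 2 * cb * sb * vcs + cb**2 * vss) / cb**4)
        r = np.hypot(cb, sb)
        rbars.append(r)
        r_vars.append((cb**2 * vcc + 2 * cb * sb * vcs + sb**2 * vss) / r**2)

    k = len(groups)
    h_means = _weighted_chi2(tangents, t_vars)
    h_disp = _weighted_chi2(rbars, r_vars)
    means = TestResult(
        test_name="rao_homogeneity_means", statistic=h_means, df=k - 1, n=N,
        p_value=float(stats.chi2.sf(h_means, k - 1)),
    )
    disp = TestResult(
        test_name="rao_homogeneity_dispersions", statistic=h_disp, df=k - 1, n=N,
        p_value=float(stats.chi2.sf(h_disp, k - 1)),
    )
    return means, disp


def rao_homogeneity_posthoc(samples: dict) -> pd.DataFrame:
    """Pairwise Rao homogeneity tests over all C(k, 2) pairs, Bonferroni-adjusted."""
    pairs = list(itertools.combinations(sorted(samples), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        means, disp = rao_homogeneity(samples[a], samples[b])
        rows.append(
            {
                "group_a": a, "group_b": b,
                "means_stat": means.statistic, "means_p": means.p_value,
                "means_p_adj": bonferroni(means.p_value, m),
                "disp_stat": disp.statistic, "disp_p": disp.p_value,
                "disp_p_adj": bonferroni(disp.p_value, m),
            }
        )
    return pd.DataFrame(rows)


def bonferroni(p, m: int):
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p, dtype=np.float64)
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


def phase_histogram(alpha, n_bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Circular density histogram over [0, 2*pi): (bin_edges, densities sum to 1)."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    a = _as_angles(alpha)
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    total = counts.sum()
    dens = counts / total if total > 0 else counts.astype(float)
    return edges, dens


def time_histogram(alpha, rate_hz: float, bin_ms: float = 1.0):
    """Linear within-cycle histogram of onset times (default 1 ms bins).

    Phases are mapped to time within the cycle (period 1000 / rate_hz ms);
    densities sum to 1.
    """
    a = _as_angles(alpha)
    period_ms = 1000.0 / rate_hz
    t = a / TWO_PI * period_ms
    n_bins = max(2, int(np.ceil(period_ms / bin_ms)))
    edges = np.linspace(0.0, period_ms, n_bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    total = counts.sum()
    dens = counts / total if total > 0 else counts.astype(float)
    return edges, dens


def sample_von_mises(mu: float, kappa: float, n: int, seed: int) -> np.ndarray:
    """Seeded von Mises sample in [0, 2*pi) (uniform when kappa = 0)."""
    rng = np.random.default_rng(seed)
    if kappa == 0:
        return rng.uniform(0.0, TWO_PI, size=n)
    return np.mod(rng.vonmises(mu, kappa, size=n), TWO_PI)
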