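"""Negative binomial models of per-block call counts.

Calls are counted per experimental block (group x recording day x playback
condition) and modelled with a log-link NB-2 regression on playback
condition, with the silent baseline as reference level:

    ln(E[n_i]) = Intercept + B_1 * I(condition = c_1) + B_2 * I(condition = c_2) ...

Exponentiated coefficients are incidence-rate ratios (IRRs) against the
silent baseline.  A likelihood-ratio ANOVA tests the condition factor as a
whole; marginal-mean contrasts compare predicted calling rates between
pairs of conditions with Bonferroni adjustment.

Blocks of unequal duration are handled by an optional log-exposure offset
(needed e.g. to compare per-rate call counts in the random-masker condition,
where each rate's exposure is its total cycle-occupancy time).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class NBFit:
    """A fitted NB-2 count model with IRRs against the baseline condition."""

    coef_table: pd.DataFrame  # term, B, SEB, z, p, irr, irr_lo, irr_hi
    alpha: float  # NB-2 dispersion parameter (variance = mu + alpha * mu**2)
    dispersion_statistic: float  # Pearson chi2 / df_resid; ~1 when well specified
    log_likelihood: float
    conditions: list
    reference: str
    _endog: np.ndarray
    _exog: np.ndarray
    _offset: np.ndarray | None
    _cov: np.ndarray

    @property
    def irr(self) -> pd.Series:
        t = self.coef_table.set_index("term")
        return t.loc[t.index != "Intercept", "irr"]


def _design(table: pd.DataFrame, condition_col: str, reference: str):
    conds = list(pd.unique(table[condition_col]))
    if reference not in conds:
        raise ValueError(f"reference level {reference!r} not among {conds}")
    others = [c for c in conds if c != reference]
    X = np.column_stack(
        [np.ones(len(table))]
        + [(table[condition_col] == c).to_numpy(float) for c in others]
    )
    names = ["Intercept"] + [f"condition[{c}]" for c in others]
    return X, names, [reference] + others


def fit_nb(
    table: pd.DataFrame,
    count_col: str = "n_calls",
    condition_col: str = "playback_condition",
    reference: str = "silent",
    exposure_col: str | None = None,
) -> NBFit:
    """Fit the NB-2 condition model to a count table.

    ``exposure_col`` (block durations) adds a log-exposure offset; omit it
    for equal-duration blocks.  Zero-count conditions (perfect separation on
    the log scale) trigger a documented fallback: a half-count is added to
    every block of such conditions, with a warning.
    """
    y = table[count_col].to_numpy(dtype=np.float64)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X, names, conds = _design(table, condition_col, reference)
    offset = None
    if exposure_col is not None:
        exp_t = table[exposure_col].to_numpy(dtype=np.float64)
        if np.any(exp_t <= 0):
            raise ValueError("exposure must be positive")
        offset = np.log(exp_t)
    for c in conds:
        if y[(table[condition_col] == c).to_numpy()].sum() == 0:
            import warnings

            warnings.warn(
                f"condition {c!r} has zero total counts; adding 1/2 to its "
                "blocks to keep the log-link estimable", stacklevel=2
            )
            y = y + 0.5 * (table[condition_col] == c).to_numpy(float)
    model = sm.NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    res = model.fit(disp=0, maxiter=200)
    k = X.shape[1]
    B = res.params[:k]
    SE = res.bse[:k]
    alpha = float(res.params[k])
    ci = res.conf_int()
    z = B / SE
    p = 2 * stats.norm.sf(np.abs(z))
    coef_table = pd.DataFrame(
        {
            "term": names,
            "B": B,
            "SEB": SE,
            "z": z,
            "p": p,
            "irr": np.exp(B),
            "irr_lo": np.exp(ci[:k, 0]),
            "irr_hi": np.exp(ci[:k, 1]),
        }
    )
    mu = res.predict()
    var = mu + alpha * mu**2
    df_resid = len(y) - k
    pearson = float(np.sum((y - mu) ** 2 / var) / df_resid) if df_resid > 0 else np.nan
    return NBFit(
        coef_table=coef_table,
        alpha=alpha,
        dispersion_statistic=pearson,
        log_likelihood=float(res.llf),
        conditions=conds,
        reference=reference,
        _endog=y,
        _exog=X,
        _offset=offset,
        _cov=np.asarray(res.cov_params())[:k, :k],
    )


def lr_anova(fit: NBFit) -> dict:
    """Likelihood-ratio test of the condition factor (vs intercept-only).

    Both models are evaluated as NB GLMs at the full model's dispersion, the
    standard partial-LRT construction for a single factor: chi2 = 2 * delta
    log-likelihood with df = n_conditions - 1.
    """
    fam = sm.families.NegativeBinomial(alpha=fit.alpha)
    kw = {"offset": fit._offset} if fit._offset is not None else {}
    full = sm.GLM(fit._endog, fit._exog, family=fam, **kw).fit()
    null = sm.GLM(fit._endog, np.ones((len(fit._endog), 1)), family=fam, **kw).fit()
    chi2 = 2.0 * (full.llf - null.llf)
    df = fit._exog.shape[1] - 1
    return {
        "test_name": "lr_anova_condition",
        "statistic": float(chi2),
        "df": df,
        "p_value": float(stats.chi2.sf(chi2, df)),
    }


def emmeans_contrasts(fit: NBFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means per condition and pairwise contrasts.

    Means are linear predictor values per condition (delta-method SEs from
    the coefficient covariance), reported on the response scale as predicted
    calling rates.  Pairwise differences are z-tested and Bonferroni-adjusted
    over all C(k, 2) pairs.
    """
    k = fit._exog.shape[1]
    conds = fit.conditions
    # row i of L maps coefficients -> linear predictor of condition i
    L = np.zeros((len(conds), k))
    L[:, 0] = 1.0
    for i in range(1, len(conds)):
        L[i, i] = 1.0
    eta = L @ fit.coef_table["B"].to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit._cov, L))
    means = pd.DataFrame(
        {
            "condition": conds,
            "log_mean": eta,
            "se": se,
            "predicted_rate": np.exp(eta),
            "rate_lo": np.exp(eta - 1.96 * se),
            "rate_hi": np.exp(eta + 1.96 * se),
        }
    )
    pairs = list(itertools.combinations(range(len(conds)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        d = L[i] - L[j]
        diff = float(d @ fit.coef_table["B"].to_numpy())
        sed = float(np.sqrt(d @ fit._cov @ d))
        z = diff / sed if sed > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z)) if sed > 0 else 1.0
        rows.append(
            {
                "contrast": f"{conds[i]} - {conds[j]}",
                "log_ratio": diff,
                "se": sed,
                "z": z,
                "p": p,
                "p_adj": min(1.0, m * p),
                "rate_ratio": np.exp(diff),
            }
        )
    return means, pd.DataFrame(rows)


def rate_exposures(cycle_sequence) -> pd.DataFrame:
    """Total occupancy time per modulation rate in a cycle sequence.

    In the random-masker condition each rate is on air only while its cycles
    play; fair per-rate comparisons need these durations as exposures.
    """
    df = cycle_sequence.to_frame()
    out = (
        df.assign(duration_s=df["end_s"] - df["start_s"])
        .groupby("rate_hz", as_index=False)["duration_s"]
        .sum()
        .rename(columns={"duration_s": "exposure_s"})
    )
    return out
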