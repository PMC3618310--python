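"""Moderated-t differential expression with fixed fold-change/FDR cutoffs.

One linear model (a one-way layout over the strain x pH conditions) is fit
per gene on the normalized log10 scale. Per-gene residual variances s_g^2
with d_g = n - k degrees of freedom are shrunk toward a global prior
(s_0^2, d_0) estimated across genes by an empirical-Bayes method-of-moments
fit on log s_g^2 — under the hierarchical model s_g^2 ~ s_0^2 F(d_g, d_0),
the mean and variance of log s_g^2 identify both hyperparameters. The
moderated statistic for a two-condition contrast is

    t_g = (mean_a - mean_b) / sqrt(s~_g^2 (1/n_a + 1/n_b)),
    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),

on d_0 + d_g degrees of freedom. A gene is called up when its linear fold
change is >= 2 and the Benjamini-Hochberg adjusted P < 0.05 (down:
FC <= 1/2), the cutoffs used throughout this pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleMetadata, ValidationError

VARIANCE_FLOOR = 1e-12


@dataclass
class ModeratedModel:
    """Per-gene condition means and (moderated) variance components."""

    means: pd.DataFrame          # genes x conditions
    s2: pd.Series                # per-gene pooled residual variance
    df_residual: int             # d_g (same for every gene in a balanced fit)
    n_per_condition: dict[str, int]
    d0: float | None = None      # prior df (inf allowed)
    s02: float | None = None     # prior variance

    @property
    def prior_estimated(self) -> bool:
        return self.d0 is not None and self.s02 is not None


def fit_condition_means(
    m: ExpressionMatrix | pd.DataFrame,
    meta: SampleMetadata,
) -> ModeratedModel:
    """Condition means and pooled residual variance per gene.

    The residual variance pools within-condition scatter over *all*
    conditions, so d_g = n_samples - n_conditions (8 for the full
    2 strains x 2 pH x 3 replicates design).
    """
    if isinstance(m, ExpressionMatrix):
        values = m.gene_values()
    else:
        values = m
    cond_samples = meta.condition_samples()
    cond_samples = {c: [s for s in ss if s in values.columns] for c, ss in cond_samples.items()}
    cond_samples = {c: ss for c, ss in cond_samples.items() if ss}
    n_total = sum(len(ss) for ss in cond_samples.values())
    k = len(cond_samples)
    for cond, ss in cond_samples.items():
        if len(ss) < 2:
            raise ValidationError(f"condition {cond} has {len(ss)} replicate(s); >= 2 required")
    df_resid = n_total - k
    means = {}
    rss = np.zeros(len(values))
    for cond, ss in cond_samples.items():
        block = values[ss]
        mu = block.mean(axis=1)
        means[cond] = mu
        rss += ((block.sub(mu, axis=0)) ** 2).sum(axis=1).to_numpy()
    s2 = pd.Series(rss / df_resid, index=values.index, name="s2")
    return ModeratedModel(
        means=pd.DataFrame(means),
        s2=s2,
        df_residual=df_resid,
        n_per_condition={c: len(ss) for c, ss in cond_samples.items()},
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def estimate_prior(s2: pd.Series | np.ndarray, d_g: int) -> tuple[float, float]:
    """Empirical-Bayes hyperparameters (d0, s0^2) from per-gene variances.

    Moment fit on z = log s_g^2: under s_g^2 ~ s0^2 F(d_g, d0),

        E z   = log s0^2 + [psi(d_g/2) - log(d_g/2)] - [psi(d0/2) - log(d0/2)]
        Var z = trigamma(d_g/2) + trigamma(d0/2).

    When the sample variance of z does not exceed the chi-square
    contribution trigamma(d_g/2), the prior is effectively infinitely
    informative and d0 = inf is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    s2 = np.maximum(s2, VARIANCE_FLOOR)
    if len(s2) < 50:
        raise ValidationError(f"need >= 50 genes with positive variance, got {len(s2)}")
    if d_g < 1:
        raise ValidationError("residual df must be >= 1")
    z = np.log(s2)
    mean_z = float(z.mean())
    var_z = float(z.var(ddof=1))
    if var_z < 1e-15:  # all variances identical: the common value is exact
        return math.inf, float(np.exp(mean_z))
    e_chi = special.digamma(d_g / 2.0) - math.log(d_g / 2.0)
    excess = var_z - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        return math.inf, float(math.exp(mean_z - e_chi))
    d0 = 2.0 * _trigamma_inverse(excess)
    e_inv_chi = special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    s02 = float(math.exp(mean_z - e_chi + e_inv_chi))
    return d0, s02


def with_prior(model: ModeratedModel, d0: float | None = None, s02: float | None = None) -> ModeratedModel:
    """Attach a prior: estimate it from the data unless given explicitly."""
    if d0 is None or s02 is None:
        d0_est, s02_est = estimate_prior(model.s2, model.df_residual)
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02
    model.d0 = float(d0)
    model.s02 = float(s02)
    return model


def moderated_t(model: ModeratedModel, contrast: tuple[str, str]) -> pd.DataFrame:
    """Per-gene moderated t, df, and two-sided P for condition_a - condition_b."""
    if not model.prior_estimated:
        raise ValidationError("prior not estimated; call with_prior() first")
    ca, cb = contrast
    for c in (ca, cb):
        if c not in model.means.columns:
            raise ValidationError(f"unknown condition {c!r}; have {list(model.means.columns)}")
    d0, s02, dg = model.d0, model.s02, model.df_residual
    s2 = np.maximum(model.s2.to_numpy(), VARIANCE_FLOOR)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    na, nb = model.n_per_condition[ca], model.n_per_condition[cb]
    delta = (model.means[ca] - model.means[cb]).to_numpy()
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = delta / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"log10_fc": delta, "t": t, "df": df_total, "pvalue": p},
        index=model.means.index,
    )


def adjust_bh(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(result: pd.DataFrame, fc_cut: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Add fold change, adjusted P and up/down/ns calls to a contrast table."""
    out = result.copy()
    out["fc"] = np.power(10.0, out["log10_fc"])
    if "adj_pvalue" not in out.columns:
        out["adj_pvalue"] = adjust_bh(out["pvalue"])
    sig = out["adj_pvalue"] < alpha
    call = np.where(sig & (out["fc"] >= fc_cut), "up",
                    np.where(sig & (out["fc"] <= 1.0 / fc_cut), "down", "ns"))
    out["call"] = call
    return out


def run_contrast(
    model: ModeratedModel,
    contrast: tuple[str, str],
    fc_cut: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t + BH + calls for one condition pair."""
    return call_de(moderated_t(model, contrast), fc_cut=fc_cut, alpha=alpha)


@dataclass
class TrendlineFit:
    """Least-squares trendline of one condition's means on another's."""

    slope: float
    intercept: float
    residual_sd: float
    residuals: pd.Series
    outliers: pd.Series  # |residual| > 2 * residual SD

    @property
    def n_outliers(self) -> int:
        return int(self.outliers.sum())


def trendline_outliers(x: pd.Series, y: pd.Series, sd_limit: float = 2.0) -> TrendlineFit:
    """Fit y ~ x over genes; flag residuals beyond ``sd_limit`` residual SDs.

    This is the scatter-plot view of a two-condition comparison: genes off
    the trendline respond to treatment beyond random fluctuation.
    """
    x, y = x.align(y, join="inner")
    if len(x) < 3:
        raise ValidationError("need >= 3 genes for a trendline fit")
    xv = x.to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValidationError("constant x values; trendline undefined")
    slope, intercept = np.polyfit(xv, y.to_numpy(dtype=float), 1)
    resid = y - (slope * x + intercept)
    sd = float(resid.std(ddof=2))
    # an exact fit leaves only float rounding; nothing is an outlier then
    tol = 1e-10 * max(1.0, float(np.abs(y.to_numpy()).max()))
    outliers = resid.abs() > sd_limit * sd if sd > tol else resid.abs() > np.inf
    return TrendlineFit(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=sd,
        residuals=resid,
        outliers=outliers,
    )
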