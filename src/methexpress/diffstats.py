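"""Filtering, transformation and per-feature differential statistics.

The same machinery serves methylation (beta values, tested on the
logit/M scale, effects reported as delta-beta = adult − fetal on the
beta scale) and expression (log2 intensities, effects reported as the
fetal − adult log2 ratio and as a signed fold change).

The moderated t-statistic shrinks per-feature sample variances toward a
pooled prior fitted by method of moments on the log variances: if the
per-feature variance s² follows s0²·F(df, d0) under the hierarchical
scaled-inverse-chi-square model, then

    E[log s²] = log s0² + ψ(df/2) − log(df/2) − ψ(d0/2) + log(d0/2)
    Var[log s²] = ψ'(df/2) + ψ'(d0/2)

so d0 is recovered by inverting the trigamma function ψ' and s0² from
the mean. The posterior variance  (d0·s0² + df·s²)/(d0 + df)  replaces
s² in the t-statistic, which then has df + d0 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ValidationError
from .io_formats import group_samples, normalize_chromosome

SEX_CHROMOSOMES = frozenset({"X", "Y"})


# ---------------------------------------------------------------------------
# filtering


def filter_detection(beta: pd.DataFrame, detp: pd.DataFrame,
                     threshold: float = 0.05):
    """Retain probes whose detection p-value is below ``threshold`` in
    every sample. Returns ``(filtered_beta, n_removed)``."""
    if beta.shape != detp.shape or list(beta.index) != list(detp.index) \
            or list(beta.columns) != list(detp.columns):
        raise ValidationError(
            "beta and detection-p matrices must share shape and ids "
            f"(beta {beta.shape}, detection-p {detp.shape})"
        )
    keep = (detp.to_numpy() < threshold).all(axis=1)
    return beta.loc[keep], int((~keep).sum())


def filter_sex_chromosomes(beta: pd.DataFrame, annot: pd.DataFrame):
    """Drop probes annotated to chromosome X or Y.

    Chromosome labels are normalized ('chrX' == 'X') before comparison.
    Returns ``(filtered_beta, n_removed)``.
    """
    missing = [p for p in beta.index if p not in annot.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} probe(s) missing from annotation, e.g. "
            f"{missing[:5]}"
        )
    chrom = annot.loc[beta.index, "CHR"].map(normalize_chromosome)
    keep = ~chrom.isin(SEX_CHROMOSOMES)
    return beta.loc[keep.to_numpy()], int((~keep).sum())


# ---------------------------------------------------------------------------
# transformation


def logit_transform(beta, offset: float = 1e-6):
    """M-value transform: M = log2((β + offset) / (1 − β + offset)).

    The offset keeps the transform finite at β = 0 and β = 1. Accepts a
    DataFrame or array; NaN propagates.
    """
    if offset < 0:
        raise ValidationError(f"offset must be non-negative, got {offset}")
    arr = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore"):
        m = np.log2((arr + offset) / (1.0 - arr + offset))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


# ---------------------------------------------------------------------------
# per-feature two-group model


def fit_group_model(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-feature ordinary least squares for the two-group design.

    Missing values are excluded pairwise (per feature, per group). With
    numeric covariates in the design, features containing missing values
    are rejected, and each feature is fit against the full design matrix
    [intercept, adult indicator, covariates]; the reported effect is the
    adult − fetal coefficient.

    Returns a frame indexed like ``matrix`` with columns: mean_fetal,
    mean_adult, effect, var_fetal, var_adult, s2 (pooled residual
    variance), df (residual degrees of freedom), leverage (the variance
    multiplier of the contrast), zero_variance (flag).
    """
    groups = group_samples(design)
    fetal, adult = groups["fetal"], groups["adult"]
    for s in list(fetal) + list(adult):
        if s not in matrix.columns:
            raise ValidationError(f"design sample {s!r} absent from matrix")
    covars = [c for c in design.columns if c not in ("sample_id", "group")]

    xf = matrix[fetal].to_numpy(dtype=float)
    xa = matrix[adult].to_numpy(dtype=float)

    if covars:
        return _fit_with_covariates(matrix, design, fetal, adult, covars)

    nf = np.sum(~np.isnan(xf), axis=1)
    na = np.sum(~np.isnan(xa), axis=1)
    if (nf < 2).any() or (na < 2).any():
        bad = matrix.index[(nf < 2) | (na < 2)][:5].tolist()
        raise ValidationError(
            f"feature(s) with <2 non-missing values in a group: {bad}"
        )
    with np.errstate(invalid="ignore"):
        mf = np.nanmean(xf, axis=1)
        ma = np.nanmean(xa, axis=1)
        vf = np.nanvar(xf, axis=1, ddof=1)
        va = np.nanvar(xa, axis=1, ddof=1)
    df = nf + na - 2
    s2 = ((nf - 1) * vf + (na - 1) * va) / df
    leverage = 1.0 / nf + 1.0 / na
    return pd.DataFrame(
        {
            "mean_fetal": mf,
            "mean_adult": ma,
            "effect": ma - mf,
            "var_fetal": vf,
            "var_adult": va,
            "s2": s2,
            "df": df.astype(float),
            "leverage": leverage,
            "zero_variance": s2 == 0.0,
        },
        index=matrix.index,
    )


def _fit_with_covariates(matrix, design, fetal, adult, covars):
    cols = list(fetal) + list(adult)
    y = matrix[cols].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError(
            "missing values are not supported together with covariates"
        )
    n = len(cols)
    adult_ind = np.array([0.0] * len(fetal) + [1.0] * len(adult))
    covar_mat = design.loc[cols, covars].to_numpy(dtype=float)
    x = np.column_stack([np.ones(n), adult_ind, covar_mat])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValidationError(
            f"rank-deficient design matrix (rank {rank} < {x.shape[1]})"
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = y @ x @ xtx_inv.T           # features x params
    resid = y - coef @ x.T
    df = n - x.shape[1]
    if df < 1:
        raise ValidationError("no residual degrees of freedom")
    s2 = np.sum(resid**2, axis=1) / df
    leverage = xtx_inv[1, 1]
    mf = y[:, : len(fetal)].mean(axis=1)
    ma = y[:, len(fetal):].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_fetal": mf,
            "mean_adult": ma,
            "effect": coef[:, 1],
            "var_fetal": matrix[fetal].var(axis=1, ddof=1),
            "var_adult": matrix[adult].var(axis=1, ddof=1),
            "s2": s2,
            "df": float(df),
            "leverage": leverage,
            "zero_variance": s2 == 0.0,
        },
        index=matrix.index,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


@dataclass
class ModerationEstimate:
    """Fitted variance prior: d0 (prior df, may be inf), s20 (prior
    variance) and the per-feature posterior variances."""

    d0: float
    s20: float
    posterior: np.ndarray

    @property
    def infinite_prior(self) -> bool:
        return np.isinf(self.d0)


def trigamma_inverse(x: float) -> float:
    """Solve ψ'(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2, df) -> ModerationEstimate:
    """Fit the variance prior (d0, s0²) by method of moments on log
    sample variances and return posterior variances.

    Zero variances are excluded from estimation (log 0 breaks the
    moment match) and assigned the prior variance s0² as posterior.
    When the spread of log variances does not exceed the chi-square
    sampling floor, d0 is flagged infinite and s0² is the geometric
    mean of the positive variances, so that all-equal inputs return
    posterior == the common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    if (s2 < 0).any():
        raise ValidationError("negative sample variance")
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError(
            f"need at least 2 features with positive variance, got {ok.sum()}"
        )
    z = np.log(s2[ok])
    dfk = df[ok]
    e = z - special.digamma(dfk / 2.0) + np.log(dfk / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    rhs = evar - np.mean(special.polygamma(1, dfk / 2.0))
    if rhs > 0:
        d0 = 2.0 * trigamma_inverse(rhs)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s20 = float(np.exp(z.mean()))
    if np.isinf(d0):
        posterior = np.full_like(s2, s20)
    else:
        posterior = (d0 * s20 + df * s2) / (d0 + df)
        posterior[~ok] = s20
    return ModerationEstimate(d0=float(d0), s20=s20, posterior=posterior)


def moderated_test(effects, posterior_var, leverage, df, d0):
    """Moderated t-test: t = effect / sqrt(posterior · leverage), p from
    the t distribution with df + d0 degrees of freedom (normal when the
    prior df is infinite). Returns ``(t, p)`` arrays."""
    effects = np.asarray(effects, dtype=float)
    posterior_var = np.asarray(posterior_var, dtype=float)
    leverage = np.broadcast_to(np.asarray(leverage, dtype=float), effects.shape)
    df = np.broadcast_to(np.asarray(df, dtype=float), effects.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effects / np.sqrt(posterior_var * leverage)
    t = np.where(effects == 0.0, 0.0, t)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    return t, p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q for the feature with the i-th smallest p is
    min_{j >= i} m·p_(j)/j, capped at 1 (the cumulative-minimum
    formulation, which handles ties and preserves the p ordering).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D array")
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][:3]
        raise ValidationError(f"p-values outside [0,1]: {bad}")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(qs, 1.0)
    return q


def signed_fold_change(fetal_log2, adult_log2):
    """Signed expression ratio: +r when fetal is higher (r = 2^(fetal −
    adult) ≥ 1), −1/r when adult is higher; magnitude always ≥ 1."""
    r = np.power(2.0, np.asarray(fetal_log2, dtype=float)
                 - np.asarray(adult_log2, dtype=float))
    return np.where(r >= 1.0, r, -1.0 / r)


# ---------------------------------------------------------------------------
# high-level differential tables


def differential_methylation(beta: pd.DataFrame, design: pd.DataFrame,
                             offset: float = 1e-6,
                             moderation: bool = True) -> pd.DataFrame:
    """Full differential-methylation table.

    Testing happens on M-values (base-2 logit with ``offset``); group
    means, delta-beta (adult − fetal) and the per-group variances are
    reported on the beta scale. Columns: mean_fetal, mean_adult,
    delta_beta, var_fetal, var_adult, t, p, q.
    """
    fit_m = fit_group_model(logit_transform(beta, offset), design)
    fit_b = fit_group_model(beta, design)
    t, p = _run_test(fit_m, moderation)
    out = pd.DataFrame(
        {
            "mean_fetal": fit_b["mean_fetal"],
            "mean_adult": fit_b["mean_adult"],
            "delta_beta": fit_b["mean_adult"] - fit_b["mean_fetal"],
            "var_fetal": fit_b["var_fetal"],
            "var_adult": fit_b["var_adult"],
            "t": t,
            "p": p,
        },
        index=beta.index,
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def differential_expression(expr: pd.DataFrame, design: pd.DataFrame,
                            moderation: bool = True) -> pd.DataFrame:
    """Full differential-expression table on log2 intensities.

    ``log2_ratio`` is fetal − adult; ``fold_change`` is the signed
    ratio (+r fetal higher, −r adult higher, |r| ≥ 1). Columns:
    mean_fetal, mean_adult, log2_ratio, fold_change, var_fetal,
    var_adult, t, p, q.
    """
    fit = fit_group_model(expr, design)
    t, p = _run_test(fit, moderation)
    log2_ratio = fit["mean_fetal"] - fit["mean_adult"]
    out = pd.DataFrame(
        {
            "mean_fetal": fit["mean_fetal"],
            "mean_adult": fit["mean_adult"],
            "log2_ratio": log2_ratio,
            "fold_change": signed_fold_change(fit["mean_fetal"],
                                              fit["mean_adult"]),
            "var_fetal": fit["var_fetal"],
            "var_adult": fit["var_adult"],
            "t": t,
            "p": p,
        },
        index=expr.index,
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _run_test(fit: pd.DataFrame, moderation: bool):
    s2 = fit["s2"].to_numpy()
    df = fit["df"].to_numpy()
    if moderation:
        est = moderate_variances(s2, df)
        post, d0 = est.posterior, est.d0
    else:
        post, d0 = s2, 0.0
    return moderated_test(fit["effect"].to_numpy(), post,
                          fit["leverage"].to_numpy(), df, d0)


# ---------------------------------------------------------------------------
# summaries


def variance_summary(beta: pd.DataFrame, design: pd.DataFrame,
                     cutoff: float = 0.01) -> pd.DataFrame:
    """Per-group mean of per-CpG sample variances (n−1 denominator) and
    the fraction of CpGs with variance below ``cutoff``."""
    groups = group_samples(design)
    rows = []
    for grp, samples in groups.items():
        v = beta[samples].var(axis=1, ddof=1).to_numpy()
        v = v[~np.isnan(v)]
        rows.append(
            {
                "group": grp,
                "mean_variance": float(v.mean()),
                f"fraction_lt_{cutoff:g}": float((v < cutoff).mean()),
                "n_cpgs": int(len(v)),
            }
        )
    return pd.DataFrame(rows)


def beta_histograms(values, bin_width: float = 0.05,
                    value_range: tuple[float, float] = (0.0, 1.0)):
    """Histogram with left-closed right-open bins (the last bin closed).

    Returns ``(edges, counts)``; counts sum to the input length. Values
    outside ``value_range`` raise."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    lo, hi = value_range
    if len(values) and ((values < lo) | (values > hi)).any():
        bad = values[(values < lo) | (values > hi)][0]
        raise ValidationError(f"value {bad} outside range [{lo}, {hi}]")
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    edges[-1] = hi
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
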