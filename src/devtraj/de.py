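"""Minimal negative-binomial differential-expression engine and normalization.

The engine mirrors the interface of a standard NB Wald workflow: per-sample
size factors by median-of-ratios, a per-gene NB Wald test between two groups
of samples with a moment estimate of the dispersion, Benjamini-Hochberg
adjustment within the comparison, and a conversion of adjusted p-values to
signed Z-scores (upper-tail normal quantile, signed by direction of change).

Any externally produced differential-expression table with the same columns
(``log2fc``, ``pvalue``, ``padj``, ``z``) can be used as a drop-in
replacement downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Cap on |Z| used when adjusted p-values underflow to zero.
Z_CAP = 38.0

#: Pseudo-count (in normalized-count units) used for fold changes and Wald
#: standard errors so that groups with zero counts stay finite.
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEResult:
    """Result of one two-group comparison.

    ``table`` is indexed by gene with columns ``base_mean_a``,
    ``base_mean_b``, ``log2fc``, ``pvalue``, ``padj``, ``z`` and ``tested``.
    ``log2fc`` (and hence the sign of ``z``) measures the change of group B
    relative to group A, i.e. positive means higher in B.
    """

    comparison: str
    group_a: str
    group_b: str
    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def comparison_label(group_a: str, group_b: str) -> str:
    return f"{group_a}_vs_{group_b}"


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def estimate_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one positive scalar per sample/column).

    Ratios are taken against the per-gene geometric mean over samples, and
    the median is computed over genes with nonzero counts in *all* samples.
    Factors are scale-equivariant up to a common rescaling (the
    geometric-mean reference scales with the data).
    If no such gene exists, a fallback uses, per sample, the genes that are
    nonzero in that sample (geometric means over positive entries only).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be a 2-D matrix (genes x samples)")
    if x.shape[0] == 0 or x.shape[1] == 0 or not np.any(x > 0):
        raise ValueError("cannot estimate size factors from an all-zero matrix")
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    all_positive = np.all(x > 0, axis=1)
    if np.any(all_positive):
        log_gm = logx[all_positive].mean(axis=1)
        factors = np.exp(np.median(logx[all_positive] - log_gm[:, None], axis=0))
    else:
        warnings.warn(
            "no gene has nonzero counts in every sample; "
            "falling back to positive-count geometric means",
            RuntimeWarning,
            stacklevel=2,
        )
        npos = (x > 0).sum(axis=1)
        usable = npos > 0
        log_gm = np.full(x.shape[0], np.nan)
        log_gm[usable] = np.where(x[usable] > 0, logx[usable], 0.0).sum(axis=1) / npos[usable]
        factors = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            ok = usable & (x[:, j] > 0)
            if not np.any(ok):
                raise ValueError(f"sample column {j} has no usable counts")
            factors[j] = np.exp(np.median(logx[ok, j] - log_gm[ok]))
    return factors


def p_to_signed_z(p, direction):
    """Convert (adjusted) p-values to signed Z-scores.

    Z = direction * Phi^{-1}(1 - p), i.e. the upper-tail standard-normal
    quantile of p signed by the direction of regulation, so that p = 2.87e-7
    maps to |Z| = 5 and p = 0.5 maps to Z = 0.  The magnitude is capped at
    ``Z_CAP`` (p-value underflow) and floored at 0 (p > 0.5 carries no
    directional significance), so sign(Z) always agrees with ``direction``
    or is zero.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    d_arr = np.broadcast_to(np.atleast_1d(np.asarray(direction, dtype=float)), p_arr.shape)
    if np.any(p_arr > 1.0) or np.any(p_arr < 0.0) or np.any(np.isnan(p_arr)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p_arr == 0.0):
        warnings.warn(
            f"p-value underflow: capping |Z| at {Z_CAP}", RuntimeWarning, stacklevel=2
        )
    with np.errstate(over="ignore"):
        magnitude = stats.norm.isf(p_arr)
    magnitude = np.clip(magnitude, 0.0, Z_CAP)
    z = np.sign(d_arr) * magnitude
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(z[0])
    return z


def nb_wald_test(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    size_factors: pd.Series | np.ndarray | None = None,
    *,
    comparison: str | None = None,
    group_a: str = "A",
    group_b: str = "B",
    pseudocount: float = PSEUDOCOUNT,
    min_nonzero_samples: int = 2,
    dispersion_prior_df: float = 20.0,
) -> DEResult:
    """NB Wald test of group B versus group A, per gene.

    Counts are normalized by ``size_factors`` (estimated on the provided
    columns when omitted).  The per-gene NB dispersion (variance =
    mu + alpha * mu^2) is moment-estimated from the within-group variances,
    pooled across the two groups, then shrunk toward the median dispersion
    over all tested genes with ``dispersion_prior_df`` pseudo-degrees of
    freedom (small replicate numbers would otherwise give the Wald
    statistic heavy t-like tails).  The Wald statistic compares the log
    normalized group means with a delta-method standard error; raw p-values
    are two-sided normal, adjusted with Benjamini-Hochberg within this
    comparison, and the signed Z is derived from the adjusted p-value via
    :func:`p_to_signed_z` using the sign of the fold change.

    Genes with fewer than ``min_nonzero_samples`` nonzero counts across the
    two groups are flagged (``tested = False``) and reported with
    log2fc = 0, p = 1 rather than dropped.
    """
    samples_a = list(samples_a)
    samples_b = list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"each compared group needs >= 2 samples "
            f"(got {len(samples_a)} vs {len(samples_b)})"
        )
    sub = counts[samples_a + samples_b]
    x = sub.to_numpy(dtype=float)
    if size_factors is None:
        sf = estimate_size_factors(x)
    else:
        if isinstance(size_factors, pd.Series):
            sf = size_factors.loc[samples_a + samples_b].to_numpy(dtype=float)
        else:
            sf = np.asarray(size_factors, dtype=float)
        if sf.shape != (x.shape[1],):
            raise ValueError("size_factors must provide one value per sample")
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")

    na, nb = len(samples_a), len(samples_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    y = x / sf
    ya, yb = y[:, idx_a], y[:, idx_b]
    mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)

    # Moment estimate of dispersion, pooled over groups.  For normalized
    # counts Var(K/s) ~= mu * (1/s) + alpha * mu^2; subtract the Poisson
    # part using the group-mean reciprocal size factor.
    inv_a = float(np.mean(1.0 / sf[idx_a]))
    inv_b = float(np.mean(1.0 / sf[idx_b]))
    num = (na - 1) * (va - mu_a * inv_a) + (nb - 1) * (vb - mu_b * inv_b)
    den = (na - 1) * mu_a**2 + (nb - 1) * mu_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.clip(alpha, 0.0, None)

    # Empirical-Bayes style shrinkage toward the across-gene mean (the mean
    # of the moment estimator is unbiased where the median is not).
    df_gene = na + nb - 2
    expressed = (mu_a > 0) | (mu_b > 0)
    trend = float(np.mean(alpha[expressed])) if np.any(expressed) else 0.0
    alpha = (df_gene * alpha + dispersion_prior_df * trend) / (
        df_gene + dispersion_prior_df
    )

    ma = mu_a + pseudocount
    mb = mu_b + pseudocount
    log2fc = np.log2(mb) - np.log2(ma)
    var_log_a = (inv_a / ma + alpha) / na
    var_log_b = (inv_b / mb + alpha) / nb
    se = np.sqrt(var_log_a + var_log_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (np.log(mb) - np.log(ma)) / se
    wald = np.where(np.isfinite(wald), wald, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))

    nonzero = (x > 0).sum(axis=1)
    tested = nonzero >= min_nonzero_samples
    pvalue = np.where(tested, pvalue, 1.0)
    log2fc = np.where(tested, log2fc, 0.0)

    padj = np.ones_like(pvalue)
    if np.any(tested):
        padj[tested] = benjamini_hochberg(pvalue[tested])
    direction = np.where(log2fc < 0, -1.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = p_to_signed_z(padj, direction)

    table = pd.DataFrame(
        {
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "z": z,
            "tested": tested,
        },
        index=counts.index,
    )
    label = comparison if comparison is not None else comparison_label(group_a, group_b)
    return DEResult(comparison=label, group_a=group_a, group_b=group_b, table=table)


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:5])
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    ls = np.asarray(library_sizes, dtype=float)
    if np.any(ls <= 0):
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths.to_numpy(dtype=float) / 1e3, ls / 1e6)
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / denom, index=counts.index, columns=counts.columns
    )


def umi_normalize(
    counts: pd.DataFrame, scale: float | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Library-size normalization of UMI counts.

    Each cell is rescaled so its total equals ``scale`` (default: the median
    cell total).  Cells with zero totals are dropped with a warning.
    Returns the normalized matrix and the per-cell size factors
    (total / scale), which can be fed to :func:`nb_wald_test`.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    totals = counts.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = list(totals.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} cells with zero total counts",
            RuntimeWarning,
            stacklevel=2,
        )
        counts = counts.loc[:, keep]
        totals = totals[keep]
    if counts.shape[1] == 0:
        raise ValueError("no cells with positive totals")
    if scale is None:
        scale = float(np.median(totals.to_numpy()))
    factors = totals / scale
    normalized = counts / factors
    return normalized, factors
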