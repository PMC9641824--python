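"""Bias-corrected differential abundance across phyla and genera.

Observed counts confound true abundances with unknown per-sample sampling
fractions (library-size/efficiency effects).  The estimator here alternates
(i) per-taxon least-squares regressions of log counts on the covariate given
current sample offsets with (ii) offset updates as the per-sample median
residual across taxa, until the offsets stabilize.  The per-taxon W
statistic is the covariate coefficient over its standard error; selection
uses a Benjamini-Hochberg q-value threshold combined with a percentile cut
on |W| within the tested taxon set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class DaConfig:
    prevalence_min: float = 0.10
    q_threshold: float = 0.01
    w_percentile: float = 0.85
    pseudocount: float = 1.0
    max_iter: int = 500
    tol: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("prevalence_min", "q_threshold", "w_percentile"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def aggregate_rank(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> tuple[pd.DataFrame, list[str]]:
    """Sum counts within a taxonomic rank; unresolved-at-rank taxa dropped."""
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} absent from taxonomy")
    labels = taxonomy.loc[counts.columns, rank]
    unresolved = labels.isna() | (labels.astype(str).str.strip() == "")
    dropped = list(labels.index[unresolved])
    kept = counts.loc[:, ~unresolved.to_numpy()]
    agg = kept.T.groupby(labels[~unresolved]).sum().T
    agg.columns.name = rank
    return agg, dropped


def prevalence_filter(counts: pd.DataFrame, min_prevalence: float = 0.10) -> pd.DataFrame:
    """Keep taxa present in strictly more than ``min_prevalence`` of samples."""
    prev = (counts > 0).mean(axis=0)
    return counts.loc[:, prev > min_prevalence]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def ancombc_fit(counts: pd.DataFrame, covariate, config: DaConfig | None = None) -> pd.DataFrame:
    """Bias-corrected per-taxon regression of log abundance on one covariate.

    ``covariate`` is numeric or a two-level factor (coded 0/1 against the
    first level encountered).  Positive log-fold change means abundance
    increases with the covariate (or is higher in the second level).
    """
    config = config or DaConfig()
    cov = pd.Series(list(covariate))
    if len(cov) != len(counts):
        raise ValueError("covariate length must match samples")
    if len(counts) < 8:
        raise ValueError("need at least 8 samples")
    if pd.api.types.is_numeric_dtype(cov):
        x1 = cov.to_numpy(dtype=float)
    else:
        levels = list(pd.unique(cov))
        if len(levels) != 2:
            raise ValueError("factor covariate must have exactly two levels")
        x1 = (cov == levels[1]).to_numpy(dtype=float)
    if np.ptp(x1) == 0:
        raise ValueError("constant covariate: W undefined for every taxon")
    y = np.log(counts.to_numpy(dtype=float) + config.pseudocount)  # samples x taxa
    n, t = y.shape
    x = np.column_stack([np.ones(n), x1])
    pinv = np.linalg.pinv(x)
    offsets = np.zeros(n)
    # Alternate (i) per-taxon regressions given offsets with (ii) an offset
    # update combining the per-sample median residual with the across-taxon
    # median of the fitted coefficients.  The coefficient median is the
    # consensus shift a sampling-fraction artifact would induce in every
    # taxon; moving it into the offsets is the bias correction, and leaves
    # per-taxon coefficients measuring deviation from that consensus.
    for _ in range(config.max_iter):
        beta = pinv @ (y - offsets[:, None])  # 2 x T
        med_beta = np.median(beta, axis=1)
        beta = beta - med_beta[:, None]
        resid = y - offsets[:, None] - x @ (beta + med_beta[:, None])
        m = np.median(resid, axis=1)
        change = x @ med_beta + m
        offsets = offsets + change
        offsets = offsets - offsets.mean()  # pin offsets to mean zero
        delta = float(np.max(np.abs(change - change.mean())))
        if delta < config.tol:
            break
    else:
        raise RuntimeError(f"offset iteration did not converge (last offset delta {delta:.3g})")
    yc = y - offsets[:, None]
    beta = pinv @ yc
    resid = yc - x @ beta
    dof = n - 2
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(se > 0, beta[1] / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(w))
    q = bh_adjust(p)
    w_cut = np.nanquantile(np.abs(w), config.w_percentile)
    selected = (q < config.q_threshold) & (np.abs(w) >= w_cut)
    return pd.DataFrame(
        {
            "taxon": counts.columns,
            "lfc": beta[1],
            "se": se,
            "W": w,
            "p": p,
            "q": q,
            "selected": selected,
        }
    ).set_index("taxon")


def differential_abundance(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    covariate,
    rank: str = "Genus",
    config: DaConfig | None = None,
) -> pd.DataFrame:
    """Aggregate to a rank, apply the prevalence filter, fit, and select."""
    config = config or DaConfig()
    agg, _ = aggregate_rank(counts, taxonomy, rank)
    agg = prevalence_filter(agg, config.prevalence_min)
    return ancombc_fit(agg, covariate, config)
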