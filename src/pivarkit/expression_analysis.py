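"""Normalization, differential expression and strain-variance models.

Size factors follow the median-of-ratios scheme; expression values for
linear modelling are log2(normalized + 1).  Pairwise differential
expression uses a negative-binomial Wald test with moment-based dispersion.
Per-cluster strain effects are one-way fixed-effect ANOVA; the global
strain effect is a linear mixed model with a random cluster intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CountMatrix, SampleTable

__all__ = [
    "NormalizationFactors",
    "DEResult",
    "VarianceExplainedResult",
    "GlobalModelResult",
    "size_factors",
    "transform_counts",
    "pairwise_de",
    "summarize_de",
    "strain_variance_explained",
    "global_strain_effect",
    "adjust_bh",
]


@dataclass
class NormalizationFactors:
    factors: dict[str, float]

    def __post_init__(self):
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("size factors must be positive")

    def as_array(self, sample_ids) -> np.ndarray:
        return np.array([self.factors[s] for s in sample_ids])


@dataclass
class DEResult:
    cluster_id: str
    comparison: tuple  # (strain_a, strain_b, tissue)
    log2fc: float
    p: float
    padj: float
    significant: bool


@dataclass
class VarianceExplainedResult:
    cluster_id: str
    r2_adj: float
    p: float
    padj: float
    undefined: bool = False


@dataclass
class GlobalModelResult:
    strain_p: float
    cluster_variance: float
    residual_variance: float
    strain_coefficients: dict
    singular: bool = False


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def size_factors(counts: CountMatrix, fallback_total_count: bool = False) -> NormalizationFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Rows with a zero in any sample are excluded from the reference
    (their log-geometric mean is -inf).  If no row is positive everywhere,
    either raise or (with ``fallback_total_count``) use library totals.
    """
    mat = counts.counts.astype(float)
    with np.errstate(divide="ignore"):
        log_rows = np.log(mat)
    finite = np.isfinite(log_rows).all(axis=1)
    if not finite.any():
        if not fallback_total_count:
            raise ValueError(
                "no cluster has nonzero counts in every sample; "
                "re-run with fallback_total_count=True to use library totals"
            )
        raw = mat.sum(axis=0)
        if (raw <= 0).any():
            raise ValueError("sample with zero total count")
    else:
        geomean = np.exp(log_rows[finite].mean(axis=1))
        ratios = mat[finite] / geomean[:, None]
        raw = np.median(ratios, axis=0)
    raw = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(dict(zip(counts.sample_ids, raw)))


def transform_counts(counts: CountMatrix, factors: NormalizationFactors) -> pd.DataFrame:
    """log2(count / size_factor + 1), clusters x samples."""
    f = factors.as_array(counts.sample_ids)
    mat = np.log2(counts.counts / f[None, :] + 1.0)
    return pd.DataFrame(mat, index=counts.cluster_ids, columns=counts.sample_ids)


def _nb_dispersion(
    norm: np.ndarray, groups: np.ndarray, floor: float = 0.01, prior_df: float = 6.0
) -> tuple[np.ndarray, float]:
    """Moderated moment estimate of NB dispersion alpha (Var = mu + alpha mu^2).

    Per-cluster moment estimates from pooled within-group residual variance
    are squeezed toward the across-cluster median with ``prior_df``
    pseudo-observations (limma-style moderation: at 2-3 samples per group
    the raw estimate has too few df to be used alone).  Returns the
    moderated alphas and the total df (residual + prior) for the
    t reference of the Wald statistic.
    """
    n_clusters = norm.shape[0]
    mu = np.zeros(n_clusters)
    ss = np.zeros(n_clusters)
    dof = 0
    for g in np.unique(groups):
        cols = groups == g
        n_g = cols.sum()
        gm = norm[:, cols].mean(axis=1)
        ss += ((norm[:, cols] - gm[:, None]) ** 2).sum(axis=1)
        mu += gm * n_g
        dof += n_g - 1
    mu /= len(groups)
    var = ss / max(1, dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.maximum(alpha, 0.0)
    prior = float(np.median(alpha))
    alpha = (dof * alpha + prior_df * prior) / (dof + prior_df)
    return np.maximum(alpha, floor), dof + prior_df


def pairwise_de(
    counts: CountMatrix,
    samples: SampleTable,
    strain_a: str,
    strain_b: str,
    tissue: str | None = None,
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
    factors: NormalizationFactors | None = None,
) -> list[DEResult]:
    """Negative-binomial Wald test of strain_b vs strain_a per cluster.

    log2 fold changes are computed on size-factor-normalized group means
    (strain_b over strain_a); the Wald statistic uses a delta-method
    standard error from the NB variance with moment-based dispersion.
    A cluster is significant iff |log2fc| > lfc_threshold and BH-adjusted
    p < fdr.
    """
    ids_a = samples.samples_for(strain_a, tissue)
    ids_b = samples.samples_for(strain_b, tissue)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("pairwise_de needs at least two samples per strain")
    used = [s for s in counts.sample_ids if s in set(ids_a) | set(ids_b)]
    if factors is None:
        factors = size_factors(counts)
    f = factors.as_array(used)
    cols = [counts.sample_ids.index(s) for s in used]
    mat = counts.counts[:, cols].astype(float)
    norm = mat / f[None, :]
    groups = np.array([0 if s in set(ids_a) else 1 for s in used])

    alpha, wald_df = _nb_dispersion(norm, groups)
    pseudo = 0.5
    sel_a, sel_b = groups == 0, groups == 1
    mean_a = norm[:, sel_a].mean(axis=1)
    mean_b = norm[:, sel_b].mean(axis=1)
    lfc = np.log2((mean_b + pseudo) / (mean_a + pseudo))

    # delta-method variance of log2(group mean of normalized counts)
    def log2_mean_var(mean_g, sel):
        fg = f[sel]
        var_sum = (mean_g[:, None] / fg[None, :] + alpha[:, None] * mean_g[:, None] ** 2).sum(axis=1)
        var_mean = var_sum / sel.sum() ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            return var_mean / ((mean_g + pseudo) * np.log(2)) ** 2

    se2 = log2_mean_var(mean_a, sel_a) + log2_mean_var(mean_b, sel_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / np.sqrt(se2)
    wald = np.where(np.isfinite(wald), wald, 0.0)
    # t reference with residual + prior df: a normal tail is anti-conservative
    # for the plug-in variance at 2-3 samples per group
    out_p = 2 * stats.t.sf(np.abs(wald), wald_df)
    padj = adjust_bh(out_p)

    comparison = (strain_a, strain_b, tissue)
    results = []
    for i, cid in enumerate(counts.cluster_ids):
        results.append(
            DEResult(
                cid, comparison, float(lfc[i]), float(out_p[i]), float(padj[i]),
                bool(abs(lfc[i]) > lfc_threshold and padj[i] < fdr),
            )
        )
    return results


def summarize_de(de_results: list[list[DEResult]]) -> pd.DataFrame:
    """Per-cluster count of significant comparisons across DE runs.

    Returns a frame with columns ``n_significant``, ``any_significant``
    (>= 1 comparison) and ``recurrent`` (>= 3 comparisons).
    """
    clusters: dict[str, int] = {}
    for run in de_results:
        for r in run:
            clusters.setdefault(r.cluster_id, 0)
            if r.significant:
                clusters[r.cluster_id] += 1
    df = pd.DataFrame(
        {"cluster_id": list(clusters), "n_significant": list(clusters.values())}
    ).set_index("cluster_id")
    df["any_significant"] = df["n_significant"] >= 1
    df["recurrent"] = df["n_significant"] >= 3
    return df


def strain_variance_explained(
    expression: pd.DataFrame, samples: SampleTable
) -> list[VarianceExplainedResult]:
    """One-way fixed-effect model of expression on strain, per cluster.

    Returns adjusted R-squared, the F-test p-value and BH-adjusted p
    across clusters.  Clusters with zero total variance are flagged
    undefined with r2_adj = 0 and p = 1.
    """
    sample_ids = list(expression.columns)
    meta = samples.frame.set_index("sample_id").loc[sample_ids]
    strains = meta["strain"].to_numpy()
    labels, codes = np.unique(strains, return_inverse=True)
    k, n = len(labels), len(sample_ids)
    if k < 2:
        raise ValueError("need >= 2 strains")
    if n - k <= 0:
        raise ValueError("zero residual degrees of freedom")

    y = expression.to_numpy(dtype=float)
    grand = y.mean(axis=1, keepdims=True)
    sst = ((y - grand) ** 2).sum(axis=1)
    sse = np.zeros(len(y))
    for g in range(k):
        cols = codes == g
        gm = y[:, cols].mean(axis=1, keepdims=True)
        sse += ((y[:, cols] - gm) ** 2).sum(axis=1)

    undefined = sst <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / sst
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
        msr = (sst - sse) / (k - 1)
        mse = sse / (n - k)
        fstat = msr / mse
    pvals = np.where(
        undefined, 1.0,
        np.where(mse <= 1e-300, 0.0, stats.f.sf(fstat, k - 1, n - k)),
    )
    r2_adj = np.where(undefined, 0.0, r2_adj)
    padj = adjust_bh(pvals)
    return [
        VarianceExplainedResult(cid, float(r2_adj[i]), float(pvals[i]), float(padj[i]),
                                bool(undefined[i]))
        for i, cid in enumerate(expression.index)
    ]


def global_strain_effect(
    expression: pd.DataFrame, samples: SampleTable
) -> GlobalModelResult:
    """Mixed model expression ~ strain + (1|cluster) over the whole matrix.

    Fit by REML for variance components; the strain p-value is a
    likelihood-ratio test between ML fits with and without the strain
    fixed effect (chi-square, df = n_strains - 1).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    long = expression.reset_index(names="cluster").melt(
        id_vars="cluster", var_name="sample_id", value_name="expr"
    )
    meta = samples.frame[["sample_id", "strain"]]
    long = long.merge(meta, on="sample_id")
    n_strains = long["strain"].nunique()
    if n_strains < 2:
        raise ValueError("need >= 2 strains")

    if expression.shape[0] == 1:
        # single cluster: degenerates to fixed-effect ANOVA
        res = strain_variance_explained(expression, samples)[0]
        return GlobalModelResult(res.p, 0.0, 1.0, {}, singular=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reml = smf.mixedlm("expr ~ C(strain)", long, groups=long["cluster"]).fit(reml=True)
        full = smf.mixedlm("expr ~ C(strain)", long, groups=long["cluster"]).fit(reml=False)
        null = smf.mixedlm("expr ~ 1", long, groups=long["cluster"]).fit(reml=False)
    lr = 2 * (full.llf - null.llf)
    strain_p = float(stats.chi2.sf(max(lr, 0.0), n_strains - 1))
    cluster_var = float(reml.cov_re.iloc[0, 0])
    coeffs = {k: float(v) for k, v in reml.fe_params.items()}
    singular = cluster_var < 1e-10
    return GlobalModelResult(strain_p, max(cluster_var, 0.0), float(reml.scale), coeffs, singular)
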