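"""Recurrence-association statistics.

Wilcoxon rank-sum tests and mean-Z differences on signature scores,
empirical-Bayes moderated-t differential expression with Benjamini-Hochberg
FDR and a fold-change filter, and hierarchical clustering of response
category genes (after excluding genes shared between categories).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .signatures import KIND_CATEGORY, SignatureRegistry

logger = logging.getLogger("rccimmune")

LABEL_RECURRENT = "recurrent"
LABEL_NON_RECURRENT = "non_recurrent"

ALTERNATIVES = ("two_sided", "less", "greater")

#: largest n+m for which the exact (enumeration) Wilcoxon null is used
EXACT_CUTOFF = 12


class AssociationError(ValueError):
    pass


def split_groups(values: pd.Series | pd.DataFrame, labels: pd.Series):
    """Split samples into (recurrent, non_recurrent) blocks by label."""
    rec_ids = labels.index[labels == LABEL_RECURRENT]
    non_ids = labels.index[labels == LABEL_NON_RECURRENT]
    if len(rec_ids) == 0 or len(non_ids) == 0:
        raise AssociationError("both recurrence groups must be non-empty")
    if isinstance(values, pd.DataFrame):
        return values.loc[rec_ids], values.loc[non_ids]
    return values.loc[rec_ids], values.loc[non_ids]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x, y, alternative: str = "two_sided", exact_cutoff: int = EXACT_CUTOFF
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` (midranks for ties).
    The null distribution is exact — full enumeration of all C(n+m, n)
    group labelings — when n+m <= exact_cutoff and there are no ties;
    otherwise a normal approximation with tie correction and continuity
    correction is used. ``alternative='less'`` tests whether x tends to be
    smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AssociationError("wilcoxon_rank_sum requires two non-empty samples")
    if alternative not in ALTERNATIVES:
        raise AssociationError(f"alternative must be one of {ALTERNATIVES}")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    w = float(ranks[:n].sum())

    has_ties = np.unique(combined).size < combined.size
    if n + m <= exact_cutoff and not has_ties:
        return w, _exact_rank_sum_p(ranks, n, w, alternative)

    N = n + m
    mean_w = n * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((N) * (N - 1))
    var_w = n * m / 12.0 * ((N + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    sd = np.sqrt(var_w)
    # continuity correction: shrink |W - E[W]| by 0.5 toward the null mean
    if alternative == "less":
        z = (w - mean_w + 0.5) / sd
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        z = (w - mean_w - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        d = abs(w - mean_w) - 0.5
        z = max(d, 0.0) / sd
        p = 2.0 * stats.norm.sf(z)
    return w, float(min(p, 1.0))


def _exact_rank_sum_p(ranks: np.ndarray, n: int, w_obs: float, alternative: str) -> float:
    """Exact p by enumerating every choice of n ranks out of n+m."""
    sums = np.array(
        [sum(c) for c in itertools.combinations(ranks, n)], dtype=float
    )
    total = sums.size
    if alternative == "less":
        return float((sums <= w_obs).sum() / total)
    if alternative == "greater":
        return float((sums >= w_obs).sum() / total)
    p = 2.0 * min((sums <= w_obs).sum(), (sums >= w_obs).sum()) / total
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# signature-level association
# ---------------------------------------------------------------------------


def mean_z_difference(ztable: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-signature mean Z difference, recurrent minus non-recurrent."""
    rec, non = split_groups(ztable, labels)
    delta = rec.mean(axis=0) - non.mean(axis=0)
    delta.name = "delta_z"
    return delta


def associate_signatures(
    ztable: pd.DataFrame, labels: pd.Series, alternative: str = "two_sided"
) -> pd.DataFrame:
    """Mean-Z difference + Wilcoxon test per signature, with BH q across
    signatures. Raw p drives the headline outputs; q is reported alongside.
    """
    rec, non = split_groups(ztable, labels)
    rows = []
    for sig in ztable.columns:
        w, p = wilcoxon_rank_sum(rec[sig].to_numpy(), non[sig].to_numpy(), alternative)
        rows.append((sig, rec[sig].mean() - non[sig].mean(), w, p))
    report = pd.DataFrame(rows, columns=["signature", "delta_z", "W", "p"]).set_index(
        "signature"
    )
    report["q"] = bh_fdr(report["p"].to_numpy())
    return report


# ---------------------------------------------------------------------------
# moderated t (empirical Bayes)
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log(s^2) against its theoretical
    moments under the hierarchical model, yielding prior df ``d0`` (possibly
    infinite) and prior variance ``s0^2``.
    """
    ok = (df > 0) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise AssociationError("need >=2 genes with positive residual variance")
    z = np.log(s2)
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = np.exp(e_mean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess spread in log s^2 beyond sampling noise: variances look
        # exchangeable, so the prior is a point mass at their plain mean
        d0 = np.inf
        s0_2 = s2.mean()
    return float(d0), float(s0_2)


def moderated_t(
    matrix: pd.DataFrame,
    labels: pd.Series,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test, gene by gene.

    ``matrix`` holds log2 expression (genes x samples). Per gene the pooled
    residual variance s_g^2 on d_g = n1+n2-2 df is shrunk toward a prior
    (d0, s0^2) estimated across genes by method-of-moments on log s^2:

        s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
        t~_g   = log2FC_g / (s~_g * sqrt(1/n1 + 1/n2))

    with p from a t distribution on d0 + d_g df. Passing ``d0=0`` forces the
    ordinary pooled t; ``d0=inf`` (with s0_2) forces a common variance.
    Genes with zero residual df are excluded with a warning.
    """
    rec, non = split_groups(matrix.T, labels)
    x1 = rec.T.to_numpy(dtype=float)  # genes x n1 (recurrent)
    x2 = non.T.to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise AssociationError("moderated_t requires >=2 samples per group")
    dfree = n1 + n2 - 2

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / dfree
    lfc = m1 - m2

    keep = s2 > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        logger.warning("moderated_t: excluding %d zero-variance gene(s): %s",
                       len(dropped), dropped[:5])

    if d0 is None:
        d0_fit, s0_fit = fit_variance_prior(s2[keep], np.full(keep.sum(), float(dfree)))
        d0 = d0_fit
        if s0_2 is None:
            s0_2 = s0_fit
    elif d0 > 0 and s0_2 is None:
        _, s0_2 = fit_variance_prior(s2[keep], np.full(keep.sum(), float(dfree)))

    if d0 == 0:
        s2_post = s2
        df_total = float(dfree)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + dfree * s2) / (d0 + dfree)
        df_total = d0 + dfree
    # information in the shrunk variance cannot exceed the pooled total df
    df_total = min(df_total, float(dfree) * int(keep.sum()))

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "mean_recurrent_log2": m1,
            "mean_non_recurrent_log2": m2,
            "log2fc": lfc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
        },
        index=matrix.index,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_2"] = float(s0_2) if s0_2 is not None else None
    out.attrs["df_total"] = df_total
    return out.loc[keep]


# ---------------------------------------------------------------------------
# FDR and DEG reporting
# ---------------------------------------------------------------------------


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def deg_table(
    log2_matrix: pd.DataFrame,
    labels: pd.Series,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.3,
    fc_scale: str = "linear",
    d0: float | None = None,
) -> pd.DataFrame:
    """Moderated-t DEG analysis with BH FDR and fold-change filter.

    Fold change is the ratio of group means of anti-logged (linear-scale)
    expression by default; ``fc_scale='log2'`` uses 2**log2FC instead. A
    gene is reported when max(FC, 1/FC) > fc_threshold (strict) and its BH
    q < fdr_threshold (strict), symmetric in direction.
    """
    stats_table = moderated_t(log2_matrix, labels, d0=d0)
    rec, non = split_groups(log2_matrix.T, labels)
    lin = 2.0 ** log2_matrix.loc[stats_table.index]
    mean_rec = lin[rec.index].mean(axis=1)
    mean_non = lin[non.index].mean(axis=1)
    if fc_scale == "linear":
        fc = mean_rec / mean_non
    elif fc_scale == "log2":
        fc = 2.0 ** stats_table["log2fc"]
    else:
        raise AssociationError(f"unknown fc_scale {fc_scale!r}")

    out = stats_table.copy()
    out["mean_recurrent_linear"] = mean_rec
    out["mean_non_recurrent_linear"] = mean_non
    out["fold_change"] = fc
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["reported"] = deg_filter(out["fold_change"], out["q"], fc_threshold, fdr_threshold)
    return out


def deg_filter(
    fold_change: pd.Series,
    q: pd.Series,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.3,
) -> pd.Series:
    """reported <=> max(FC, 1/FC) > fc_threshold AND q < fdr_threshold."""
    magnitude = np.maximum(fold_change, 1.0 / fold_change)
    return (magnitude > fc_threshold) & (q < fdr_threshold)


# ---------------------------------------------------------------------------
# clustering of response-category genes
# ---------------------------------------------------------------------------


def gene_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise (row) Z standardization with sample SD."""
    if matrix.shape[1] < 2:
        raise AssociationError("gene_zscore requires >=2 samples")
    sd = matrix.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise AssociationError(f"zero-variance gene(s): {list(flat.index[:5])}")
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def category_gene_set(registry: SignatureRegistry) -> list[str]:
    """Union of the 4 response-category gene sets minus genes shared by >=2
    categories (the clustering overlap-exclusion rule). Sorted for
    determinism."""
    cats = registry.of_kind(KIND_CATEGORY)
    if len(cats) < 2:
        raise AssociationError("need response-category signatures in the registry")
    counts: dict[str, int] = {}
    for sig in cats:
        for gene in sig.genes:
            counts[gene] = counts.get(gene, 0) + 1
    keep = sorted(g for g, c in counts.items() if c == 1)
    if not keep:
        raise AssociationError("overlap exclusion removed every category gene")
    return keep


@dataclass
class ClusterResult:
    row_order: list[int]
    col_order: list[int]
    row_heights: list[float]
    col_heights: list[float]
    row_labels: list[int]
    col_labels: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "row_order": self.row_order,
            "col_order": self.col_order,
            "row_heights": self.row_heights,
            "col_heights": self.col_heights,
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
        }


def hierarchical_cluster(
    zmatrix: pd.DataFrame,
    n_flat_clusters: int = 2,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of rows (genes) and columns (samples).

    Euclidean distance with complete linkage by default; deterministic given
    the input (scipy's nearest-neighbor-chain agglomeration). Merge heights
    are non-decreasing for the default linkage choices.
    """
    if zmatrix.shape[0] < 2 or zmatrix.shape[1] < 2:
        raise AssociationError("clustering needs >=2 rows and >=2 columns")
    arr = zmatrix.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise AssociationError("non-finite values in clustering input")
    row_link = linkage(arr, method=method, metric=metric)
    col_link = linkage(arr.T, method=method, metric=metric)
    return ClusterResult(
        row_order=[int(i) for i in leaves_list(row_link)],
        col_order=[int(i) for i in leaves_list(col_link)],
        row_heights=[float(h) for h in row_link[:, 2]],
        col_heights=[float(h) for h in col_link[:, 2]],
        row_labels=[int(c) for c in fcluster(row_link, n_flat_clusters, criterion="maxclust")],
        col_labels=[int(c) for c in fcluster(col_link, n_flat_clusters, criterion="maxclust")],
        row_linkage=row_link,
        col_linkage=col_link,
    )
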