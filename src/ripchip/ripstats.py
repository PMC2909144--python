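"""Differential statistics and average-percentile-rank (APR) target calling.

The target-calling procedure is rank-based: within each replicate of a
condition, every probe gets a fractional percentile rank of its normalized
log-ratio among the expressed probes; the per-condition APR is the mean of
those ranks over replicates. A probe is called an RNP target when its IP APR
exceeds the IP cut, its mock-IP APR stays below the mock cut, and its
geometric-mean fold enrichment of IP over mock exceeds the fold cut — all
strict inequalities, exactly as stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix


@dataclass
class DifferentialResult:
    """Per-probe Welch t-score, two-sided p and log2 fold change (IP - mock)."""

    probe_ids: np.ndarray
    t_score: np.ndarray
    p_value: np.ndarray
    log_fold_change: np.ndarray
    bh_q: np.ndarray | None = None


@dataclass
class TargetCall:
    probe_ids: np.ndarray
    apr_ip: np.ndarray
    apr_mock: np.ndarray
    fold_enrichment: np.ndarray
    is_target: np.ndarray

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probe_ids,
            "apr_ip": self.apr_ip,
            "apr_mock": self.apr_mock,
            "fold_enrichment": self.fold_enrichment,
            "is_target": self.is_target,
        })


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Fractional percentile ranks in (0, 1]: average tied rank divided by n.

    The top untied value maps to exactly 1; a constant vector of length n
    maps everywhere to (n+1)/(2n). NaNs propagate as NaN and do not consume
    rank mass.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("all values are NaN/non-finite")
    out = np.full(values.shape, np.nan)
    n = int(finite.sum())
    out[finite] = stats.rankdata(values[finite], method="average") / n
    return out


def average_percentile_rank(columns: np.ndarray) -> np.ndarray:
    """Mean over replicate columns of per-replicate percentile ranks."""
    columns = np.atleast_2d(np.asarray(columns, dtype=float))
    if columns.ndim != 2 or columns.shape[1] < 2:
        raise ValueError("need at least 2 replicate columns")
    ranks = np.column_stack([percentile_ranks(columns[:, j])
                             for j in range(columns.shape[1])])
    return ranks.mean(axis=1)


def fold_enrichment(ip_columns: np.ndarray, mock_columns: np.ndarray) -> np.ndarray:
    """Linear fold of IP over mock: 2**(mean log2 IP - mean log2 mock).

    A geometric mean on the linear scale, so fold == 2**log_fold_change.
    """
    ip = np.atleast_2d(np.asarray(ip_columns, float))
    mock = np.atleast_2d(np.asarray(mock_columns, float))
    return np.exp2(ip.mean(axis=1) - mock.mean(axis=1))


def t_statistics(probe_ids: np.ndarray, ip_columns: np.ndarray,
                 mock_columns: np.ndarray, equal_var: bool = False,
                 variance_floor: bool = False) -> DifferentialResult:
    """Row-wise two-sample t comparing IP vs mock log-ratios.

    Welch (unequal variance) by default; set ``equal_var`` for the pooled
    form. ``variance_floor`` adds the 1st percentile of per-probe pooled
    variances to each group variance, preventing infinite t on zero-variance
    probes; off by default so toy examples match the textbook formula.
    """
    ip = np.atleast_2d(np.asarray(ip_columns, float))
    mock = np.atleast_2d(np.asarray(mock_columns, float))
    if ip.shape[1] < 2 or mock.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    lfc = ip.mean(axis=1) - mock.mean(axis=1)

    if variance_floor:
        v_ip = ip.var(axis=1, ddof=1)
        v_mock = mock.var(axis=1, ddof=1)
        pooled = ((ip.shape[1] - 1) * v_ip + (mock.shape[1] - 1) * v_mock) / (
            ip.shape[1] + mock.shape[1] - 2)
        floor = np.percentile(pooled, 1)
        t, p = _t_with_floor(ip, mock, floor, equal_var)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(ip, mock, axis=1, equal_var=equal_var)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        # zero variance in both groups: signed-infinity convention, p = 0;
        # t = 0 (p = 1) when the means are also identical
        bad = ~np.isfinite(t)
        if bad.any():
            t = np.where(bad, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf), t)
            p = np.where(bad, np.where(lfc == 0, 1.0, 0.0), p)
    q = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1]
    return DifferentialResult(np.asarray(probe_ids, dtype=object),
                              t, p, lfc, bh_q=q)


def _t_with_floor(ip: np.ndarray, mock: np.ndarray, floor: float,
                  equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = ip.shape[1], mock.shape[1]
    v1 = ip.var(axis=1, ddof=1) + floor
    v2 = mock.var(axis=1, ddof=1) + floor
    diff = ip.mean(axis=1) - mock.mean(axis=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full_like(se, n1 + n2 - 2)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = diff / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def call_targets(probe_ids: np.ndarray, apr_ip: np.ndarray, apr_mock: np.ndarray,
                 fold: np.ndarray, ip_cut: float = 0.95, mock_cut: float = 0.95,
                 fold_cut: float = 2.0) -> TargetCall:
    """Apply the three-part threshold rule with strict inequalities."""
    probe_ids = np.asarray(probe_ids, dtype=object)
    apr_ip = np.asarray(apr_ip, float)
    apr_mock = np.asarray(apr_mock, float)
    fold = np.asarray(fold, float)
    if not (len(probe_ids) == len(apr_ip) == len(apr_mock) == len(fold)):
        raise ValueError("misaligned input vector lengths")
    is_target = (apr_ip > ip_cut) & (apr_mock < mock_cut) & (fold > fold_cut)
    return TargetCall(probe_ids, apr_ip, apr_mock, fold, is_target)


def call_targets_from_matrix(matrix: ExpressionMatrix, ip_cut: float = 0.95,
                             mock_cut: float = 0.95, fold_cut: float = 2.0
                             ) -> tuple[TargetCall, DifferentialResult]:
    """APR + differential statistics over the expressed universe of a matrix."""
    expr = matrix.expressed()
    ip = expr.columns_for("IP")
    mock = expr.columns_for("mock")
    apr_ip = average_percentile_rank(ip)
    apr_mock = average_percentile_rank(mock)
    fold = fold_enrichment(ip, mock)
    call = call_targets(expr.probe_ids, apr_ip, apr_mock, fold,
                        ip_cut=ip_cut, mock_cut=mock_cut, fold_cut=fold_cut)
    diff = t_statistics(expr.probe_ids, ip, mock)
    return call, diff


def qq_against_normal(t_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantile pairs of standardized scores against the standard normal.

    Returns (theoretical, empirical): normal quantiles at (i - 0.5)/n and the
    sorted standardized scores. A heavy right tail shows as empirical points
    above the diagonal at the top.
    """
    t = np.asarray(t_scores, float)
    t = t[np.isfinite(t)]
    if len(t) < 10:
        raise ValueError("need >= 10 finite scores")
    sd = t.std(ddof=1)
    z = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
    emp = np.sort(z)
    n = len(emp)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, emp


def squared_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two per-probe summary vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def cluster_targets(values: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Average-linkage hierarchical clustering on 1 - Pearson distance.

    Clusters both probes (rows) and samples (columns) of the target
    submatrix; returns (row_order, col_order, row_linkage, col_linkage) for
    TreeView export.
    """
    values = np.asarray(values, float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 target probes to cluster")

    def _link(mat: np.ndarray) -> np.ndarray:
        # correlation distance is undefined for constant rows; nudge them
        mat = mat + 0.0
        const = mat.std(axis=1) == 0
        if const.any():
            mat[const, 0] += 1e-9
        d = np.clip(pdist(mat, metric="correlation"), 0.0, None)
        return hierarchy.linkage(d, method="average")

    row_tree = _link(values)
    col_tree = _link(values.T)
    row_order = hierarchy.leaves_list(row_tree)
    col_order = hierarchy.leaves_list(col_tree)
    return row_order, col_order, row_tree, col_tree
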