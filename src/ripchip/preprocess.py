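"""From raw scans to a filtered, normalized, collapsed expression matrix.

Pipeline order is fixed: within-array loess normalization of M on A, scale
normalization across arrays (equalize the median absolute deviation), median
collapsing of within-slide replicate probes, and finally the expression
filter applied as a per-probe mask. The filter itself is evaluated on the
raw intensities — foreground versus its own local background — before any
normalization, since that is what the >2-fold rule compares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .arrayio import ArrayScan, ROLES

#: corrected (background-subtracted) intensities are floored here before logs
INTENSITY_FLOOR = 0.5


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of normalized log2(sample/reference) ratios."""

    probe_ids: np.ndarray
    sample_meta: list[tuple[str, int]]   # (role, replicate) per column
    values: np.ndarray
    expressed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.expressed_mask = np.asarray(self.expressed_mask, dtype=bool)
        if self.values.shape != (len(self.probe_ids), len(self.sample_meta)):
            raise ValueError("values shape inconsistent with probes/samples")
        if len(self.expressed_mask) != len(self.probe_ids):
            raise ValueError("expressed_mask length mismatch")

    @property
    def sample_names(self) -> list[str]:
        return [f"{role}_{rep}" for role, rep in self.sample_meta]

    def columns_for(self, role: str) -> np.ndarray:
        """Column values for one role, replicate order; error if absent."""
        idx = [j for j, (r, _) in enumerate(self.sample_meta) if r == role]
        if not idx:
            raise ValueError(f"no samples with role {role!r}")
        return self.values[:, idx]

    def restrict(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.probe_ids[mask], list(self.sample_meta),
                                self.values[mask], self.expressed_mask[mask])

    def expressed(self) -> "ExpressionMatrix":
        return self.restrict(self.expressed_mask)


def _check_common_probes(scans: list[ArrayScan]) -> np.ndarray:
    if not scans:
        raise ValueError("empty scan list")
    ref_ids = scans[0].probe_ids
    for scan in scans[1:]:
        if len(scan) != len(ref_ids) or not np.array_equal(scan.probe_ids, ref_ids):
            raise ValueError(
                f"scan {scan.role} rep {scan.replicate} disagrees on the probe id set")
    return ref_ids


def expression_filter(scans: list[ArrayScan], fold: float = 2.0) -> np.ndarray:
    """Per-probe expressed mask from the raw >``fold``-over-background rule.

    A probe qualifies if there is at least one condition group (IP, mock or
    total) in which its sample foreground exceeds ``fold`` times its local
    background in *every* replicate of that group.
    """
    _check_common_probes(scans)
    if fold <= 1:
        raise ValueError("fold must be > 1")
    n = len(scans[0])
    mask = np.zeros(n, dtype=bool)
    for role in ROLES:
        group = [s for s in scans if s.role == role]
        if not group:
            continue
        passing = np.ones(n, dtype=bool)
        for scan in group:
            passing &= scan.sample_fg > fold * scan.sample_bg
        mask |= passing
    return mask


def background_correct(scan: ArrayScan) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted channel intensities, floored to stay positive."""
    s = np.maximum(scan.sample_fg - scan.sample_bg, INTENSITY_FLOOR)
    r = np.maximum(scan.ref_fg - scan.ref_bg, INTENSITY_FLOOR)
    return s, r


def normalize_within_array(scan: ArrayScan, span: float = 0.4,
                           iterations: int = 3) -> np.ndarray:
    """Loess-normalized per-probe M for one array.

    M = log2(sample/reference) after background subtraction; the returned
    values are M minus a robust local-linear (loess) fit of M on
    A = 1/2 log2(sample*reference), removing smooth intensity-dependent dye
    bias. ``span`` is the loess fraction, with tricube weights and
    ``iterations`` robustness reweightings.
    """
    s, r = background_correct(scan)
    m = np.log2(s) - np.log2(r)
    a = 0.5 * (np.log2(s) + np.log2(r))
    finite = np.isfinite(m) & np.isfinite(a)
    if finite.sum() < 10:
        raise ValueError("fewer than 10 finite (M, A) pairs; cannot fit loess")
    if np.ptp(a[finite]) == 0:
        # degenerate: all spots at one intensity; the smoother is the mean
        fit = np.full_like(m, m[finite].mean())
    else:
        delta = 0.01 * np.ptp(a[finite])  # interpolation shortcut for speed
        fit = np.full_like(m, np.nan)
        fit[finite] = lowess(m[finite], a[finite], frac=span, it=iterations,
                             delta=delta, return_sorted=False)
    return m - fit


def scale_across_arrays(m_vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Equalize the MAD of every array's M vector.

    Each vector is divided by (its MAD / geometric mean of all MADs), so the
    common post-scaling MAD is the geometric mean of the originals.
    """
    if len(m_vectors) < 2:
        raise ValueError("need at least 2 arrays to scale")
    mads = []
    for v in m_vectors:
        v = np.asarray(v, dtype=float)
        mad = np.median(np.abs(v - np.median(v)))
        if mad == 0:
            raise ValueError("array with MAD = 0 cannot be scale-normalized")
        mads.append(mad)
    log_g = np.mean(np.log(mads))
    g = float(np.exp(log_g))
    return [np.asarray(v, float) * (g / mad) for v, mad in zip(m_vectors, mads)]


def collapse_replicate_probes(probe_ids: np.ndarray, values: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse rows sharing a probe id to their per-sample median.

    Output rows are unique ids in order of first occurrence. A no-op when ids
    are already unique.
    """
    probe_ids = np.asarray(probe_ids, dtype=object)
    values = np.asarray(values, dtype=float)
    unique_ids, first_pos, inverse = np.unique(
        probe_ids, return_index=True, return_inverse=True)
    if len(unique_ids) == len(probe_ids):
        return probe_ids, values
    order = np.argsort(first_pos)            # first-occurrence order
    df = pd.DataFrame(values)
    med = df.groupby(inverse, sort=True).median().to_numpy()
    return unique_ids[order], med[order]


def build_expression_matrix(scans: list[ArrayScan], span: float = 0.4,
                            filter_fold: float = 2.0) -> ExpressionMatrix:
    """Run the full preprocessing chain on a set of scans."""
    probe_ids = _check_common_probes(scans)
    scans = sorted(scans, key=lambda s: (ROLES.index(s.role), s.replicate))
    mask_rows = expression_filter(scans, fold=filter_fold)

    m_vectors = [normalize_within_array(s, span=span) for s in scans]
    m_vectors = scale_across_arrays(m_vectors)
    values = np.column_stack(m_vectors)

    # a collapsed probe is expressed if any of its spots passed the filter
    unique_ids, collapsed = collapse_replicate_probes(probe_ids, values)
    if len(unique_ids) != len(probe_ids):
        mask_df = pd.Series(mask_rows).groupby(
            pd.Series(probe_ids, dtype=object).to_numpy(), sort=False).any()
        mask = mask_df.reindex(unique_ids).to_numpy(dtype=bool)
    else:
        mask = mask_rows

    meta = [(s.role, s.replicate) for s in scans]
    return ExpressionMatrix(probe_ids=unique_ids, sample_meta=meta,
                            values=collapsed, expressed_mask=mask)
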