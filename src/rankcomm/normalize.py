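"""Between-cell normalization: TMM scale factors, CPM, and the voom-style
log transformation.

TMM (trimmed mean of M-values) corrects for composition bias between
libraries by averaging doubly trimmed gene-wise log-ratios against a
reference cell, weighting each gene by the inverse of its asymptotic
binomial variance. Factors are rescaled to geometric mean one so the grand
expression scale is untouched. The voom transform maps counts to
log2 counts-per-million with small offsets, optionally attaching precision
weights from an empirical mean-variance trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.api as sm

from .exceptions import NormalizationError
from .io import CountMatrix

__all__ = ["NormalizedMatrix", "tmm_factors", "cpm", "voom_transform"]


@dataclass
class NormalizedMatrix:
    """log2 normalized expression (genes x cells), optionally with voom
    precision weights of identical shape."""

    values: np.ndarray
    gene_ids: list[str]
    barcodes: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("normalized matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized matrix contains non-finite values")


def _as_counts_array(m: CountMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, CountMatrix):
        return m.counts
    return np.asarray(m)


def _tmm_one(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    label: str = "?",
) -> float:
    """Log2 TMM factor of one observation column against the reference."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise NormalizationError(
            f"cell {label} shares no positive genes with the reference"
        )
    o = obs[both] / n_obs
    r = ref[both] / n_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # inverse asymptotic binomial variance weights
    v = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (n_ref * ref[both])
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * M[keep]) / np.sum(w))
    return f if np.isfinite(f) else 0.0


def tmm_factors(
    m: CountMatrix | np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factor per cell.

    The reference cell is the one whose upper-quartile CPM is closest to the
    mean upper-quartile across cells. Trim fractions default to the
    published values: 0.30 on M (log-ratio) and 0.05 on A (log-abundance).
    Returned factors have geometric mean one.
    """
    counts = _as_counts_array(m).astype(float)
    if counts.shape[1] < 2:
        raise NormalizationError("TMM requires at least 2 cells")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise NormalizationError("every cell must have a positive library size")
    uq = np.quantile(counts / lib * 1e6, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    n_ref = lib[ref_idx]
    names = m.barcodes if isinstance(m, CountMatrix) else [str(j) for j in range(counts.shape[1])]
    log_f = np.array(
        [
            _tmm_one(counts[:, j], ref, lib[j], n_ref, trim_m, trim_a, label=names[j])
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** (log_f - log_f.mean())  # geometric mean 1
    return factors


def cpm(m: CountMatrix | np.ndarray, factors: np.ndarray | None = None) -> np.ndarray:
    """Counts per million on effective library sizes (library x TMM factor)."""
    counts = _as_counts_array(m).astype(float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise NormalizationError("zero library size")
    if factors is None:
        factors = np.ones(counts.shape[1])
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.shape[1],):
        raise ValueError("factors not aligned to cells")
    return counts / (lib * factors) * 1e6


def voom_transform(
    m: CountMatrix,
    factors: np.ndarray | None = None,
    compute_weights: bool = False,
    lowess_frac: float = 0.5,
) -> NormalizedMatrix:
    """voom-style log2-CPM with offsets; optionally with precision weights.

    value = log2((count + 0.5) / (lib * factor + 1) * 1e6).

    When ``compute_weights`` is set, a lowess curve of sqrt-standard-deviation
    against mean log2-count is fitted across genes and evaluated at each
    entry's fitted log-count; weights are the fourth inverse power of the
    trend. Downstream interaction scoring uses the transformed values only,
    so weights are off by default.
    """
    counts = _as_counts_array(m).astype(float)
    lib = counts.sum(axis=0)
    if factors is None:
        factors = np.ones(counts.shape[1])
    factors = np.asarray(factors, dtype=float)
    eff = lib * factors
    values = np.log2((counts + 0.5) / (eff + 1.0) * 1e6)
    weights = None
    if compute_weights:
        weights = _voom_weights(counts, eff, values, lowess_frac)
    return NormalizedMatrix(values, list(m.gene_ids), list(m.barcodes), weights)


def _voom_weights(
    counts: np.ndarray, eff: np.ndarray, values: np.ndarray, frac: float
) -> np.ndarray:
    # mean log2 count per gene, on the scale of a typical effective library
    mean_logcpm = values.mean(axis=1)
    sx = mean_logcpm + np.log2(np.mean(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(values.std(axis=1, ddof=1)) if values.shape[1] > 1 else np.zeros_like(sx)
    order = np.argsort(sx, kind="stable")
    fit = sm.nonparametric.lowess(sy[order], sx[order], frac=frac, return_sorted=True)
    # fitted log-count of each entry, interpolated on the trend
    fitted = np.log2(counts + 0.5)
    trend = np.interp(fitted, fit[:, 0], fit[:, 1])
    trend = np.clip(trend, 1e-6, None)
    return trend ** (-4.0)


def pseudobulk_factors(
    m: CountMatrix,
    labels: pd.Series | np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """TMM computed on per-cell-type summed counts, broadcast to member cells.

    A more stable alternative to per-cell TMM on sparse data; the per-group
    factor geometric mean is one, then factors are assigned to each cell of
    the group.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_cells:
        raise ValueError("labels not aligned to cells")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise NormalizationError("pseudo-bulk TMM requires at least 2 groups")
    bulk = np.column_stack([m.counts[:, labels == g].sum(axis=1) for g in groups])
    f = tmm_factors(bulk, trim_m=trim_m, trim_a=trim_a)
    lookup = dict(zip(groups, f))
    return np.array([lookup[g] for g in labels])
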