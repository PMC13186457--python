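"""scikit-learn-style estimators wrapping the normalization, DGBD and
interaction-scoring cores.

These follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``check_is_fitted``-compatible) so
they compose with pipelines and model selection. sklearn orientation is
used throughout: X is (n_cells, n_genes), the transpose of the on-disk
genes x cells convention handled by :mod:`rankcomm.io`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import interactions as _inter
from . import normalize as _norm
from .dgbd import DEFAULT_BOUNDS, dgbd_pmf, fit_dgbd, gof_dgbd, rank_frequency
from .io import CountMatrix, LRPair, filter_cells

__all__ = ["TMMVoomNormalizer", "DGBDRankModel", "CrossTalker"]


def _to_count_matrix(X, y=None) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Accept a CountMatrix, a cells x genes DataFrame, or a plain array."""
    if isinstance(X, CountMatrix):
        cm = X
    elif isinstance(X, pd.DataFrame):
        cm = CountMatrix(
            X.to_numpy().T, [str(c) for c in X.columns], [str(i) for i in X.index]
        )
    else:
        X = np.asarray(X)
        cm = CountMatrix(
            X.T,
            [f"G{i:04d}" for i in range(1, X.shape[1] + 1)],
            [f"C{i:05d}" for i in range(X.shape[0])],
        )
    ann = None
    if y is not None:
        y = np.asarray(y)
        if y.shape[0] != cm.n_cells:
            raise ValueError("y length does not match the number of cells")
        ann = pd.DataFrame({"barcode": cm.barcodes, "cell_type": y.astype(str)})
    return cm, ann


class TMMVoomNormalizer(TransformerMixin, BaseEstimator):
    """TMM scale factors followed by the voom log2-CPM transformation.

    Normalization factors are a per-sample quantity: ``fit`` computes and
    stores the factors for the samples it is given, and ``transform`` must
    be called on those same samples. Use ``fit_transform`` for the usual
    one-shot normalization.

    Parameters
    ----------
    trim_m, trim_a : float
        Two-sided trim fractions on the M (log-ratio) and A (log-abundance)
        distributions; published defaults 0.30 and 0.05.
    compute_weights : bool
        Attach voom precision weights (``weights_``) after transform.
    """

    def __init__(self, trim_m: float = 0.3, trim_a: float = 0.05, compute_weights: bool = False):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.compute_weights = compute_weights

    def fit(self, X, y=None):
        cm, _ = _to_count_matrix(X)
        self.factors_ = _norm.tmm_factors(cm, trim_m=self.trim_m, trim_a=self.trim_a)
        self.library_sizes_ = cm.library_sizes().astype(float)
        self.n_features_in_ = cm.n_genes
        return self

    def transform(self, X):
        check_is_fitted(self, "factors_")
        cm, _ = _to_count_matrix(X)
        if cm.n_cells != self.factors_.shape[0]:
            raise ValueError(
                "TMM factors are per-sample; transform the same cells that were fitted"
            )
        nm = _norm.voom_transform(cm, self.factors_, compute_weights=self.compute_weights)
        self.weights_ = None if nm.weights is None else nm.weights.T
        return nm.values.T


class DGBDRankModel(BaseEstimator):
    """Maximum-likelihood DGBD fit of one expression vector's rank profile.

    ``fit`` takes the per-cell expression values of a single gene within a
    single cell type, builds the binned rank-frequency vector, and estimates
    the shape parameters (alpha: head, beta: tail) by bounded quasi-Newton.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted shape parameters.
    log_likelihood_ : float
        Multinomial log-likelihood at the optimum.
    converged_, degenerate_ : bool
    n_ranks_ : int
        Number of occupied bins the model was fitted over.
    gof_deviance_, gof_p_ : float
        Deviance against the saturated multinomial and its chi-square
        p-value (NaN below 4 ranks).
    """

    def __init__(self, n_bins: int = 20, bounds=DEFAULT_BOUNDS):
        self.n_bins = n_bins
        self.bounds = bounds

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        rf = rank_frequency(values, n_bins=self.n_bins)
        fit = fit_dgbd(rf, bounds=self.bounds)
        gof = gof_dgbd(rf, fit)
        self.rank_frequency_ = rf
        self.alpha_ = fit.alpha
        self.beta_ = fit.beta
        self.log_norm_ = fit.log_norm
        self.log_likelihood_ = fit.log_likelihood
        self.converged_ = fit.converged
        self.degenerate_ = fit.degenerate
        self.n_ranks_ = fit.N
        self.gof_deviance_ = gof.deviance
        self.gof_p_ = gof.p_value
        return self

    def pmf(self) -> np.ndarray:
        """Fitted rank mass function over 1..n_ranks_."""
        check_is_fitted(self, "alpha_")
        return dgbd_pmf(self.alpha_, self.beta_, self.n_ranks_)


class CrossTalker(BaseEstimator):
    """End-to-end ligand-receptor communication inference.

    ``fit(X, y)`` takes cells x genes UMI counts (CountMatrix, DataFrame
    with gene columns, or array) and per-cell type labels ``y``, then runs
    cell filtering, TMM + voom normalization, per-(gene, type) DGBD
    profiling, interaction scoring, label-permutation significance and
    co-receptor triad scoring.

    Parameters
    ----------
    lr_pairs : list of LRPair
        The ligand-receptor database to score (like a fixed vocabulary).
    min_genes : int
        Cells expressing fewer distinct genes are dropped (droplet QC).
    n_bins : int
        Expression bins for the rank-frequency construction.
    min_cells : int
        Smallest cell type size that gets a profile.
    min_frac : float
        Expression-breadth gate on both sides of an interaction.
    require_gof, gof_alpha
        Gate interactions on the DGBD goodness of fit.
    n_perm : int
        Label permutations for the significance test.
    score_mode : {"product", "dgbd_weighted"}
    tmm_groupby : {None, "cell_type"}
        Per-cell TMM (default) or pseudo-bulk TMM per type broadcast to cells.
    random_state : int or None

    Attributes
    ----------
    profiles_ : DataFrame of per-(gene, cell type) expression summaries.
    interactions_ : DataFrame with strength, p_value, q_value per
        (ligand, receptor, sender, receiver).
    coreceptors_ : DataFrame of significant co-receptor triads.
    factors_ : TMM factors of the retained cells.
    """

    def __init__(
        self,
        lr_pairs: list[LRPair] | None = None,
        min_genes: int = 200,
        n_bins: int = 20,
        min_cells: int = 10,
        min_frac: float = 0.1,
        require_gof: bool = True,
        gof_alpha: float = 0.05,
        n_perm: int = 1000,
        score_mode: str = "product",
        tmm_groupby: str | None = None,
        random_state: int | None = None,
    ):
        self.lr_pairs = lr_pairs
        self.min_genes = min_genes
        self.n_bins = n_bins
        self.min_cells = min_cells
        self.min_frac = min_frac
        self.require_gof = require_gof
        self.gof_alpha = gof_alpha
        self.n_perm = n_perm
        self.score_mode = score_mode
        self.tmm_groupby = tmm_groupby
        self.random_state = random_state

    def fit(self, X, y):
        if not self.lr_pairs:
            raise ValueError("lr_pairs must be a non-empty list of LRPair")
        cm, ann = _to_count_matrix(X, y)
        cm = filter_cells(cm, min_genes=self.min_genes)
        kept = set(cm.barcodes)
        ann = ann[ann["barcode"].isin(kept)].reset_index(drop=True)

        if self.tmm_groupby == "cell_type":
            order = {b: i for i, b in enumerate(cm.barcodes)}
            labels = np.empty(cm.n_cells, dtype=object)
            for b, t in zip(ann["barcode"], ann["cell_type"]):
                labels[order[b]] = t
            factors = _norm.pseudobulk_factors(cm, labels)
        elif self.tmm_groupby is None:
            factors = _norm.tmm_factors(cm)
        else:
            raise ValueError(f"unknown tmm_groupby: {self.tmm_groupby!r}")
        nm = _norm.voom_transform(cm, factors)

        genes = {p.ligand for p in self.lr_pairs} | {p.receptor for p in self.lr_pairs}
        genes |= {c for p in self.lr_pairs for c in p.co_receptors}
        profiles = _inter.expression_profiles(
            nm, cm, ann, genes, min_cells=self.min_cells, n_bins=self.n_bins
        )
        scores = _inter.score_interactions(
            profiles,
            self.lr_pairs,
            min_frac=self.min_frac,
            require_gof=self.require_gof,
            gof_alpha=self.gof_alpha,
            score_mode=self.score_mode,
        )
        scores = _inter.permutation_test(
            scores,
            nm,
            cm,
            ann,
            n_perm=self.n_perm,
            seed=np.random.default_rng(self.random_state),
            min_frac=self.min_frac,
        )
        self.count_matrix_ = cm
        self.annotation_ = ann
        self.factors_ = factors
        self.normalized_ = nm
        self.profiles_ = profiles
        self.interactions_ = scores
        self.coreceptors_ = _inter.co_receptor_scores(
            scores, profiles, self.lr_pairs, min_frac=self.min_frac
        )
        self.n_features_in_ = cm.n_genes
        return self

    def interaction_matrix(self, ligand: str, receptor: str) -> pd.DataFrame:
        """Senders x receivers strength matrix for one pair."""
        check_is_fitted(self, "interactions_")
        return _inter.interaction_matrix(self.interactions_, ligand, receptor)
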