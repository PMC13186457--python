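"""Ligand-receptor interaction scoring between annotated cell types.

For every gene of interest and every sufficiently large cell type, an
expression profile is built: mean rectified voom expression, fraction of
cells with nonzero counts, and a DGBD fit of the within-type expression
rank-frequency with its goodness of fit. A directed interaction
(ligand, receptor, sender, receiver) scores the product of the sender's
ligand mean and the receiver's receptor mean, gated on expression breadth
(and optionally on DGBD goodness of fit, which screens out profiles whose
rank-occupancy shape the model cannot describe). Significance comes from a
cell-type label permutation null with Benjamini-Hochberg FDR across the
nonzero-strength family; co-receptor triads extend significant pairs with
receiver-side co-receptor expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dgbd import fit_dgbd, gof_dgbd, rank_frequency
from .exceptions import EmptyResultError
from .io import CountMatrix, LRPair
from .normalize import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "expression_profiles",
    "score_interactions",
    "permutation_test",
    "interaction_matrix",
    "co_receptor_scores",
]

PROFILE_COLUMNS = [
    "gene",
    "cell_type",
    "mean_expr",
    "frac_expressed",
    "n_cells",
    "alpha",
    "beta",
    "log_likelihood",
    "converged",
    "degenerate",
    "gof_deviance",
    "gof_p",
    "gof_q",
]


def _gene_index(gene_ids: list[str]) -> dict[str, int]:
    """Case-insensitive symbol -> row index (no alias expansion)."""
    return {g.upper(): i for i, g in enumerate(gene_ids)}


def rectified_values(nm: NormalizedMatrix, cm: CountMatrix) -> tuple[np.ndarray, float]:
    """voom values shifted by the global floor, clamped at zero, with
    zero-count entries pinned to exactly zero.

    voom values are signed logs; a product interaction score needs a
    non-negative scale on which an unexpressed gene contributes exactly
    nothing. Entries with a positive count keep their library-normalized
    rectified value.
    """
    floor = float(nm.values.min())
    rect = np.maximum(nm.values - floor, 0.0)
    rect[cm.counts == 0] = 0.0
    return rect, floor


def expression_profiles(
    nm: NormalizedMatrix,
    cm: CountMatrix,
    ann: pd.DataFrame,
    genes: set[str] | list[str],
    min_cells: int = 10,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-(gene, cell type) expression summaries with DGBD fits.

    Cell types with fewer than ``min_cells`` annotated cells are skipped
    with a logged notice. ``genes`` are matched case-insensitively against
    the matrix gene ids; absent genes are ignored here (callers log them).
    """
    if list(nm.barcodes) != list(cm.barcodes) or list(nm.gene_ids) != list(cm.gene_ids):
        raise ValueError("normalized matrix and count matrix are not aligned")
    bc_to_col = {b: j for j, b in enumerate(cm.barcodes)}
    missing = [b for b in ann["barcode"] if b not in bc_to_col]
    if missing:
        raise ValueError(
            f"{len(missing)} annotated barcodes absent from the count matrix "
            f"(first: {missing[0]!r})"
        )
    gidx = _gene_index(cm.gene_ids)
    gene_rows = {g: gidx[g.upper()] for g in genes if g.upper() in gidx}

    rect, _ = rectified_values(nm, cm)
    rows = []
    for cell_type, grp in ann.groupby("cell_type", sort=True):
        cols = np.array([bc_to_col[b] for b in grp["barcode"]])
        if cols.size < min_cells:
            logger.info(
                "cell type %r has %d cells (< %d); skipped", cell_type, cols.size, min_cells
            )
            continue
        for gene, r in sorted(gene_rows.items()):
            vals = nm.values[r, cols]
            rf = rank_frequency(vals, n_bins=n_bins)
            fit = fit_dgbd(rf)
            gof = gof_dgbd(rf, fit)
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell_type,
                    "mean_expr": float(rect[r, cols].mean()),
                    "frac_expressed": float((cm.counts[r, cols] > 0).mean()),
                    "n_cells": int(cols.size),
                    "alpha": fit.alpha,
                    "beta": fit.beta,
                    "log_likelihood": fit.log_likelihood,
                    "converged": fit.converged,
                    "degenerate": fit.degenerate,
                    "gof_deviance": gof.deviance,
                    "gof_p": gof.p_value,
                }
            )
    if not rows:
        raise EmptyResultError(f"no cell type reaches min_cells={min_cells}")
    out = pd.DataFrame(rows, columns=PROFILE_COLUMNS[:-1])
    # the GOF screen runs over the whole profile family, so control the FDR
    # of the screen rather than its per-test error rate
    out["gof_q"] = np.nan
    finite = np.isfinite(out["gof_p"].to_numpy())
    if finite.any():
        out.loc[finite, "gof_q"] = multipletests(
            out.loc[finite, "gof_p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def _profile_lookup(profiles: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
    return {
        (row.gene.upper(), row.cell_type): row
        for row in profiles.itertuples(index=False)
    }


def _gate_ok(row, min_frac: float, require_gof: bool, gof_alpha: float) -> bool:
    if row.frac_expressed < min_frac:
        return False
    if require_gof and np.isfinite(row.gof_q) and row.gof_q < gof_alpha:
        return False
    return True


def _dgbd_shape_weight(row) -> float:
    return max(0.0, 1.0 + row.beta - row.alpha)


def score_interactions(
    profiles: pd.DataFrame,
    lr_db: list[LRPair],
    min_frac: float = 0.1,
    require_gof: bool = True,
    gof_alpha: float = 0.05,
    score_mode: str = "product",
) -> pd.DataFrame:
    """Score every (pair, sender, receiver) combination, autocrine included.

    strength = mean_expr(ligand, sender) * mean_expr(receptor, receiver)
    when both profiles pass the breadth gate (frac_expressed >= min_frac)
    and, if ``require_gof``, the DGBD fit is not rejected at ``gof_alpha``;
    otherwise 0. With ``score_mode="dgbd_weighted"`` each factor is further
    multiplied by max(0, 1 + beta - alpha) of its fit, putting the rank-curve
    shape directly into the score. Output is sorted by descending strength,
    ties broken lexicographically.
    """
    if not lr_db:
        raise EmptyResultError("ligand-receptor database is empty")
    if score_mode not in ("product", "dgbd_weighted"):
        raise ValueError(f"unknown score_mode: {score_mode!r}")
    lookup = _profile_lookup(profiles)
    types = sorted(profiles["cell_type"].unique())
    available = {g for g, _ in lookup}
    rows = []
    for pair in lr_db:
        lig, rec = pair.ligand.upper(), pair.receptor.upper()
        if lig not in available or rec not in available:
            logger.info("pair %s-%s absent from data; skipped", pair.ligand, pair.receptor)
            continue
        for sender in types:
            lrow = lookup.get((lig, sender))
            for receiver in types:
                rrow = lookup.get((rec, receiver))
                strength = 0.0
                if (
                    lrow is not None
                    and rrow is not None
                    and _gate_ok(lrow, min_frac, require_gof, gof_alpha)
                    and _gate_ok(rrow, min_frac, require_gof, gof_alpha)
                ):
                    strength = lrow.mean_expr * rrow.mean_expr
                    if score_mode == "dgbd_weighted":
                        strength *= _dgbd_shape_weight(lrow) * _dgbd_shape_weight(rrow)
                rows.append(
                    {
                        "ligand": pair.ligand,
                        "receptor": pair.receptor,
                        "sender": sender,
                        "receiver": receiver,
                        "strength": strength,
                        "p_value": np.nan,
                        "q_value": np.nan,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "sender", "receiver", "strength", "p_value", "q_value"],
    )
    out = out.sort_values(
        by=["strength", "ligand", "receptor", "sender", "receiver"],
        ascending=[False, True, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return out


def permutation_test(
    scores: pd.DataFrame,
    nm: NormalizedMatrix,
    cm: CountMatrix,
    ann: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Attach permutation p-values and BH q-values to an interaction table.

    Cell-type labels are permuted uniformly ``n_perm`` times (type sizes
    preserved); per permutation, strengths are recomputed under the breadth
    gate only — the goodness-of-fit gate stays frozen at its observed value
    so the null does not require refitting thousands of DGBDs.
    p = (1 + #{perm >= observed}) / (1 + n_perm); q by Benjamini-Hochberg
    over entries with observed strength > 0 (others get q = 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bc_to_col = {b: j for j, b in enumerate(cm.barcodes)}
    cols = np.array([bc_to_col[b] for b in ann["barcode"]])
    labels = ann["cell_type"].to_numpy()
    types = sorted(set(scores["sender"]) | set(scores["receiver"]))
    type_pos = {t: k for k, t in enumerate(types)}

    gidx = _gene_index(cm.gene_ids)
    genes = sorted({g.upper() for g in scores["ligand"]} | {g.upper() for g in scores["receptor"]})
    genes = [g for g in genes if g in gidx]
    grow = {g: i for i, g in enumerate(genes)}
    rows = np.array([gidx[g] for g in genes])

    rect, _ = rectified_values(nm, cm)
    V = rect[np.ix_(rows, cols)]  # genes_sub x annotated cells
    B = (cm.counts[np.ix_(rows, cols)] > 0).astype(float)

    lig_i = scores["ligand"].str.upper().map(grow).to_numpy()
    rec_i = scores["receptor"].str.upper().map(grow).to_numpy()
    snd_i = scores["sender"].map(type_pos).to_numpy()
    rcv_i = scores["receiver"].map(type_pos).to_numpy()
    valid = ~(pd.isna(lig_i) | pd.isna(rec_i))
    lig_i = np.where(valid, lig_i, 0).astype(int)
    rec_i = np.where(valid, rec_i, 0).astype(int)
    observed = scores["strength"].to_numpy()

    onehot = np.zeros((labels.size, len(types)))
    for k, t in enumerate(types):
        onehot[labels == t, k] = 1.0
    sizes = onehot.sum(axis=0)
    sizes[sizes == 0] = 1.0

    exceed = np.zeros(len(scores), dtype=np.int64)
    perm_onehot = np.empty_like(onehot)
    for _ in range(n_perm):
        perm = rng.permutation(labels.size)
        perm_onehot[:] = onehot[perm]
        means = (V @ perm_onehot) / sizes
        fracs = (B @ perm_onehot) / sizes
        s = means[lig_i, snd_i] * means[rec_i, rcv_i]
        gate = (fracs[lig_i, snd_i] >= min_frac) & (fracs[rec_i, rcv_i] >= min_frac)
        s = np.where(gate & valid, s, 0.0)
        exceed += s >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)

    out = scores.copy()
    out["p_value"] = p
    q = np.ones(len(out))
    tested = observed > 0
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out["q_value"] = q
    return out


def interaction_matrix(scores: pd.DataFrame, ligand: str, receptor: str) -> pd.DataFrame:
    """Dense senders x receivers strength matrix for one ligand-receptor pair.

    Rows and columns follow the sorted unique label order; combinations
    absent from the score table are 0.
    """
    sub = scores[
        (scores["ligand"].str.upper() == ligand.upper())
        & (scores["receptor"].str.upper() == receptor.upper())
    ]
    if sub.empty:
        raise KeyError(f"pair {ligand}-{receptor} not present in scores")
    senders = sorted(set(scores["sender"]))
    receivers = sorted(set(scores["receiver"]))
    mat = pd.DataFrame(0.0, index=senders, columns=receivers)
    for row in sub.itertuples(index=False):
        mat.loc[row.sender, row.receiver] = row.strength
    mat.index.name = "sender"
    mat.columns.name = "receiver"
    return mat


def co_receptor_scores(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    lr_db: list[LRPair],
    min_frac: float = 0.1,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Co-receptor triads for significant ligand-receptor interactions.

    For each entry with q <= ``q_threshold`` whose pair lists co-receptors,
    every co-receptor expressed broadly enough in the receiver
    (frac_expressed >= min_frac) yields a triad with
    co_strength = strength * mean_expr(co_receptor, receiver), sorted
    descending. An empty table is a valid result.
    """
    co_by_pair = {
        (p.ligand.upper(), p.receptor.upper()): p.co_receptors for p in lr_db if p.co_receptors
    }
    lookup = _profile_lookup(profiles)
    rows = []
    sig = scores[(scores["q_value"] <= q_threshold) & (scores["strength"] > 0)]
    for row in sig.itertuples(index=False):
        cos = co_by_pair.get((row.ligand.upper(), row.receptor.upper()), [])
        for co in cos:
            prow = lookup.get((co.upper(), row.receiver))
            if prow is None or prow.frac_expressed < min_frac:
                continue
            rows.append(
                {
                    "ligand": row.ligand,
                    "receptor": row.receptor,
                    "co_receptor": co,
                    "sender": row.sender,
                    "receiver": row.receiver,
                    "co_strength": row.strength * prow.mean_expr,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "co_receptor", "sender", "receiver", "co_strength"],
    )
    return out.sort_values(
        by=["co_strength", "ligand", "receptor", "co_receptor", "sender", "receiver"],
        ascending=[False, True, True, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
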