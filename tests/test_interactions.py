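import numpy as np
import pandas as pd
import pytest

import rankcomm as rc
from rankcomm.exceptions import EmptyResultError
from rankcomm.interactions import (
    co_receptor_scores,
    expression_profiles,
    interaction_matrix,
    permutation_test,
    score_interactions,
)
from rankcomm.normalize import tmm_factors, voom_transform

from conftest import make_annotation


def _small_pipeline(cm, ann, genes, min_cells=5, n_bins=10):
    f = tmm_factors(cm)
    nm = voom_transform(cm, f)
    profiles = expression_profiles(nm, cm, ann, genes, min_cells=min_cells, n_bins=n_bins)
    return nm, profiles


@pytest.fixture
def structured():
    """Two cell types; LIG expressed only in S, REC only in R."""
    rng = np.random.default_rng(8)
    n_per = 40
    counts = rng.negative_binomial(2, 0.5, size=(20, 2 * n_per))
    genes = ["LIG", "REC"] + [f"G{i:03d}" for i in range(18)]
    counts[0, :] = 0
    counts[0, :n_per] = rng.negative_binomial(2, 0.2, size=n_per)  # LIG in S
    counts[1, :] = 0
    counts[1, n_per:] = rng.negative_binomial(2, 0.2, size=n_per)  # REC in R
    barcodes = [f"c{i:03d}" for i in range(2 * n_per)]
    cm = rc.CountMatrix(counts, genes, barcodes)
    ann = make_annotation(barcodes, ["S"] * n_per + ["R"] * n_per)
    return cm, ann


class TestExpressionProfiles:
    def test_zero_count_gene_has_zero_profile(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        row = profiles.query("gene == 'LIG' and cell_type == 'R'").iloc[0]
        assert row.frac_expressed == 0.0
        assert row.mean_expr == 0.0

    def test_small_type_excluded(self, structured):
        cm, ann = structured
        ann2 = ann.copy()
        ann2.loc[ann2.index[-3:], "cell_type"] = "Tiny"
        nm, profiles = _small_pipeline(cm, ann2, {"LIG", "REC"}, min_cells=5)
        assert "Tiny" not in set(profiles["cell_type"])

    def test_ubiquitous_gene_full_fraction(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 10, size=(5, 30))
        cm = rc.CountMatrix(counts, [f"g{i}" for i in range(5)], [f"c{i}" for i in range(30)])
        ann = make_annotation(cm.barcodes, ["T"] * 30)
        nm, profiles = _small_pipeline(cm, ann, {"g0"})
        assert profiles.iloc[0].frac_expressed == 1.0

    def test_no_type_reaches_min_cells(self, structured):
        cm, ann = structured
        with pytest.raises(EmptyResultError):
            _small_pipeline(cm, ann, {"LIG"}, min_cells=1000)

    def test_unknown_barcode_rejected(self, structured):
        cm, ann = structured
        bad = pd.concat(
            [ann, pd.DataFrame({"barcode": ["ghost"], "cell_type": ["S"]})],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="ghost"):
            _small_pipeline(cm, bad, {"LIG"})


class TestScoreInteractions:
    def test_planted_pair_is_maximal(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        scores = score_interactions(profiles, [rc.LRPair("LIG", "REC")], require_gof=False)
        top = scores.iloc[0]
        assert (top.sender, top.receiver) == ("S", "R")
        assert top.strength > 0
        # direct mean computation agrees
        lrow = profiles.query("gene=='LIG' and cell_type=='S'").iloc[0]
        rrow = profiles.query("gene=='REC' and cell_type=='R'").iloc[0]
        assert top.strength == pytest.approx(lrow.mean_expr * rrow.mean_expr)

    def test_breadth_gate_zeroes_strength(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        frac = profiles.query("gene=='REC' and cell_type=='R'").iloc[0].frac_expressed
        scores = score_interactions(
            profiles, [rc.LRPair("LIG", "REC")], min_frac=frac + 0.01, require_gof=False
        )
        assert scores.query("sender=='S' and receiver=='R'").iloc[0].strength == 0.0

    def test_all_zero_expression_all_zero_strengths(self):
        counts = np.zeros((4, 20), dtype=int)
        counts[3, :] = 1  # keep libraries positive
        cm = rc.CountMatrix(counts, ["L", "R", "x", "y"], [f"c{i}" for i in range(20)])
        ann = make_annotation(cm.barcodes, ["A"] * 10 + ["B"] * 10)
        nm, profiles = _small_pipeline(cm, ann, {"L", "R"})
        scores = score_interactions(profiles, [rc.LRPair("L", "R")], require_gof=False)
        assert (scores["strength"] == 0).all()

    def test_empty_db_is_error(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG"})
        with pytest.raises(EmptyResultError):
            score_interactions(profiles, [])

    def test_absent_gene_pair_skipped(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        scores = score_interactions(
            profiles, [rc.LRPair("LIG", "REC"), rc.LRPair("NOPE", "REC")], require_gof=False
        )
        assert set(scores["ligand"]) == {"LIG"}

    def test_scoring_locality(self, structured):
        """Doubling a non-LR gene's counts does not change strengths
        downstream of a fixed normalization."""
        cm, ann = structured
        f = tmm_factors(cm)
        nm = voom_transform(cm, f)
        profiles = expression_profiles(nm, cm, ann, {"LIG", "REC"}, min_cells=5)
        s1 = score_interactions(profiles, [rc.LRPair("LIG", "REC")], require_gof=False)

        counts2 = cm.counts.copy()
        counts2[5, :] *= 2
        cm2 = rc.CountMatrix(counts2, cm.gene_ids, cm.barcodes)
        nm2 = rc.NormalizedMatrix(nm.values, nm.gene_ids, nm.barcodes)
        profiles2 = expression_profiles(nm2, cm2, ann, {"LIG", "REC"}, min_cells=5)
        s2 = score_interactions(profiles2, [rc.LRPair("LIG", "REC")], require_gof=False)
        pd.testing.assert_frame_equal(s1, s2)

    def test_invariant_to_cell_relabeling(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        s1 = score_interactions(profiles, [rc.LRPair("LIG", "REC")], require_gof=False)

        perm = np.random.default_rng(0).permutation(cm.n_cells)
        cm2 = rc.CountMatrix(
            cm.counts[:, perm], cm.gene_ids, [cm.barcodes[j] for j in perm]
        )
        ann2 = ann.iloc[list(perm)].reset_index(drop=True)
        nm2, profiles2 = _small_pipeline(cm2, ann2, {"LIG", "REC"})
        s2 = score_interactions(profiles2, [rc.LRPair("LIG", "REC")], require_gof=False)
        pd.testing.assert_frame_equal(s1, s2)

    def test_dgbd_weighted_mode_runs(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        s = score_interactions(
            profiles, [rc.LRPair("LIG", "REC")], require_gof=False, score_mode="dgbd_weighted"
        )
        assert (s["strength"] >= 0).all()


class TestPermutationTest:
    def test_zero_strength_gives_p_one(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        scores = score_interactions(
            profiles, [rc.LRPair("LIG", "REC")], min_frac=0.99, require_gof=False
        )
        assert (scores["strength"] == 0).all()
        out = permutation_test(scores, nm, cm, ann, n_perm=49, seed=1)
        assert (out["p_value"] == 1.0).all()
        assert (out["q_value"] == 1.0).all()

    def test_planted_pair_attains_minimum_p(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        scores = score_interactions(profiles, [rc.LRPair("LIG", "REC")], require_gof=False)
        out = permutation_test(scores, nm, cm, ann, n_perm=999, seed=2)
        p = out.query("sender=='S' and receiver=='R'").iloc[0].p_value
        assert p == pytest.approx(1 / 1000)

    def test_q_monotone_in_p(self, fitted_crosstalker):
        scores = fitted_crosstalker.interactions_
        tested = scores[scores["strength"] > 0].sort_values("p_value")
        assert (np.diff(tested["q_value"].to_numpy()) >= -1e-12).all()

    def test_determinism_per_seed(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        scores = score_interactions(profiles, [rc.LRPair("LIG", "REC")], require_gof=False)
        a = permutation_test(scores, nm, cm, ann, n_perm=99, seed=7)
        b = permutation_test(scores, nm, cm, ann, n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestInteractionMatrix:
    def test_single_nonzero_cell(self, structured):
        cm, ann = structured
        nm, profiles = _small_pipeline(cm, ann, {"LIG", "REC"})
        scores = score_interactions(profiles, [rc.LRPair("LIG", "REC")], require_gof=False)
        mat = interaction_matrix(scores, "LIG", "REC")
        assert mat.shape == (2, 2)
        assert (mat.to_numpy() > 0).sum() == 1
        assert mat.loc["S", "R"] > 0

    def test_entries_match_list(self, fitted_crosstalker):
        scores = fitted_crosstalker.interactions_
        mat = interaction_matrix(scores, "MIF", "CD74")
        for row in scores.query("ligand=='MIF' and receptor=='CD74'").itertuples():
            assert mat.loc[row.sender, row.receiver] == row.strength

    def test_label_order_sorted(self, fitted_crosstalker):
        mat = fitted_crosstalker.interaction_matrix("MIF", "CD74")
        assert list(mat.index) == sorted(mat.index)
        assert list(mat.columns) == sorted(mat.columns)

    def test_unknown_pair_raises(self, fitted_crosstalker):
        with pytest.raises(KeyError):
            fitted_crosstalker.interaction_matrix("NOPE", "NADA")


class TestCoReceptors:
    def test_triads_for_significant_pair(self, fitted_crosstalker):
        tri = fitted_crosstalker.coreceptors_
        tumor_myeloid = tri.query(
            "ligand=='MIF' and receptor=='CD74' and sender=='Tumor' and receiver=='Myeloid'"
        )
        assert set(tumor_myeloid["co_receptor"]) == {"CXCR4", "CD44"}

    def test_breadth_gate_omits_triad(self, fitted_crosstalker):
        model = fitted_crosstalker
        tri = co_receptor_scores(
            model.interactions_, model.profiles_, model.lr_pairs, min_frac=1.01
        )
        assert tri.empty

    def test_no_significant_pairs_empty(self, fitted_crosstalker):
        model = fitted_crosstalker
        scores = model.interactions_.copy()
        scores["q_value"] = 1.0
        tri = co_receptor_scores(scores, model.profiles_, model.lr_pairs)
        assert tri.empty

    def test_co_strength_formula(self, fitted_crosstalker):
        model = fitted_crosstalker
        tri = model.coreceptors_
        row = tri.iloc[0]
        prow = model.profiles_.query(
            "gene == @row.co_receptor and cell_type == @row.receiver"
        ).iloc[0]
        srow = model.interactions_.query(
            "ligand==@row.ligand and receptor==@row.receptor and "
            "sender==@row.sender and receiver==@row.receiver"
        ).iloc[0]
        assert row.co_strength == pytest.approx(srow.strength * prow.mean_expr)
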