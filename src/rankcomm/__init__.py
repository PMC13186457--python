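"""rankcomm: rank-distribution-based ligand-receptor communication inference
for annotated single-cell UMI data.

The method models per-(gene, cell type) expression with the discrete
generalized beta distribution over binned expression ranks — a noise- and
dropout-tolerant summary of how expression mass is distributed — after TMM
and voom normalization, and scores directed sender -> receiver
ligand-receptor interactions with a label-permutation significance test.
"""

from importlib import resources

from .dgbd import (
    DGBDFit,
    RankFrequency,
    dgbd_pmf,
    fit_dgbd,
    gof_dgbd,
    rank_frequency,
)
from .estimators import CrossTalker, DGBDRankModel, TMMVoomNormalizer
from .interactions import (
    co_receptor_scores,
    expression_profiles,
    interaction_matrix,
    permutation_test,
    score_interactions,
)
from .io import (
    CountMatrix,
    LRPair,
    filter_cells,
    read_annotations,
    read_counts,
    read_lr_database,
    write_interactions,
)
from .normalize import NormalizedMatrix, cpm, tmm_factors, voom_transform
from .synthetic import SimConfig, simulate_counts, simulate_dgbd_ranks

__version__ = "0.1.0"


def demo_lr_path():
    """Path to the packaged demo ligand-receptor table (MIF-CD74 and other
    tumor-immune axes with curated co-receptors)."""
    return resources.files("rankcomm").joinpath("data/lr_demo.tsv")


__all__ = [
    "CountMatrix",
    "LRPair",
    "RankFrequency",
    "DGBDFit",
    "NormalizedMatrix",
    "SimConfig",
    "CrossTalker",
    "DGBDRankModel",
    "TMMVoomNormalizer",
    "read_counts",
    "read_annotations",
    "read_lr_database",
    "filter_cells",
    "write_interactions",
    "tmm_factors",
    "cpm",
    "voom_transform",
    "dgbd_pmf",
    "rank_frequency",
    "fit_dgbd",
    "gof_dgbd",
    "expression_profiles",
    "score_interactions",
    "permutation_test",
    "interaction_matrix",
    "co_receptor_scores",
    "simulate_counts",
    "simulate_dgbd_ranks",
    "demo_lr_path",
]
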