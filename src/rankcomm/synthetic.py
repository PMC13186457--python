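"""Seeded synthetic single-cell UMI datasets with planted ligand-receptor
circuits, plus exact DGBD rank-frequency samplers for fitter tests.

Counts follow a negative binomial (mean, size) law with independent
Bernoulli zero-inflation ("dropout"), the minimal generative model carrying
the over-dispersion and sparsity of droplet scRNA-seq. A planted circuit
(ligand, receptor, sender, receiver, fold_change) raises the ligand's mean
in the sender type and the receptor's mean in the receiver type, giving a
known ground truth for recovery tests. No batch effects, doublets or
trajectory structure are modeled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dgbd import RankFrequency, dgbd_pmf
from .exceptions import ConfigError
from .io import CountMatrix, write_annotations, write_counts_mtx

__all__ = ["SimConfig", "simulate_counts", "simulate_dgbd_ranks", "write_dataset"]


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    fold_change entries multiply ``baseline_mean`` for one (gene, cell type);
    ``lr_circuits`` are expanded into planted entries for (ligand, sender)
    and (receptor, receiver).
    """

    n_genes: int = 1000
    cell_types: list[tuple[str, int]] = field(
        default_factory=lambda: [("Tumor", 200), ("Tcell", 200), ("Bcell", 200), ("Myeloid", 200)]
    )
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    dropout: float = 0.3
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    lr_circuits: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.cell_types or any(n < 1 for _, n in self.cell_types):
            raise ConfigError("every cell type needs n_cells >= 1")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if not (0 <= self.dropout < 1):
            raise ConfigError("dropout must be in [0, 1)")
        labels = {t for t, _ in self.cell_types}
        for gene, ct, fc in self.all_planted():
            if fc <= 0:
                raise ConfigError(f"fold_change must be positive ({gene}, {ct})")
            if ct not in labels:
                raise ConfigError(f"planted cell type {ct!r} not among cell_types")
        if len(self.gene_ids()) != self.n_genes:
            raise ConfigError("more named genes than n_genes")

    def all_planted(self) -> list[tuple[str, str, float]]:
        """planted entries plus the expansion of lr_circuits."""
        entries = list(self.planted)
        for lig, rec, sender, receiver, fc in self.lr_circuits:
            entries.append((lig, sender, fc))
            entries.append((rec, receiver, fc))
        return entries

    def gene_ids(self) -> list[str]:
        """Named genes referenced by planted programs first, then G0001..."""
        named: list[str] = []
        for gene, _, _ in self.all_planted():
            if gene not in named:
                named.append(gene)
        pad = [f"G{i:04d}" for i in range(1, self.n_genes - len(named) + 1)]
        return named + pad

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            n_genes=int(raw.get("n_genes", 1000)),
            cell_types=[(str(t), int(n)) for t, n in raw.get("cell_types", cls().cell_types)],
            baseline_mean=float(raw.get("baseline_mean", 0.5)),
            dispersion=float(raw.get("dispersion", 2.0)),
            dropout=float(raw.get("dropout", 0.3)),
            planted=[(str(g), str(t), float(f)) for g, t, f in raw.get("planted", [])],
            lr_circuits=[
                (str(l), str(r), str(s), str(v), float(f))
                for l, r, s, v, f in raw.get("lr_circuits", [])
            ],
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | os.PathLike) -> None:
        raw = {
            "n_genes": self.n_genes,
            "cell_types": [list(x) for x in self.cell_types],
            "baseline_mean": self.baseline_mean,
            "dispersion": self.dispersion,
            "dropout": self.dropout,
            "planted": [list(x) for x in self.planted],
            "lr_circuits": [list(x) for x in self.lr_circuits],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw a (CountMatrix, annotation, truth) triple from the config.

    count ~ NB(mean = baseline_mean * fold_change(gene, type), size =
    dispersion), then zeroed independently with probability ``dropout``.
    Deterministic for a fixed seed. The truth table lists every planted
    (gene, cell_type, fold_change).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = cfg.gene_ids()
    g_pos = {g: i for i, g in enumerate(gene_ids)}
    n_cells = sum(n for _, n in cfg.cell_types)

    fold = {}
    for gene, ct, fc in cfg.all_planted():
        key = (gene, ct)
        fold[key] = max(fold.get(key, 1.0), fc)

    counts = np.empty((cfg.n_genes, n_cells), dtype=np.int64)
    barcodes: list[str] = []
    labels: list[str] = []
    col = 0
    for ct, n in cfg.cell_types:
        means = np.full(cfg.n_genes, cfg.baseline_mean)
        for (gene, ct2), fc in fold.items():
            if ct2 == ct:
                means[g_pos[gene]] = cfg.baseline_mean * fc
        size = cfg.dispersion
        p = size / (size + means)
        block = rng.negative_binomial(size, p[:, None], size=(cfg.n_genes, n))
        if cfg.dropout > 0:
            block = np.where(rng.random(block.shape) < cfg.dropout, 0, block)
        counts[:, col : col + n] = block
        barcodes.extend(f"{ct}_{i:05d}" for i in range(n))
        labels.extend([ct] * n)
        col += n

    cm = CountMatrix(counts, gene_ids, barcodes)
    ann = pd.DataFrame({"barcode": barcodes, "cell_type": labels})
    truth = pd.DataFrame(
        [(g, t, f) for (g, t), f in sorted(fold.items())],
        columns=["gene", "cell_type", "fold_change"],
    )
    return cm, ann, truth


def simulate_dgbd_ranks(
    alpha: float, beta: float, N: int, n: int, seed: int | np.random.Generator = 0
) -> RankFrequency:
    """Sample z ~ Multinomial(n, DGBD(alpha, beta, N)), drop empty ranks,
    re-sort descending. Deterministic per seed."""
    if n < N or N < 1:
        raise ValueError("need n >= N >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.multinomial(n, dgbd_pmf(alpha, beta, N))
    z = z[z > 0]
    return RankFrequency(np.sort(z)[::-1])


def write_dataset(cfg: SimConfig, outdir: str | os.PathLike) -> None:
    """Materialize a simulated dataset as MTX triplet + annotation + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, ann, truth = simulate_counts(cfg)
    write_counts_mtx(cm, outdir / "counts")
    write_annotations(ann, outdir / "annotations.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cfg.to_yaml(outdir / "sim_config.yaml")
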