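"""Functional marker panels: presence matrices, pigmentation calls,
ecotype contrasts and gene-content ordination.

The default panel ships as a YAML asset (``data/marker_panel.yaml``); the
ordination is classical principal coordinates on Jaccard distances over
binarized gene content, with eigenvector signs fixed so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class MarkerPanel:
    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        for name, genes in self.groups:
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate gene names in group {name!r}")

    @property
    def genes(self) -> list[str]:
        out = []
        for _name, genes in self.groups:
            out.extend(g for g in genes if g not in out)
        return out

    def group_of(self, gene: str) -> str | None:
        for name, genes in self.groups:
            if gene in genes:
                return name
        return None

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "MarkerPanel":
        return cls(tuple((k, tuple(v)) for k, v in mapping.items()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "MarkerPanel":
        ref = resources.files("picocult").joinpath("data/marker_panel.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


def marker_matrix(ko: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Copy-number matrix restricted to panel genes (missing gene -> 0).

    ``ko`` is a genomes x genes table of non-negative integer copy
    numbers indexed by genome_id.
    """
    if ko.empty:
        raise ValueError("KO table is empty")
    if not panel.genes:
        raise ValueError("marker panel is empty")
    if ko.index.duplicated().any():
        dups = ko.index[ko.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genome_id rows: {dups}")
    if (ko.to_numpy() < 0).any():
        raise ValueError("copy numbers must be non-negative")
    out = ko.reindex(columns=panel.genes, fill_value=0).fillna(0).astype(int)
    out.index.name = "genome_id"
    return out


def pigment_call(row: Mapping[str, int] | pd.Series) -> str:
    """"red" iff both phycoerythrin genes (cpeA and cpeB) are present."""
    for gene in ("cpeA", "cpeB"):
        if gene not in row:
            raise KeyError(f"marker row lacks required column {gene!r}")
    return "red" if row["cpeA"] >= 1 and row["cpeB"] >= 1 else "green"


def ecotype_contrast(
    matrix: pd.DataFrame,
    ecotype_of_genome: Mapping[str, str],
    focal: str,
    min_focal: float = 0.8,
    max_other: float = 0.2,
) -> list[str]:
    """Genes selectively present in the focal ecotype.

    A gene is diagnostic iff present (copy >= 1) in >= ``min_focal`` of
    focal genomes and in <= ``max_other`` of the genomes of every other
    ecotype.  Requires at least two ecotypes in the labeling.
    """
    labels = pd.Series({g: ecotype_of_genome[g] for g in matrix.index})
    ecotypes = sorted(labels.unique())
    if len(ecotypes) < 2:
        raise ValueError("need at least two ecotypes for a contrast")
    if focal not in ecotypes:
        raise ValueError(f"focal ecotype {focal!r} absent from labels ({ecotypes})")
    present = matrix >= 1
    focal_rate = present.loc[labels[labels == focal].index].mean()
    diagnostic = focal_rate >= min_focal
    for other in ecotypes:
        if other == focal:
            continue
        other_rate = present.loc[labels[labels == other].index].mean()
        diagnostic &= other_rate <= max_other
    return [g for g in matrix.columns if diagnostic[g]]


def jaccard_distances(ko: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distance on binarized gene content."""
    binary = (ko.to_numpy() >= 1)
    if (~binary.any(axis=1)).any():
        empty = list(ko.index[~binary.any(axis=1)])
        raise ValueError(f"all-zero gene profiles (Jaccard undefined): {empty}")
    d = squareform(pdist(binary, metric="jaccard"))
    return pd.DataFrame(d, index=ko.index, columns=ko.index)


def gene_content_ordination(ko: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Classical PCoA embedding of genomes by gene-content Jaccard distance.

    Deterministic: each axis's sign is fixed so its largest-magnitude
    coordinate is positive.  Returns a (genomes x n_axes) frame with
    columns PCo1, PCo2, ...
    """
    if len(ko) < 3:
        raise ValueError("ordination needs at least 3 genomes")
    dist = jaccard_distances(ko).to_numpy()
    n = dist.shape[0]
    d2 = dist**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:n_axes]
    coords = np.zeros((n, n_axes))
    for axis, idx in enumerate(order):
        lam = eigvals[idx]
        vec = eigvecs[:, idx] * np.sqrt(max(lam, 0.0))
        peak = np.argmax(np.abs(vec))
        if vec[peak] < 0:
            vec = -vec
        coords[:, axis] = vec
    return pd.DataFrame(
        coords, index=ko.index, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
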