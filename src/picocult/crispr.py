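"""CRISPR-Cas profiling: operon-completeness calls, per-group prevalence
reports, Cas1 hit curation and greedy identity-threshold protein clustering.

The subtype gene requirements ship as an editable YAML asset
(``data/cas_subtypes.yaml``).  Low-quality gene matches count toward
completeness but stay flagged in the locus table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import Align

from .cooccurrence import round_half_up

LOCUS_COLUMNS = [
    "genome_id",
    "locus_id",
    "subtype",
    "gene_name",
    "gene_quality",
    "n_spacers_in_locus",
]


class SubtypeSchema:
    """Adaptation/interference gene requirements per CRISPR-Cas subtype.

    Interference requirements are lists whose entries are either a gene
    name or a list of synonymous names (any one suffices).
    """

    def __init__(self, adaptation: Sequence[str], interference: Mapping[str, Sequence]):
        if "cas1" not in adaptation:
            raise ValueError("adaptation gene set must include cas1")
        self.adaptation = list(adaptation)
        self.interference = {
            subtype: [[g] if isinstance(g, str) else list(g) for g in genes]
            for subtype, genes in interference.items()
        }
        for subtype, genes in self.interference.items():
            if not genes:
                raise ValueError(f"empty interference set for subtype {subtype}")

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.interference)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubtypeSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw["adaptation"], raw["interference"])

    @classmethod
    def default(cls) -> "SubtypeSchema":
        ref = resources.files("picocult").joinpath("data/cas_subtypes.yaml")
        raw = yaml.safe_load(ref.read_text())
        return cls(raw["adaptation"], raw["interference"])


@dataclass(frozen=True)
class Cas1Config:
    max_p_value: float = 0.01   # strict <
    min_length_aa: int = 80     # strict >
    top_k: int = 10
    cluster_identity: float = 0.90
    cluster_coverage: float = 0.80

    def __post_init__(self):
        for name in ("max_p_value", "min_length_aa", "top_k",
                     "cluster_identity", "cluster_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def locus_completeness(
    locus_rows: pd.DataFrame, schema: SubtypeSchema | None = None
) -> tuple[bool, bool, bool]:
    """(adaptation_complete, interference_complete, cas1_less_with_spacers)
    for the rows of a single locus.

    Genes of any quality count.  An empty row set yields (False, False,
    False).
    """
    schema = schema or SubtypeSchema.default()
    if locus_rows.empty:
        return False, False, False
    subtypes = set(locus_rows["subtype"])
    if len(subtypes) != 1:
        raise ValueError(f"rows span multiple subtypes: {sorted(subtypes)}")
    (subtype,) = subtypes
    if subtype not in schema.interference:
        raise KeyError(
            f"unknown subtype {subtype!r}; known subtypes: {schema.subtypes}"
        )
    genes = set(locus_rows["gene_name"])
    adaptation_complete = all(g in genes for g in schema.adaptation)
    interference_complete = all(
        any(syn in genes for syn in requirement)
        for requirement in schema.interference[subtype]
    )
    n_spacers = int(locus_rows["n_spacers_in_locus"].iloc[0])
    cas1_less_with_spacers = "cas1" not in genes and n_spacers >= 1
    return adaptation_complete, interference_complete, cas1_less_with_spacers


def prevalence_by_group(
    loci: pd.DataFrame, group_of_genome: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group CRISPR-Cas prevalence report.

    A genome is positive when it has >= 1 locus; a positive genome "lacks
    cas1" when no locus of that genome contains a cas1 gene.  Percentages
    are reported rounded half-up to one decimal alongside the raw
    fractions; groups with zero genomes are omitted with a warning.
    """
    unknown = set(loci["genome_id"]) - set(group_of_genome)
    if unknown:
        raise KeyError(f"genomes without group assignment: {sorted(unknown)}")
    groups = pd.Series(dict(group_of_genome), name="group")
    rows = []
    for group, members in groups.groupby(groups).groups.items():
        members = list(members)
        if not members:
            warnings.warn(f"group {group!r} has zero genomes; omitted")
            continue
        sub = loci[loci["genome_id"].isin(members)]
        positives = sorted(set(sub["genome_id"]))
        has_cas1 = set(sub.loc[sub["gene_name"] == "cas1", "genome_id"])
        lacking = [g for g in positives if g not in has_cas1]
        subtype_counts = (
            sub.drop_duplicates(["genome_id", "locus_id"])
            .groupby("subtype")["genome_id"]
            .nunique()
            .to_dict()
        )
        frac_pos = len(positives) / len(members)
        frac_lacking = len(lacking) / len(positives) if positives else 0.0
        rows.append(
            {
                "group": group,
                "n_genomes": len(members),
                "n_with_system": len(positives),
                "fraction_with_system": frac_pos,
                "percent_with_system": round_half_up(100 * frac_pos),
                "n_lacking_cas1": len(lacking),
                "fraction_lacking_cas1": frac_lacking,
                "percent_lacking_cas1": round_half_up(100 * frac_lacking),
                "subtype_counts": subtype_counts,
            }
        )
    return pd.DataFrame(rows)


def cas1_filter_hits(hits: pd.DataFrame, config: Cas1Config | None = None) -> list[str]:
    """Retain hits with p-value strictly below and length strictly above
    the thresholds."""
    config = config or Cas1Config()
    if hits.empty:
        raise ValueError("empty hit table")
    if (hits["length_aa"] < 0).any():
        raise ValueError("negative sequence length in hit table")
    keep = (hits["p_value"] < config.max_p_value) & (
        hits["length_aa"] > config.min_length_aa
    )
    return list(hits.loc[keep, "seq_id"])


def topk_neighbors(
    similarities: pd.DataFrame, k: int = 10
) -> dict[str, list[str]]:
    """Top-k highest-scoring targets per query; ties broken by target id.

    ``similarities`` has columns (query_id, target_id, score).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[str]] = {}
    for query, sub in similarities.groupby("query_id", sort=True):
        ranked = sub.sort_values(
            ["score", "target_id"], ascending=[False, True], kind="stable"
        )
        out[query] = list(ranked["target_id"].head(k))
    return out


def _make_aligner(config: Cas1Config) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def alignment_identity(
    a: str, b: str, aligner: Align.PairwiseAligner
) -> tuple[float, float, float]:
    """Global-alignment identity and mutual coverage of two proteins.

    Identity = matches / alignment columns excluding terminal gaps;
    coverage of each sequence = residues inside the non-terminal-gap
    region / sequence length.
    """
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    cols = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    if not cols:
        return 0.0, 0.0, 0.0
    first, last = cols[0], cols[-1]
    span_a = ga[first : last + 1]
    span_b = gb[first : last + 1]
    ncols = last - first + 1
    matches = sum(1 for x, y in zip(span_a, span_b) if x == y and x != "-")
    cov_a = sum(1 for x in span_a if x != "-") / len(a)
    cov_b = sum(1 for y in span_b if y != "-") / len(b)
    return matches / ncols, cov_a, cov_b


def greedy_cluster(
    sequences: Mapping[str, str], config: Cas1Config | None = None
) -> pd.DataFrame:
    """Greedy incremental clustering at an identity/coverage threshold.

    Sequences are processed longest-first (ties by id); each joins the
    first existing centroid with identity >= cluster_identity and
    bidirectional coverage >= cluster_coverage, else founds a new cluster.
    Returns a table (seq_id, centroid_id).
    """
    config = config or Cas1Config()
    if not sequences:
        raise ValueError("no sequences to cluster")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence: {sid}")
    aligner = _make_aligner(config)
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    centroids: list[str] = []
    assignment: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid]
        for cid in centroids:
            identity, cov_a, cov_b = alignment_identity(seq, sequences[cid], aligner)
            if (
                identity >= config.cluster_identity
                and cov_a >= config.cluster_coverage
                and cov_b >= config.cluster_coverage
            ):
                assignment[sid] = cid
                break
        else:
            centroids.append(sid)
            assignment[sid] = sid
    return pd.DataFrame(
        {"seq_id": list(sequences), "centroid_id": [assignment[s] for s in sequences]}
    )


def curate_cas1(
    hits: pd.DataFrame,
    similarities: pd.DataFrame,
    sequences: Mapping[str, str],
    config: Cas1Config | None = None,
) -> dict[str, str]:
    """Full curation chain: p-value/length filter -> top-k neighbor union
    -> greedy clustering; returns the centroid sequences."""
    config = config or Cas1Config()
    retained = set(cas1_filter_hits(hits, config))
    sim = similarities[
        similarities["query_id"].isin(retained)
        & similarities["target_id"].isin(retained)
    ]
    selected: set[str] = set(sim["query_id"].unique())
    for targets in topk_neighbors(sim, config.top_k).values():
        selected.update(targets)
    pool = {s: sequences[s] for s in sorted(selected) if s in sequences}
    if not pool:
        return {}
    clusters = greedy_cluster(pool, config)
    return {c: sequences[c] for c in sorted(clusters["centroid_id"].unique())}
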