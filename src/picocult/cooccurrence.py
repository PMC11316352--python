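"""Prevalence filtering and ecotype x taxon co-occurrence (heat-tree) tables.

Counting is culture-level: a taxon present through several genomes in one
culture counts once.  The prevalence denominator is all cultures in the
presence matrix.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching reported-percentage style."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class PresenceMatrix:
    culture_ids: list[str]
    genome_ids: list[str]
    presence: np.ndarray  # bool, cultures x genomes
    ecotype_of_culture: dict[str, str]

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.culture_ids), len(self.genome_ids)):
            raise ValueError("presence matrix shape does not match id lists")
        missing = [c for c in self.culture_ids if c not in self.ecotype_of_culture]
        if missing:
            raise ValueError(f"cultures without ecotype label: {missing}")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, ecotype_of_culture: Mapping[str, str]
    ) -> "PresenceMatrix":
        """Build from a cultures x genomes 0/1 DataFrame."""
        return cls(
            list(df.index),
            list(df.columns),
            df.to_numpy(dtype=bool),
            dict(ecotype_of_culture),
        )


@dataclass(frozen=True)
class PrevalenceConfig:
    min_culture_fraction: float = 0.05  # strict >

    def __post_init__(self):
        if not 0 < self.min_culture_fraction < 1:
            raise ValueError("min_culture_fraction must be in (0, 1)")


class TaxonomyTable:
    """genome_id -> ranked lineage (domain .. species)."""

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self.lineages = {}
        for gid, lineage in lineages.items():
            lineage = [str(x) for x in lineage]
            if len(lineage) > len(RANKS):
                raise ValueError(f"lineage for {gid} has more than {len(RANKS)} ranks")
            if any(not x for x in lineage):
                raise ValueError(f"empty rank name in lineage for {gid}")
            self.lineages[gid] = list(lineage)

    @classmethod
    def from_strings(cls, mapping: Mapping[str, str], sep: str = ";") -> "TaxonomyTable":
        return cls({g: s.split(sep) for g, s in mapping.items()})

    def name_at(self, genome_id: str, rank: str) -> str:
        i = RANKS.index(rank)
        lineage = self.lineages[genome_id]
        if i >= len(lineage):
            raise KeyError(f"{genome_id} has no {rank}-level name")
        return lineage[i]


def prevalence_filter(
    matrix: PresenceMatrix, config: PrevalenceConfig | None = None
) -> pd.DataFrame:
    """Per-genome prevalence with a strict > threshold retention flag."""
    config = config or PrevalenceConfig()
    n_cultures = len(matrix.culture_ids)
    if n_cultures == 0:
        raise ValueError("presence matrix has no cultures")
    prevalence = matrix.presence.sum(axis=0) / n_cultures
    return pd.DataFrame(
        {
            "genome_id": matrix.genome_ids,
            "n_cultures_present": matrix.presence.sum(axis=0),
            "prevalence": prevalence,
            "retained": prevalence > config.min_culture_fraction,
        }
    )


def _culture_sets_by_taxon(
    matrix: PresenceMatrix, taxonomy: TaxonomyTable, rank: str, genome_ids: Sequence[str]
) -> dict[str, set[str]]:
    """taxon name -> set of culture ids where >= 1 member genome is present."""
    missing = [g for g in genome_ids if g not in taxonomy.lineages]
    if missing:
        raise KeyError(f"genome(s) missing from taxonomy: {missing}")
    col_of = {g: i for i, g in enumerate(matrix.genome_ids)}
    sets: dict[str, set[str]] = {}
    for gid in genome_ids:
        taxon = taxonomy.name_at(gid, rank)
        cultures = {
            matrix.culture_ids[i]
            for i in np.nonzero(matrix.presence[:, col_of[gid]])[0]
        }
        sets.setdefault(taxon, set()).update(cultures)
    return sets


def cooccurrence_counts(
    matrix: PresenceMatrix,
    taxonomy: TaxonomyTable,
    level: str = "genus",
    genome_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ecotype x taxon co-occurrence counts at one taxonomic rank.

    Cell (e, t) = number of cultures of ecotype e containing >= 1 genome of
    taxon t.  ``genome_ids`` restricts to (e.g. prevalence-retained)
    genomes; default all.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    genome_ids = list(genome_ids) if genome_ids is not None else matrix.genome_ids
    sets = _culture_sets_by_taxon(matrix, taxonomy, level, genome_ids)
    ecotypes = sorted(set(matrix.ecotype_of_culture[c] for c in matrix.culture_ids))
    taxa = sorted(sets)
    data = {
        t: [
            sum(1 for c in sets[t] if matrix.ecotype_of_culture[c] == e)
            for e in ecotypes
        ]
        for t in taxa
    }
    return pd.DataFrame(data, index=pd.Index(ecotypes, name="ecotype"))


def heat_tree_table(
    matrix: PresenceMatrix,
    taxonomy: TaxonomyTable,
    genome_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Node table over every rank of the lineage tree.

    One row per taxon at each rank with the number of genomes under the
    taxon and per-ecotype culture-level co-occurrence counts (unions over
    child taxa, so a parent's count is >= each child's).
    """
    genome_ids = list(genome_ids) if genome_ids is not None else matrix.genome_ids
    ecotypes = sorted(set(matrix.ecotype_of_culture[c] for c in matrix.culture_ids))
    rows = []
    for rank_i, rank in enumerate(RANKS):
        with_rank = [
            g for g in genome_ids if len(taxonomy.lineages.get(g, [])) > rank_i
        ]
        if not with_rank:
            continue
        sets = _culture_sets_by_taxon(matrix, taxonomy, rank, with_rank)
        n_genomes = {}
        for g in with_rank:
            n_genomes[taxonomy.name_at(g, rank)] = (
                n_genomes.get(taxonomy.name_at(g, rank), 0) + 1
            )
        for taxon in sorted(sets):
            row = {
                "taxon": taxon,
                "rank": rank,
                "n_genomes": n_genomes[taxon],
            }
            for e in ecotypes:
                row[f"count_{e}"] = sum(
                    1 for c in sets[taxon] if matrix.ecotype_of_culture[c] == e
                )
            rows.append(row)
    return pd.DataFrame(rows)


def ecotype_shares(assignments: Mapping[str, str]) -> pd.DataFrame:
    """Share of genomes per group label, as printed percentages.

    Returns (label, n, percent) with percent = 100 * n / total rounded
    half-up to one decimal.
    """
    if not assignments:
        raise ValueError("no assignments given")
    counts = pd.Series(list(assignments.values())).value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "label": counts.index,
            "n": counts.to_numpy(),
            "percent": [round_half_up(100.0 * n / total) for n in counts],
        }
    )
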