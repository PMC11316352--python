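"""Pairwise average nucleotide identity and identity-threshold clustering.

The estimator is fragment-based and fully deterministic: the query is cut
into non-overlapping fixed-length fragments, each fragment is placed on the
reference (either strand) by exact k-mer seeding followed by ungapped
evaluation over the whole fragment, and the best placement's identity is
kept.  Fragments at or above the identity floor count as aligned; ANI is
the mean identity of aligned fragments.  Directed estimates are
symmetrized by arithmetic mean.

Species and population partitions are connected components of the graph
with an edge wherever ANI >= cutoff (single linkage), so the partition at
a lower cutoff is always a coarsening of the one at a higher cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from . import _seq
from .synthetic import GenomeRecord


@dataclass(frozen=True)
class AniConfig:
    fragment_length: int = 1000
    kmer_size: int = 16
    min_fragment_identity: float = 0.80
    min_aligned_fraction: float = 0.20
    species_cutoff: float = 0.95
    population_cutoff: float = 0.85
    max_candidates_per_fragment: int = 64

    def __post_init__(self):
        if not self.population_cutoff < self.species_cutoff:
            raise ValueError("population_cutoff must be below species_cutoff")
        for name in ("min_fragment_identity", "min_aligned_fraction",
                     "species_cutoff", "population_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class AniMatrix:
    genome_ids: list[str]
    ani: np.ndarray              # fractions; NaN = missing
    aligned_fraction: np.ndarray

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.genome_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (
                        self.genome_ids[i],
                        self.genome_ids[j],
                        self.ani[i, j],
                        self.aligned_fraction[i, j],
                    )
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "ani", "aligned_fraction"])


def _best_fragment_identity(
    frag: np.ndarray,
    ref: np.ndarray,
    index: _seq.KmerIndex,
    config: AniConfig,
) -> float | None:
    """Best ungapped placement identity of one fragment, either strand.

    Identity denominator is the full fragment length; reference overhangs
    count as mismatches.  Returns None when no seed matches at all.
    """
    flen = frag.shape[0]
    best = -1.0
    for strand_frag in (frag, (3 - frag)[::-1]):
        kpos, kmers = _seq.kmer_codes(strand_frag, index.k)
        if kpos.size == 0:
            continue
        lo = np.searchsorted(index._sorted_kmers, kmers, side="left")
        hi = np.searchsorted(index._sorted_kmers, kmers, side="right")
        owner, flat = _seq.expand_ranges(lo, hi)
        if flat.size == 0:
            continue
        offsets = index._sorted_pos[flat] - kpos[owner]
        cand, votes = np.unique(offsets, return_counts=True)
        if cand.size > config.max_candidates_per_fragment:
            order = np.lexsort((cand, -votes))[: config.max_candidates_per_fragment]
            cand = cand[order]
        for off in cand:
            off = int(off)
            identity, aligned = _seq.ungapped_identity(ref, strand_frag, off)
            score = identity * aligned / flen  # matches / fragment_length
            if score > best:
                best = score
    return None if best < 0 else best


def directed_ani(
    query: GenomeRecord, reference: GenomeRecord, config: AniConfig | None = None
) -> tuple[float | None, float]:
    """One-directional fragment-recruitment ANI of ``query`` on ``reference``.

    Returns ``(ani, aligned_fraction)``; ani is None when the aligned
    fraction falls below ``config.min_aligned_fraction``.
    """
    config = config or AniConfig()
    flen = config.fragment_length
    if len(query.sequence) < flen or len(reference.sequence) < flen:
        raise ValueError(f"both sequences must be >= fragment_length ({flen} bp)")
    qcodes = _seq.encode(query.sequence)
    rcodes = _seq.encode(reference.sequence)
    index = _seq.KmerIndex(rcodes, config.kmer_size)

    n_fragments = qcodes.shape[0] // flen
    identities = []
    for i in range(n_fragments):
        frag = qcodes[i * flen : (i + 1) * flen]
        ident = _best_fragment_identity(frag, rcodes, index, config)
        if ident is not None and ident >= config.min_fragment_identity:
            identities.append(ident)
    aligned_fraction = len(identities) / n_fragments
    if aligned_fraction < config.min_aligned_fraction:
        return None, aligned_fraction
    return float(np.mean(identities)), aligned_fraction


def ani_matrix(
    genomes: Sequence[GenomeRecord], config: AniConfig | None = None
) -> AniMatrix:
    """All-pairs symmetric ANI (mean of the two directed estimates)."""
    config = config or AniConfig()
    if len(genomes) < 2:
        raise ValueError("ani_matrix needs at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in collection")
    n = len(genomes)
    ani = np.full((n, n), np.nan)
    af = np.zeros((n, n))
    np.fill_diagonal(ani, 1.0)
    np.fill_diagonal(af, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a_ij, f_ij = directed_ani(genomes[i], genomes[j], config)
            a_ji, f_ji = directed_ani(genomes[j], genomes[i], config)
            vals = [v for v in (a_ij, a_ji) if v is not None]
            # one informative direction is enough; missing only if both miss
            ani[i, j] = ani[j, i] = float(np.mean(vals)) if vals else np.nan
            af[i, j] = af[j, i] = (f_ij + f_ji) / 2
    return AniMatrix(ids, ani, af)


def cluster_at(matrix: AniMatrix, cutoff: float) -> pd.DataFrame:
    """Single-linkage clusters: connected components of the ANI >= cutoff graph.

    Cluster labels are the lexicographically smallest member id.  Returns a
    DataFrame (genome_id, cluster) ordered as the input matrix.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    ids = matrix.genome_ids
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.ani[i, j]
            if not np.isnan(v) and v >= cutoff:
                parent[find(i)] = find(j)
    members: dict[int, list[str]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(ids[i])
    label_of = {}
    for group in members.values():
        label = min(group)
        for gid in group:
            label_of[gid] = label
    return pd.DataFrame({"genome_id": ids, "cluster": [label_of[g] for g in ids]})


def heatmap_order(matrix: AniMatrix) -> list[str]:
    """Leaf order from average-linkage clustering on 1 - ANI (missing -> 1)."""
    d = 1.0 - np.where(np.isnan(matrix.ani), 0.0, matrix.ani)
    np.fill_diagonal(d, 0.0)
    d[np.isnan(matrix.ani)] = 1.0
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    return [matrix.genome_ids[i] for i in leaves_list(link)]
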