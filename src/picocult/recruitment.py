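"""Read recruitment: masking, subsampling, seeded ungapped mapping,
coverage statistics and breadth-based presence calls.

Mapping places each read by exact 15-mer seeding on either strand followed
by ungapped evaluation at every candidate diagonal; the single best
placement (highest identity, ties broken by leftmost start, then forward
strand) is reported iff it passes the identity / read-coverage / length
filters.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seq
from .synthetic import GenomeRecord

MAP_KMER = 15


@dataclass(frozen=True)
class RecruitConfig:
    min_identity: float = 0.95
    min_read_coverage: float = 0.90
    min_alignment_length: int = 50
    subsample_reads: int = 20_000_000
    presence_breadth: float = 0.95
    seed: int = 0

    def __post_init__(self):
        for name in ("min_identity", "min_read_coverage", "presence_breadth"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_alignment_length < 1:
            raise ValueError("min_alignment_length must be >= 1")


@dataclass(frozen=True)
class CoverageProfile:
    genome_id: str
    sample_id: str
    aligned_bases: int
    effective_genome_length: int
    breadth: float
    depth: float
    coverage_per_gb: float


def mask_intervals(
    genome: GenomeRecord, intervals: Sequence[tuple[int, int]]
) -> GenomeRecord:
    """Replace interval positions (0-based, half-open) with N.

    Masked positions are excluded from k-mer seeding, the breadth
    numerator and the effective genome length downstream.
    """
    n = genome.length_bp
    for start, end in intervals:
        if start < 0 or end > n or start >= end:
            raise ValueError(f"invalid interval [{start}, {end}) on {n} bp genome")
    if not intervals:
        return genome
    codes = _seq.encode(genome.sequence)
    for start, end in intervals:
        codes[start:end] = 4
    return genome.with_sequence(_seq.decode(codes))


def subsample(
    reads: Sequence[tuple[str, str, str]], n: int, seed: int
) -> list[tuple[str, str, str]]:
    """Uniform sample of exactly ``n`` reads without replacement.

    Returns all reads when fewer than ``n`` exist; sampled reads keep
    their original order.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(reads) <= n:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in keep]


def _read_kmer_matrix(mat: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer codes along axis 1; windows with N get code -1.

    Codes follow the same base-4 convention as :func:`picocult._seq.kmer_codes`
    (weight 4**j for in-window position j).
    """
    n, length = mat.shape
    m = length - k + 1
    vals = np.where(mat == 4, 0, mat).astype(np.int64)
    weights = 4 ** np.arange(k, dtype=np.int64)
    codes = np.empty((n, m), dtype=np.int64)
    codes[:, 0] = vals[:, :k] @ weights
    top = np.int64(4 ** (k - 1))
    for i in range(1, m):
        codes[:, i] = (codes[:, i - 1] - vals[:, i - 1]) // 4 + vals[:, i + k - 1] * top
    # invalidate windows containing N
    cs = np.cumsum(mat == 4, axis=1)
    n_count = cs[:, k - 1 :].copy()
    n_count[:, 1:] -= cs[:, : m - 1]
    codes[n_count > 0] = -1
    return codes


class _ReadBatch:
    """Reads of one common length, encoded once for reuse across genomes."""

    def __init__(self, idxs: list[int], reads: Sequence[tuple[str, str, str]]):
        self.idxs = idxs
        self.fwd = np.stack([_seq.encode(reads[i][1]) for i in idxs])
        rev = (3 - self.fwd[:, ::-1]) % 5  # revcomp; N (code 4) stays 4
        rev[self.fwd[:, ::-1] == 4] = 4
        self.rev = rev
        # per strand: (n_kmer_positions, sorted flat kmer codes, argsort order)
        self.kmers: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        for strand, mat in (("+", self.fwd), ("-", rev)):
            km = _read_kmer_matrix(mat, MAP_KMER)
            flat = km.ravel()
            order = np.argsort(flat, kind="stable")
            self.kmers[strand] = (km.shape[1], flat[order], order)


def _prepare_batches(reads: Sequence[tuple[str, str, str]]) -> list[_ReadBatch]:
    by_len: dict[int, list[int]] = {}
    for i, (_rid, seq, _q) in enumerate(reads):
        by_len.setdefault(len(seq), []).append(i)
    return [
        _ReadBatch(idxs, reads)
        for length, idxs in sorted(by_len.items())
        if length >= MAP_KMER
    ]


def map_reads_multi(
    reads: Sequence[tuple[str, str, str]],
    genomes: Sequence[GenomeRecord],
    config: RecruitConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Map one read set against several genomes, encoding reads only once.

    Returns ``{genome_id: alignment table}``; see :func:`map_reads` for the
    table layout.
    """
    config = config or RecruitConfig()
    columns = ["read_id", "genome_id", "start", "end", "strand", "identity",
               "aligned_length"]
    batches = _prepare_batches(reads) if len(reads) else []
    out: dict[str, pd.DataFrame] = {}
    for genome in genomes:
        ref = _seq.encode(genome.sequence)
        if int((ref != 4).sum()) < MAP_KMER:
            raise ValueError(
                f"{genome.genome_id} has fewer unmasked positions than the seed size"
            )
        index = _seq.KmerIndex(ref, MAP_KMER)
        out_rows: list[tuple] = []
        for batch in batches:
            length = batch.fwd.shape[1]
            best = _map_batch(batch, ref, index, config)
            for row_i, placement in enumerate(best):
                if placement is None:
                    continue
                start, strand, matches, aligned = placement
                identity = matches / aligned
                if (
                    identity >= config.min_identity
                    and aligned / length >= config.min_read_coverage
                    and aligned >= config.min_alignment_length
                ):
                    out_rows.append(
                        (
                            reads[batch.idxs[row_i]][0],
                            genome.genome_id,
                            max(start, 0),
                            min(start + length, ref.shape[0]),
                            strand,
                            identity,
                            aligned,
                        )
                    )
        df = pd.DataFrame(out_rows, columns=columns)
        out[genome.genome_id] = (
            df.sort_values(["read_id"], kind="stable").reset_index(drop=True)
        )
    return out


def map_reads(
    reads: Sequence[tuple[str, str, str]],
    genome: GenomeRecord,
    config: RecruitConfig | None = None,
) -> pd.DataFrame:
    """Map reads to one (possibly masked) genome.

    Returns a table (read_id, genome_id, start, end, strand, identity,
    aligned_length) with at most one row per read.  Identity is computed
    over the ungapped extension clipped at the genome ends; masked (N)
    genome positions never match.
    """
    return map_reads_multi(reads, [genome], config)[genome.genome_id]


def _strand_candidates(
    kmers: tuple[int, np.ndarray, np.ndarray], index: _seq.KmerIndex, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unique (read_index, diagonal_offset) seed candidates for one strand.

    The genome's (deduplicated) k-mers are searched against the batch's
    pre-sorted read k-mers, so the per-genome cost scales with genome size
    rather than read count.
    """
    n_kpos, sorted_flat, order = kmers
    gk, g_first = np.unique(index._sorted_kmers, return_index=True)
    lo = np.searchsorted(sorted_flat, gk, side="left")
    hi = np.searchsorted(sorted_flat, gk, side="right")
    hit = hi > lo
    if not hit.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # expand genome-side duplicates only for k-mers that hit any read
    g_counts = np.diff(np.append(g_first, index._sorted_kmers.shape[0]))
    owner_g, g_slot = _seq.expand_ranges(g_first[hit], (g_first + g_counts)[hit])
    gpos = index._sorted_pos[g_slot]
    lo_h, hi_h = lo[hit], hi[hit]
    owner, read_slot = _seq.expand_ranges(lo_h[owner_g], hi_h[owner_g])
    flat_idx = order[read_slot]
    read_idx = flat_idx // n_kpos
    kpos = flat_idx % n_kpos
    offsets = np.repeat(gpos, (hi_h - lo_h)[owner_g]) - kpos
    span = index.length + 2 * length
    keys = np.unique(read_idx * span + (offsets + length))
    return keys // span, keys % span - length


def _map_batch(
    batch: "_ReadBatch",
    ref: np.ndarray,
    index: _seq.KmerIndex,
    config: RecruitConfig,
) -> list[tuple[int, str, int, int] | None]:
    """Best placement per read: (start, strand, matches, aligned_length).

    Ranking: highest identity, then leftmost clipped start, then forward
    strand before reverse.
    """
    fwd, rev = batch.fwd, batch.rev
    n, length = fwd.shape
    glen = ref.shape[0]
    windows = (
        np.lib.stride_tricks.sliding_window_view(ref, length) if glen >= length else None
    )

    reads_all, offs_all, strands_all, matches_all, aligned_all = [], [], [], [], []
    for strand_code, mat in ((0, fwd), (1, rev)):
        r_idx, offs = _strand_candidates(batch.kmers["+" if strand_code == 0 else "-"], index, length)
        if r_idx.size == 0:
            continue
        full = (offs >= 0) & (offs <= glen - length) if windows is not None else np.zeros(r_idx.shape, bool)
        if full.any():
            w = windows[offs[full]]
            q = mat[r_idx[full]]
            m = ((w == q) & (w != 4)).sum(axis=1)
            reads_all.append(r_idx[full])
            offs_all.append(offs[full])
            strands_all.append(np.full(int(full.sum()), strand_code))
            matches_all.append(m)
            aligned_all.append(np.full(int(full.sum()), length))
        for r, off in zip(r_idx[~full], offs[~full]):
            identity, aligned = _seq.ungapped_identity(ref, mat[r], int(off))
            if aligned == 0:
                continue
            reads_all.append(np.array([r]))
            offs_all.append(np.array([off]))
            strands_all.append(np.array([strand_code]))
            matches_all.append(np.array([int(round(identity * aligned))]))
            aligned_all.append(np.array([aligned]))

    results: list[tuple[int, str, int, int] | None] = [None] * n
    if not reads_all:
        return results
    r = np.concatenate(reads_all)
    off = np.concatenate(offs_all)
    strand = np.concatenate(strands_all)
    matches = np.concatenate(matches_all)
    aligned = np.concatenate(aligned_all)
    identity = matches / aligned
    start_clip = np.maximum(off, 0)
    order = np.lexsort((strand, start_clip, -identity, r))
    r_sorted = r[order]
    first = np.ones(order.shape[0], dtype=bool)
    first[1:] = r_sorted[1:] != r_sorted[:-1]
    for k in order[first]:
        results[int(r[k])] = (
            int(off[k]),
            "+" if strand[k] == 0 else "-",
            int(matches[k]),
            int(aligned[k]),
        )
    return results


def coverage_stats(
    alignments: pd.DataFrame,
    genome: GenomeRecord,
    total_sampled_bases: int,
    sample_id: str = "sample",
) -> CoverageProfile:
    """Depth/breadth profile of one genome, excluding masked positions.

    depth = aligned bases on unmasked positions / effective length;
    breadth = unmasked positions covered >= 1x / effective length;
    coverage_per_gb = depth / (total_sampled_bases / 1e9).
    """
    codes = _seq.encode(genome.sequence)
    unmasked = codes != 4
    effective = int(unmasked.sum())
    if effective == 0:
        raise ValueError("effective genome length is zero (fully masked)")
    depth_arr = np.zeros(codes.shape[0] + 1, dtype=np.int64)
    for start, end in zip(alignments.get("start", []), alignments.get("end", [])):
        depth_arr[start] += 1
        depth_arr[end] -= 1
    depth_arr = np.cumsum(depth_arr[:-1])
    depth_arr[~unmasked] = 0
    aligned_bases = int(depth_arr.sum())
    breadth = float((depth_arr > 0).sum() / effective)
    depth = aligned_bases / effective
    cov_per_gb = depth / (total_sampled_bases / 1e9) if total_sampled_bases else 0.0
    return CoverageProfile(
        genome_id=genome.genome_id,
        sample_id=sample_id,
        aligned_bases=aligned_bases,
        effective_genome_length=effective,
        breadth=breadth,
        depth=depth,
        coverage_per_gb=cov_per_gb,
    )


def presence_call(profile: CoverageProfile, config: RecruitConfig | None = None) -> bool:
    """Present iff breadth is strictly above the presence threshold."""
    config = config or RecruitConfig()
    return profile.breadth > config.presence_breadth
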