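"""Taxonomy-based contig decontamination, CheckM-style QC gate, bin naming.

A bin's consensus class is the plurality class over all its genes
(off-target labels excluded), computed once on the full bin.  A contig is
dropped when its off-target gene fraction is strictly above the threshold,
or when its own plurality class disagrees with the bin consensus, or both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

OFFTARGET_LABELS = frozenset({"no_hit", "eukaryote", "virus"})
METHOD_CODES = {"maxbin": "mx", "metabat1": "m1", "metabat2": "m2"}

GENE_TABLE_COLUMNS = ["bin_id", "contig_id", "gene_index", "class_call"]


@dataclass(frozen=True)
class DecontamConfig:
    max_offtarget_fraction: float = 0.30
    offtarget_labels: frozenset[str] = OFFTARGET_LABELS

    def __post_init__(self):
        if not 0 < self.max_offtarget_fraction < 1:
            raise ValueError("max_offtarget_fraction must be in (0, 1)")


@dataclass(frozen=True)
class BinStats:
    bin_id: str
    completeness: float
    contamination: float

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")


@dataclass(frozen=True)
class QCThresholds:
    min_completeness: float = 80.0
    max_contamination: float = 5.0

    def __post_init__(self):
        if self.min_completeness < 0 or self.max_contamination < 0:
            raise ValueError("thresholds must be non-negative")


class NoConsensusError(ValueError):
    """Raised when every gene in a bin is off-target."""


def _validate_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_TABLE_COLUMNS[1:] if c not in table.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if table.empty:
        raise ValueError("gene table is empty")
    if table.duplicated(["contig_id", "gene_index"]).any():
        raise ValueError("duplicate (contig_id, gene_index) rows")
    return table


def _plurality(calls: pd.Series, offtarget: frozenset[str]) -> str | None:
    """Plurality class among classified genes; lexicographic tie-break."""
    counts = Counter(c for c in calls if c not in offtarget)
    if not counts:
        return None
    best = max(counts.values())
    return min(c for c, n in counts.items() if n == best)


def consensus_class(
    table: pd.DataFrame, config: DecontamConfig | None = None
) -> str:
    """Plurality class over all genes of the bin, off-target labels excluded."""
    config = config or DecontamConfig()
    table = _validate_gene_table(table)
    consensus = _plurality(table["class_call"], config.offtarget_labels)
    if consensus is None:
        raise NoConsensusError("all genes are off-target; no consensus class")
    return consensus


def flag_contigs(
    table: pd.DataFrame, config: DecontamConfig | None = None
) -> pd.DataFrame:
    """Per-contig keep/drop decisions for one bin.

    Consensus is computed once on the full bin; both rules are then applied
    in a single pass.  A contig with zero classified genes is judged only
    by the off-target-fraction rule.  Returns a table (contig_id, decision,
    reason, offtarget_fraction, contig_class, consensus_class) covering
    every contig exactly once.
    """
    config = config or DecontamConfig()
    table = _validate_gene_table(table)
    consensus = consensus_class(table, config)

    rows = []
    for contig_id, sub in table.groupby("contig_id", sort=True):
        calls = sub["class_call"]
        off_frac = float(calls.isin(config.offtarget_labels).mean())
        contig_class = _plurality(calls, config.offtarget_labels)
        over_fraction = off_frac > config.max_offtarget_fraction
        disagrees = contig_class is not None and contig_class != consensus
        if over_fraction and disagrees:
            reason = "both"
        elif over_fraction:
            reason = "offtarget_fraction"
        elif disagrees:
            reason = "class_disagreement"
        else:
            reason = ""
        rows.append(
            (
                contig_id,
                "drop" if reason else "keep",
                reason,
                off_frac,
                contig_class or "",
                consensus,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "decision",
            "reason",
            "offtarget_fraction",
            "contig_class",
            "consensus_class",
        ],
    )


def qc_gate(stats: BinStats, thresholds: QCThresholds | None = None) -> bool:
    """Inclusive quality gate: completeness >= 80 and contamination <= 5."""
    thresholds = thresholds or QCThresholds()
    return (
        stats.completeness >= thresholds.min_completeness
        and stats.contamination <= thresholds.max_contamination
    )


def name_bin(sample_id: str, method: str, number: int) -> str:
    """Compose a bin id as <sample>.<method code>.<number>."""
    if method not in METHOD_CODES:
        raise ValueError(
            f"unknown binning method {method!r}; expected one of {sorted(METHOD_CODES)}"
        )
    if number < 1:
        raise ValueError("bin number must be >= 1")
    return f"{sample_id}.{METHOD_CODES[method]}.{number}"
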