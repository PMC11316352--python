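"""Synthetic culture-genomics data with known ground truth.

Everything downstream of assembly is exercised on data produced here:
genomes with controlled GC, genome pairs at planned nucleotide identity,
shotgun read sets with recorded origins, per-contig gene-taxonomy tables
with planted contaminants, KO presence tables with ecotype marker panels,
and cas-locus tables with controllable cas1 dropout.

The error model is substitution-only (no indels), which keeps identity
bookkeeping exact for the ANI and read-mapping oracles.  All randomness
flows through ``numpy.random.default_rng`` seeds; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq, io

ROLES = ("picocyanobacterium", "heterotroph")
ECOTYPES = ("SC5.3", "LN", "LNLT", "HN", "LP")

#: genes present only in genomes of the keyed ecotype (the planted panels)
ECOTYPE_DIAGNOSTICS: dict[str, frozenset[str]] = {
    "HN": frozenset({"cheB", "cheR", "pilA"}),
    "LNLT": frozenset({"treS", "otsA", "otsB"}),
    "LP": frozenset({"mlhB"}),
}
#: red-pigmented ecotypes additionally carry the phycoerythrin genes
RED_ECOTYPES = frozenset({"SC5.3", "LN", "LNLT"})
PIGMENT_GENES = frozenset({"cpeA", "cpeB"})
#: genes carried by every picocyanobacterial genome regardless of ecotype
UNIVERSAL_GENES = frozenset(
    {"narB", "nirA", "nrtA", "nrtB", "nrtC", "amt", "urea_transport", "cysH"}
)


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence with simulation metadata."""

    genome_id: str
    sequence: str
    role: str = "picocyanobacterium"
    ecotype: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.ecotype is not None and self.ecotype not in ECOTYPES:
            raise ValueError(
                f"unknown ecotype {self.ecotype!r}; expected one of {ECOTYPES}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return _seq.gc_fraction(self.sequence)

    def with_sequence(self, sequence: str, genome_id: str | None = None) -> "GenomeRecord":
        return dataclasses.replace(
            self, sequence=sequence, genome_id=genome_id or self.genome_id
        )


@dataclass(frozen=True)
class CultureTruth:
    """Ground-truth composition of one simulated non-axenic culture."""

    culture_id: str
    member_genome_ids: tuple[str, ...]
    relative_abundances: tuple[float, ...]
    n_reads: int
    read_length: int
    substitution_rate: float
    seed: int

    def __post_init__(self):
        if len(self.member_genome_ids) != len(self.relative_abundances):
            raise ValueError("members and abundances differ in length")
        total = float(sum(self.relative_abundances))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    n_cultures: int = 20
    heterotroph_pool_size: int = 6
    planted_symbiont_prevalence: float = 0.25
    genome_length_range: tuple[int, int] = (20_000, 40_000)
    gc_range: tuple[float, float] = (0.45, 0.65)
    n_reads_per_culture: int = 2_000
    read_length: int = 150
    substitution_rate: float = 0.002
    master_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.planted_symbiont_prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        for lo, hi in (self.genome_length_range, self.gc_range):
            if lo > hi:
                raise ValueError("range bounds must be ordered low <= high")


def generate_genome(
    length_bp: int,
    gc: float,
    seed: int,
    genome_id: str = "genome",
    role: str = "picocyanobacterium",
    ecotype: str | None = None,
) -> GenomeRecord:
    """Random genome whose per-base GC probability is ``gc``.

    For length >= 100 kb the empirical GC lands within ~3 binomial standard
    deviations (< 0.005) of the request.
    """
    if length_bp < 1000:
        raise ValueError(f"length_bp must be >= 1000, got {length_bp}")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    is_gc = rng.random(length_bp) < gc
    pick = rng.integers(0, 2, size=length_bp, dtype=np.uint8)
    # A=0 C=1 G=2 T=3: GC bases are 1/2, AT bases are 0/3
    codes = np.where(is_gc, pick + 1, pick * 3).astype(np.uint8)
    return GenomeRecord(genome_id, _seq.decode(codes), role=role, ecotype=ecotype)


def mutate_genome(
    genome: GenomeRecord,
    target_identity: float,
    seed: int,
    genome_id: str | None = None,
) -> tuple[GenomeRecord, np.ndarray]:
    """Place substitutions uniformly at rate ``1 - target_identity``.

    Returns the mutated genome and the sorted array of 0-based mutated
    positions; every listed position holds a base different from the
    original, so realized identity is exactly
    ``1 - len(positions) / length``.
    """
    if not 0.5 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0.5, 1.0]")
    codes = _seq.encode(genome.sequence)
    if (codes == 4).any():
        raise ValueError("genome contains ambiguous bases; cannot mutate exactly")
    rng = np.random.default_rng(seed)
    hit = rng.random(codes.shape[0]) < (1.0 - target_identity)
    positions = np.nonzero(hit)[0]
    shifted = codes.copy()
    # adding 1..3 mod 4 guarantees a different base at every chosen site
    shifted[positions] = (
        codes[positions] + rng.integers(1, 4, size=positions.shape[0])
    ) % 4
    new_id = genome_id or f"{genome.genome_id}_id{target_identity:g}"
    return genome.with_sequence(_seq.decode(shifted), genome_id=new_id), positions


def generate_reads(
    culture: CultureTruth, genomes: Mapping[str, GenomeRecord]
) -> list[tuple[str, str, str]]:
    """Simulate a shotgun read set for one culture.

    Reads are allocated to members by a multinomial draw weighted by
    abundance x genome length, drawn from either strand with probability
    0.5, and hit with substitution errors at ``substitution_rate``.  Each
    read name records its origin as
    ``<culture>|<genome>|<start>|<strand>|<serial>`` (0-based start on the
    forward strand), which downstream oracle tests rely on.
    """
    missing = [g for g in culture.member_genome_ids if g not in genomes]
    if missing:
        raise KeyError(f"member genome(s) not found: {missing}")
    members = [genomes[g] for g in culture.member_genome_ids]
    shortest = min(m.length_bp for m in members)
    if culture.read_length > shortest:
        raise ValueError(
            f"read_length {culture.read_length} exceeds shortest member genome ({shortest} bp)"
        )
    rng = np.random.default_rng(culture.seed)
    weights = np.array(
        [a * m.length_bp for a, m in zip(culture.relative_abundances, members)]
    )
    counts = rng.multinomial(culture.n_reads, weights / weights.sum())

    reads: list[tuple[str, str, str]] = []
    L = culture.read_length
    qual = "I" * L
    serial = 0
    for member, n in zip(members, counts):
        if n == 0:
            continue
        codes = _seq.encode(member.sequence)
        starts = rng.integers(0, member.length_bp - L + 1, size=n)
        fwd = rng.random(n) < 0.5
        err = rng.random((n, L)) < culture.substitution_rate
        shifts = rng.integers(1, 4, size=(n, L))
        for i in range(n):
            frag = codes[starts[i] : starts[i] + L]
            if not fwd[i]:
                frag = 3 - frag[::-1]  # reverse complement in code space
            frag = frag.copy()
            e = err[i]
            frag[e] = (frag[e] + shifts[i][e]) % 4
            strand = "+" if fwd[i] else "-"
            name = f"{culture.culture_id}|{member.genome_id}|{starts[i]}|{strand}|{serial}"
            reads.append((name, _seq.decode(frag), qual))
            serial += 1
    return reads


def parse_read_origin(read_id: str) -> tuple[str, str, int, str]:
    """Invert the read-name convention of :func:`generate_reads`."""
    culture, genome, start, strand, _serial = read_id.split("|")
    return culture, genome, int(start), strand


# ---------------------------------------------------------------------------
# taxonomy tables with planted contaminant contigs
# ---------------------------------------------------------------------------

def generate_bin_gene_table(
    n_contigs: int,
    consensus_class: str,
    contaminant_spec: Sequence[tuple[int, str, float]],
    seed: int,
    bin_id: str = "bin",
    genes_per_contig: int = 20,
    background_offtarget: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Per-contig, per-gene class calls for one bin, with planted contaminants.

    Clean contigs keep >= 90% of genes on ``consensus_class`` (the rest are
    "no_hit" background); each ``(index, label, fraction)`` entry overrides
    ``round(fraction * genes_per_contig)`` genes of that contig with
    ``label``.  Returns the gene table (columns bin_id, contig_id,
    gene_index, class_call) and a truth map contig_id -> planted label
    (None for clean contigs).
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    for idx, _label, frac in contaminant_spec:
        if not 0 <= idx < n_contigs:
            raise IndexError(f"contaminant contig index {idx} out of range")
        if not 0 <= frac <= 1:
            raise ValueError(f"contaminant fraction {frac} outside [0, 1]")
    rng = np.random.default_rng(seed)
    planted = {idx: (label, frac) for idx, label, frac in contaminant_spec}
    max_bg = int(0.10 * genes_per_contig)

    rows = []
    truth: dict[str, str | None] = {}
    for c in range(n_contigs):
        contig_id = f"{bin_id}_c{c:03d}"
        calls = np.array([consensus_class] * genes_per_contig, dtype=object)
        n_bg = min(rng.binomial(genes_per_contig, background_offtarget), max_bg)
        if n_bg:
            calls[rng.choice(genes_per_contig, size=n_bg, replace=False)] = "no_hit"
        if c in planted:
            label, frac = planted[c]
            n_bad = int(round(frac * genes_per_contig))
            calls[rng.choice(genes_per_contig, size=n_bad, replace=False)] = label
            truth[contig_id] = label
        else:
            truth[contig_id] = None
        rows.extend(
            (bin_id, contig_id, g, calls[g]) for g in range(genes_per_contig)
        )
    table = pd.DataFrame(
        rows, columns=["bin_id", "contig_id", "gene_index", "class_call"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# KO presence tables with ecotype marker panels
# ---------------------------------------------------------------------------

def generate_ko_table(
    ecotype: str,
    panel_genes: Sequence[str],
    dropout: float,
    seed: int,
) -> dict[str, int]:
    """Gene -> copy-number profile for one genome of ``ecotype``.

    Ecotype-diagnostic genes (and pigment genes for red ecotypes) are
    present at copy 1 minus random dropout; universal genes are always
    present; diagnostics of *other* ecotypes are absent; any remaining
    panel genes appear at a 0.05 background rate.
    """
    if ecotype not in ECOTYPES:
        raise ValueError(f"unknown ecotype {ecotype!r}; expected one of {ECOTYPES}")
    if not 0 <= dropout < 1:
        raise ValueError(f"dropout must be in [0, 1), got {dropout}")
    rng = np.random.default_rng(seed)
    own = set(ECOTYPE_DIAGNOSTICS.get(ecotype, frozenset()))
    if ecotype in RED_ECOTYPES:
        own |= PIGMENT_GENES
    foreign = set().union(*ECOTYPE_DIAGNOSTICS.values()) | PIGMENT_GENES
    foreign -= own

    profile: dict[str, int] = {}
    for gene in panel_genes:
        if gene in UNIVERSAL_GENES:
            profile[gene] = 1
        elif gene in own:
            profile[gene] = 0 if rng.random() < dropout else 1
        elif gene in foreign:
            profile[gene] = 0
        else:
            profile[gene] = 1 if rng.random() < 0.05 else 0
    return profile


def generate_ko_panel(
    ecotype_of_genome: Mapping[str, str],
    panel_genes: Sequence[str],
    dropout: float,
    seed: int,
) -> pd.DataFrame:
    """KO table (genomes x genes) for a collection of ecotyped genomes."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ecotype_of_genome))
    rows = {}
    for (gid, eco), child in zip(ecotype_of_genome.items(), children):
        rows[gid] = generate_ko_table(
            eco, panel_genes, dropout, seed=child.generate_state(1)[0]
        )
    df = pd.DataFrame.from_dict(rows, orient="index").loc[
        list(ecotype_of_genome), list(panel_genes)
    ]
    df.index.name = "genome_id"
    return df


# ---------------------------------------------------------------------------
# cas-locus tables with cas1 dropout
# ---------------------------------------------------------------------------

_SUBTYPE_GENES = {
    "I-E": ["cas1", "cas2", "cas3", "cse1", "cse2", "cas7", "cas5", "cas6e"],
    "I-G": ["cas1", "cas2", "cas3", "csb", "cas7", "cas5"],
    "III-B": ["cas1", "cas2", "cas10", "cmr1", "cmr3", "cmr4", "cmr5", "cmr6"],
}


def generate_cas_locus_table(
    n_genomes: int,
    n_positive: int,
    n_cas1_less: int,
    seed: int,
    subtypes: Sequence[str] = ("I-G", "I-E", "III-B"),
    group: str = "freshwater",
) -> tuple[pd.DataFrame, dict[str, str], dict[str, dict]]:
    """CRISPRCasTyper-like locus table for a synthetic genome panel.

    ``n_positive`` genomes carry one complete locus of a cycled subtype;
    ``n_cas1_less`` of those have the cas1 row removed while keeping >= 1
    spacer.  Returns (locus table, genome -> group mapping over the whole
    panel, truth per genome).
    """
    if not 0 <= n_cas1_less <= n_positive <= n_genomes:
        raise ValueError("need 0 <= n_cas1_less <= n_positive <= n_genomes")
    unknown = [s for s in subtypes if s not in _SUBTYPE_GENES]
    if unknown:
        raise ValueError(f"unknown subtype(s) {unknown}; known: {sorted(_SUBTYPE_GENES)}")
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i:04d}" for i in range(n_genomes)]
    positives = sorted(rng.choice(n_genomes, size=n_positive, replace=False))
    cas1_less = set(
        np.asarray(positives)[
            sorted(rng.choice(n_positive, size=n_cas1_less, replace=False))
        ]
    )

    rows = []
    truth: dict[str, dict] = {g: {"positive": False} for g in genome_ids}
    for rank, gidx in enumerate(positives):
        gid = genome_ids[gidx]
        subtype = subtypes[rank % len(subtypes)]
        n_spacers = int(rng.integers(1, 25))
        locus = f"{gid}_locus1"
        for gene in _SUBTYPE_GENES[subtype]:
            if gene == "cas1" and gidx in cas1_less:
                continue
            quality = "low" if rng.random() < 0.1 else "high"
            rows.append((gid, locus, subtype, gene, quality, n_spacers))
        truth[gid] = {
            "positive": True,
            "subtype": subtype,
            "cas1_less": gidx in cas1_less,
            "n_spacers": n_spacers,
        }
    table = pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "locus_id",
            "subtype",
            "gene_name",
            "gene_quality",
            "n_spacers_in_locus",
        ],
    )
    groups = {g: group for g in genome_ids}
    return table, groups, truth


# ---------------------------------------------------------------------------
# whole-collection driver
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCollection:
    genomes: dict[str, GenomeRecord]
    cultures: list[CultureTruth]
    symbiont_id: str
    ecotype_of_culture: dict[str, str]


def simulate_collection(config: SimulationConfig) -> SimulatedCollection:
    """Build a culture collection: one picocyanobacterium per ecotype, a
    heterotroph pool with one planted symbiont, and per-culture truths.

    Each culture holds exactly one picocyanobacterium (cycled over
    ecotypes) at 70% abundance plus 0-3 heterotrophs sharing the rest.
    The symbiont is planted into ``round(prevalence * n_cultures)``
    cultures; decoy heterotrophs are used at most 4 times each.
    """
    rng = np.random.default_rng(config.master_seed)
    lo, hi = config.genome_length_range
    glo, ghi = config.gc_range

    genomes: dict[str, GenomeRecord] = {}
    for i, eco in enumerate(ECOTYPES):
        gid = f"pico_{eco.replace('.', '')}"
        genomes[gid] = generate_genome(
            int(rng.integers(lo, hi + 1)),
            float(rng.uniform(glo, ghi)),
            seed=int(rng.integers(0, 2**31)),
            genome_id=gid,
            role="picocyanobacterium",
            ecotype=eco,
        )
    pico_ids = list(genomes)

    het_ids = []
    for i in range(config.heterotroph_pool_size):
        gid = f"het_{i:02d}"
        genomes[gid] = generate_genome(
            int(rng.integers(lo, hi + 1)),
            float(rng.uniform(glo, ghi)),
            seed=int(rng.integers(0, 2**31)),
            genome_id=gid,
            role="heterotroph",
        )
        het_ids.append(gid)
    symbiont_id = het_ids[0]
    decoys = het_ids[1:]

    n_symbiont = int(round(config.planted_symbiont_prevalence * config.n_cultures))
    symbiont_cultures = set(
        rng.choice(config.n_cultures, size=n_symbiont, replace=False)
    )
    decoy_budget = {d: 4 for d in decoys}

    cultures = []
    ecotype_of_culture = {}
    for c in range(config.n_cultures):
        culture_id = f"C{c:03d}"
        pico = pico_ids[c % len(pico_ids)]
        ecotype_of_culture[culture_id] = genomes[pico].ecotype
        members = [pico]
        if c in symbiont_cultures:
            members.append(symbiont_id)
        available = [d for d in decoys if decoy_budget[d] > 0]
        n_extra = int(rng.integers(0, min(3, len(available)) + 1))
        if n_extra:
            chosen = rng.choice(len(available), size=n_extra, replace=False)
            for j in sorted(chosen):
                members.append(available[j])
                decoy_budget[available[j]] -= 1
        n_het = len(members) - 1
        abund = [0.7] + [0.3 / n_het] * n_het if n_het else [1.0]
        cultures.append(
            CultureTruth(
                culture_id=culture_id,
                member_genome_ids=tuple(members),
                relative_abundances=tuple(abund),
                n_reads=config.n_reads_per_culture,
                read_length=config.read_length,
                substitution_rate=config.substitution_rate,
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return SimulatedCollection(genomes, cultures, symbiont_id, ecotype_of_culture)


def write_collection(coll: SimulatedCollection, outdir: str | Path) -> None:
    """Serialize a simulated collection: FASTA genomes, FASTQ reads, TSV truth."""
    outdir = Path(outdir)
    for sub in ("genomes", "reads", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for gid, rec in coll.genomes.items():
        io.write_fasta({gid: rec.sequence}, outdir / "genomes" / f"{gid}.fasta")
    for culture in coll.cultures:
        reads = generate_reads(culture, coll.genomes)
        io.write_fastq(reads, outdir / "reads" / f"{culture.culture_id}.fastq.gz")

    truth = pd.DataFrame(
        [
            {
                "culture_id": c.culture_id,
                "members": ",".join(c.member_genome_ids),
                "abundances": ",".join(f"{a:.6g}" for a in c.relative_abundances),
                "n_reads": c.n_reads,
                "read_length": c.read_length,
                "substitution_rate": c.substitution_rate,
                "ecotype": coll.ecotype_of_culture[c.culture_id],
                "seed": c.seed,
            }
            for c in coll.cultures
        ]
    )
    io.write_tsv(truth, outdir / "truth" / "cultures.tsv")
    gtab = pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "role": g.role,
                "ecotype": g.ecotype or "",
                "length_bp": g.length_bp,
                "gc": round(g.gc, 6),
                "is_symbiont": g.genome_id == coll.symbiont_id,
            }
            for g in coll.genomes.values()
        ]
    )
    io.write_tsv(gtab, outdir / "truth" / "genomes.tsv")
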