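"""Synthetic data generation: SCRaMbLE pools, selection, reads, genome fixture.

This module produces everything the genotyping pipeline consumes, with the
statistical structure the analysis assumes:

* ``simulate_induction`` -- a Monte-Carlo pool of cells, each with Bernoulli
  Cre activity, a Poisson number of recombination events applied
  sequentially, and a stochastically flipped GFP reporter (the SCOUT model:
  an irreversible Cre-ON switch with a small leak rate in inactive cells).
* ``facs_gate`` -- reweighting by the GFP-positive fraction (FACS sorting).
* ``grow_select`` -- exponential enrichment under a copy-number-aware
  fitness model (histidine dropout selection by default).
* ``pcr_sample`` / ``synthesize_reads`` -- multinomial amplicon sampling with
  optional PCR length bias, and nanopore-like substitution/indel read noise.
* ``make_genome_fixture`` -- a toy multi-locus host genome with 23 bp landing
  pads at the emptied native loci, the module at a designated locus, and a
  matching GFF3 annotation.
* ``run_iterative_rounds`` -- iterative SCRaMbLE: re-induce the dominant
  genotype(s), gate, select, and summarise round by round.

All stochastic operations are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import key_to_int, stage_rng
from .design import (
    Genotype,
    ModuleDesign,
    RecombinationEvent,
    apply_event,
    canonical_key,
    copy_numbers,
    random_segment_sequence,
    render_sequence,
    revcomp,
)

__all__ = [
    "PoolConfig",
    "FitnessModel",
    "ErrorModel",
    "PoolEntry",
    "Pool",
    "simulate_induction",
    "facs_gate",
    "grow_select",
    "pcr_sample",
    "synthesize_reads",
    "make_genome_fixture",
    "run_iterative_rounds",
    "READ_ID_SEPARATOR",
    "true_key_from_read_id",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PoolConfig:
    """Per-cell model of one SCRaMbLE induction.

    n_cells is a computational scale-down of the >1e6 cells sorted in a real
    experiment; 20,000 cells give ~0.7% precision on pool frequencies.
    lambda_events is the mean number of Cre recombination events per
    Cre-active cell (Poisson).  type_weights are the relative probabilities
    of deletion/inversion/duplication per event.
    """

    n_cells: int = 20_000
    lambda_events: float = 1.5
    p_cre_active: float = 0.6
    p_reporter_flip: float = 0.9
    p_leak: float = 0.01
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"deletion": 0.35, "inversion": 0.45, "duplication": 0.20}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.lambda_events < 0:
            raise ValueError("lambda_events must be >= 0")
        for name in ("p_cre_active", "p_reporter_flip", "p_leak"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        w = dict(self.type_weights)
        if set(w) - {"deletion", "inversion", "duplication"}:
            raise ValueError(f"unknown event types in type_weights: {sorted(w)}")
        if any(v < 0 for v in w.values()):
            raise ValueError("type_weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("type_weights must sum to 1")


_DEFAULT_MU_OF_COPY = {0: 0.0, 1: 0.4, 2: 1.0}


@dataclass(frozen=True)
class FitnessModel:
    """Growth-rate model for genotypes under a given medium.

    In ``minus_his`` medium every essential gene must be present (copy >= 1)
    for growth; the dosage gene (HIS5, whose weak promoter limits pathway
    flux in the defective refactored module) sets the relative rate via
    ``mu_of_copy``: one copy grows slowly, two or more restore near-wild-type
    growth (saturating by default -- copies beyond the largest key inherit its
    value).  In ``plus_his`` medium the module is dispensable and every
    genotype grows at mu_max.
    """

    medium: str = "minus_his"
    essential_segments: frozenset[str] = frozenset(
        {"HIS1", "HIS2", "HIS3", "HIS4", "HIS5", "HIS6", "HIS7"}
    )
    mu_max: float = 1.0
    dosage_gene: str = "HIS5"
    mu_of_copy: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_MU_OF_COPY))

    def __post_init__(self) -> None:
        if self.medium not in ("plus_his", "minus_his"):
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        vals = [self.mu_of_copy[k] for k in sorted(self.mu_of_copy)]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("mu_of_copy values must lie in [0, 1] (relative to mu_max)")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("mu_of_copy must be non-decreasing in copy number")

    def relative_rate_of_copy(self, copy: int) -> float:
        """mu_of_copy with flat (saturating) extrapolation above the largest key."""
        keys = sorted(self.mu_of_copy)
        if copy in self.mu_of_copy:
            return float(self.mu_of_copy[copy])
        below = [k for k in keys if k <= copy]
        if not below:
            return 0.0
        return float(self.mu_of_copy[max(below)])

    def growth_rate(self, genotype: Genotype, design: ModuleDesign) -> float:
        """Absolute growth rate mu(genotype) in units of mu_max per generation."""
        if self.medium == "plus_his":
            return self.mu_max
        counts = copy_numbers(genotype, design)
        for name in self.essential_segments:
            seg = design.by_name(name)
            if counts[seg.segment_id - 1] == 0:
                return 0.0
        dosage = design.by_name(self.dosage_gene)
        return self.mu_max * self.relative_rate_of_copy(int(counts[dosage.segment_id - 1]))


@dataclass(frozen=True)
class ErrorModel:
    """Nanopore-like per-base read noise (generic R9-era profile).

    Rates are independent per base; p_truncate is the probability a read is
    cut at a uniform breakpoint (keeping a random side), emulating fragmented
    or aborted reads.  quality_placeholder is the constant Q score written to
    FASTQ; the genotyping pipeline never uses qualities.
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.04
    p_truncate: float = 0.05
    quality_placeholder: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.25:
                raise ValueError(f"{name}={r} outside [0, 0.25]")
        if not 0.0 <= self.p_truncate <= 1.0:
            raise ValueError("p_truncate outside [0, 1]")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, p_truncate=0.0)


# ---------------------------------------------------------------------------
# pools


@dataclass
class PoolEntry:
    abundance: float
    gfp_positive_fraction: float


@dataclass
class Pool:
    """A genotype-aggregated cell pool: canonical key -> (abundance, GFP+ fraction)."""

    entries: dict[str, PoolEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_abundance(self) -> float:
        return float(sum(e.abundance for e in self.entries.values()))

    def frequencies(self) -> dict[str, float]:
        total = self.total_abundance
        if total <= 0:
            raise ValueError("pool has no abundance")
        return {k: e.abundance / total for k, e in self.entries.items()}

    def dominant(self, k: int = 1) -> list[str]:
        """Top-k genotype keys by abundance (ties broken by key)."""
        ranked = sorted(self.entries.items(), key=lambda kv: (-kv[1].abundance, kv[0]))
        return [key for key, _ in ranked[:k]]

    def mean_copy_number(self, gene: str, design: ModuleDesign) -> float:
        """Abundance-weighted mean copy number of one gene across the pool."""
        seg = design.by_name(gene)
        total = self.total_abundance
        acc = 0.0
        for key, entry in self.entries.items():
            counts = copy_numbers(Genotype.from_key(key), design)
            acc += entry.abundance * counts[seg.segment_id - 1]
        return acc / total

    def to_rows(self) -> list[dict]:
        freqs = self.frequencies()
        return [
            {
                "genotype_key": k,
                "abundance": e.abundance,
                "frequency": freqs[k],
                "gfp_positive_fraction": e.gfp_positive_fraction,
            }
            for k, e in sorted(
                self.entries.items(), key=lambda kv: (-kv[1].abundance, kv[0])
            )
        ]


def _draw_event(
    genotype: Genotype, cfg: PoolConfig, rng: np.random.Generator
) -> RecombinationEvent | None:
    """One event: type by type_weights, then a uniform lox-site pair."""
    m = len(genotype)
    if m == 0:
        return None
    types = sorted(cfg.type_weights)
    probs = np.array([cfg.type_weights[t] for t in types])
    etype = types[rng.choice(len(types), p=probs / probs.sum())]
    # uniform unordered pair 0 <= i < j <= m
    i = int(rng.integers(0, m + 1))
    j = int(rng.integers(0, m + 1))
    while i == j:
        j = int(rng.integers(0, m + 1))
    if i > j:
        i, j = j, i
    return RecombinationEvent(etype, i, j)


def simulate_induction(
    parental_genotype: Genotype,
    design: ModuleDesign,
    pool_config: PoolConfig,
    rng: np.random.Generator | None = None,
) -> Pool:
    """Monte-Carlo SCRaMbLE induction of a clonal population.

    Each cell is Cre-active with p_cre_active; active cells apply
    Poisson(lambda_events) sequential recombination events and flip the GFP
    reporter with p_reporter_flip; inactive cells stay parental and are GFP+
    only through the leak rate.  Returns the genotype-aggregated pool.
    """
    parental_genotype.validate(design)
    if rng is None:
        rng = stage_rng(pool_config.seed, "induction")
    n = pool_config.n_cells
    active = rng.random(n) < pool_config.p_cre_active
    n_events = np.where(active, rng.poisson(pool_config.lambda_events, size=n), 0)
    gfp_p = np.where(active, pool_config.p_reporter_flip, pool_config.p_leak)
    gfp = rng.random(n) < gfp_p

    cells: dict[str, list[float]] = {}  # key -> [count, gfp_count]
    parental_key = canonical_key(parental_genotype)
    for cell in range(n):
        if n_events[cell] == 0:
            key = parental_key
        else:
            g = parental_genotype
            for _ in range(int(n_events[cell])):
                ev = _draw_event(g, pool_config, rng)
                if ev is None:  # fully deleted module: nothing left to recombine
                    break
                g = apply_event(g, ev)
            key = canonical_key(g)
        slot = cells.setdefault(key, [0.0, 0.0])
        slot[0] += 1.0
        slot[1] += float(gfp[cell])
    return Pool(
        {
            key: PoolEntry(abundance=cnt, gfp_positive_fraction=pos / cnt)
            for key, (cnt, pos) in cells.items()
        }
    )


def facs_gate(pool: Pool) -> Pool:
    """Keep only GFP-positive mass (FACS sorting of reporter-flipped cells)."""
    if not pool.entries:
        raise ValueError("cannot gate an empty pool")
    gated = {
        key: PoolEntry(e.abundance * e.gfp_positive_fraction, 1.0)
        for key, e in pool.entries.items()
        if e.abundance * e.gfp_positive_fraction > 0
    }
    if not gated:
        raise ValueError("FACS gate removed all cells (no GFP+ mass)")
    return Pool(gated)


def grow_select(
    pool: Pool,
    design: ModuleDesign,
    fitness_model: FitnessModel,
    generations: float,
    dead_carryover: float = 0.0,
) -> Pool:
    """Deterministic exponential enrichment for ``generations`` doublings.

    Abundance is multiplied by 2**(generations * mu/mu_max).  Genotypes with
    mu = 0 keep ``dead_carryover`` of their abundance (default 0), modelling
    template DNA amplified from dead or non-growing post-SCRaMbLE cells.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if not 0.0 <= dead_carryover <= 1.0:
        raise ValueError("dead_carryover outside [0, 1]")
    out: dict[str, PoolEntry] = {}
    for key, entry in pool.entries.items():
        mu = fitness_model.growth_rate(Genotype.from_key(key), design)
        if mu <= 0:
            ab = entry.abundance * dead_carryover
        else:
            ab = entry.abundance * 2.0 ** (generations * mu / fitness_model.mu_max)
        if ab > 0:
            out[key] = PoolEntry(ab, entry.gfp_positive_fraction)
    if not out:
        raise ValueError("no genotype survived selection (all zero-fitness)")
    return Pool(out)


def pcr_sample(
    pool: Pool,
    design: ModuleDesign,
    n_molecules: int,
    length_bias_beta: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Multinomial draw of amplicon molecules from the pool.

    Sampling weight is abundance * exp(-beta * amplicon_length_kb); beta = 0
    (the default -- no length enrichment was observed in the data this
    emulates) reduces to abundance-proportional sampling.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not pool.entries:
        raise ValueError("cannot sample from an empty pool")
    if rng is None:
        rng = stage_rng(seed if seed is not None else 0, "pcr")
    keys = sorted(pool.entries)
    weights = np.array(
        [
            pool.entries[k].abundance
            * np.exp(-length_bias_beta * design.amplicon_length(Genotype.from_key(k)) / 1000.0)
            for k in keys
        ]
    )
    counts = rng.multinomial(n_molecules, weights / weights.sum())
    out: list[str] = []
    for key, cnt in zip(keys, counts):
        out.extend([key] * int(cnt))
    return out


# ---------------------------------------------------------------------------
# reads

READ_ID_SEPARATOR = "|gt="

_BASE_TO_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, em: ErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitutions, insertions and deletions (vectorised)."""
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size
    if em.sub_rate > 0:
        sub = rng.random(n) < em.sub_rate
        codes = codes.copy()
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    keep = (
        rng.random(n) >= em.del_rate if em.del_rate > 0 else np.ones(n, dtype=bool)
    )
    ins = rng.random(n) < em.ins_rate if em.ins_rate > 0 else np.zeros(n, dtype=bool)
    counts = keep.astype(np.int64) + ins
    rep = np.repeat(np.arange(n), counts)
    out = codes[rep]
    # an inserted random base occupies the first emitted slot of its position
    starts = np.cumsum(counts) - counts
    ins_slots = starts[ins]
    out[ins_slots] = rng.integers(0, 4, size=ins_slots.size)
    return _CODE_TO_BASE[out].tobytes().decode()


def synthesize_reads(
    genotype_multiset: Sequence[str],
    design: ModuleDesign,
    error_model: ErrorModel | None = None,
    rng: np.random.Generator | None = None,
    name_prefix: str = "read",
) -> list[SeqRecord]:
    """Render each molecule and apply read noise; returns FASTQ-ready records.

    Strand is uniform; truncated reads keep a random side of a uniform
    breakpoint.  Read ids embed the ground-truth genotype key after
    ``|gt=`` purely as a test oracle -- the caller must never parse it.
    """
    em = error_model or ErrorModel()
    if rng is None:
        rng = stage_rng(em.seed, "reads")
    records: list[SeqRecord] = []
    rendered: dict[str, str] = {}
    for i, key in enumerate(genotype_multiset):
        if key not in rendered:
            rendered[key] = render_sequence(design, Genotype.from_key(key))
        seq = rendered[key]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = _mutate(seq, em, rng)
        if em.p_truncate > 0 and rng.random() < em.p_truncate and len(seq) > 1:
            bp = int(rng.integers(1, len(seq)))
            seq = seq[:bp] if rng.random() < 0.5 else seq[bp:]
        rec = SeqRecord(
            Seq(seq),
            id=f"{name_prefix}{i:06d}{READ_ID_SEPARATOR}{key}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [em.quality_placeholder] * len(seq)
        records.append(rec)
    return records


def true_key_from_read_id(read_id: str) -> str:
    """Ground-truth genotype key embedded in a synthetic read id (test oracle)."""
    if READ_ID_SEPARATOR not in read_id:
        raise ValueError(f"read id {read_id!r} carries no ground-truth key")
    return read_id.split(READ_ID_SEPARATOR, 1)[1]


# ---------------------------------------------------------------------------
# toy host genome


def make_genome_fixture(
    design: ModuleDesign,
    n_filler_genes: int = 4,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[str]]:
    """A toy multi-locus host genome plus GFF3 for gene-impact annotation.

    Each gene cassette gets a native-locus contig where the gene has been
    replaced by a unique 23 bp landing pad (flanked by filler sequence), and
    one module contig carries the full parental module at a designated locus
    with gene and three_prime_UTR features.  The 3'UTR of each module gene
    extends past the downstream loxPsym site into the linker, as in real
    loxPsym-bearing constructs, so recombination boundaries can disrupt it.

    Returns (FASTA records, GFF3 lines).
    """
    rng = stage_rng(seed, "genome-fixture")
    pad_len = design.landing_pad_length
    records: list[SeqRecord] = []
    gff: list[str] = ["##gff-version 3"]

    # native loci: filler . landing_pad . filler
    for seg in design.segments:
        left = random_segment_sequence(400, rng)
        pad = random_segment_sequence(pad_len, rng)
        right = random_segment_sequence(400, rng)
        contig = f"native_{seg.name}"
        records.append(SeqRecord(Seq(left + pad + right), id=contig, description=""))
        gff.append(
            "\t".join(
                [
                    contig,
                    "scramblekit",
                    "landing_pad",
                    str(len(left) + 1),
                    str(len(left) + pad_len),
                    ".",
                    "+",
                    ".",
                    f"ID=pad_{seg.name};Name={seg.name}_landing_pad",
                ]
            )
        )

    # module locus: upstream filler . parental module . downstream filler
    upstream = random_segment_sequence(500, rng)
    module_seq = design.reference_sequence()
    downstream = random_segment_sequence(500, rng)
    contig = "module_locus"
    records.append(SeqRecord(Seq(upstream + module_seq + downstream), id=contig, description=""))
    module_start = len(upstream)  # 0-based
    gff.append(
        "\t".join(
            [
                contig,
                "scramblekit",
                "region",
                str(module_start + 1),
                str(module_start + len(module_seq)),
                ".",
                "+",
                ".",
                "ID=synthetic_module;Name=synthetic_module",
            ]
        )
    )
    lox_len = len(design.lox_sequence)
    pos = module_start + len(design.left_flank)  # start of first lox (0-based)
    for idx, seg in enumerate(design.segments):
        gff.append(
            "\t".join(
                [
                    contig,
                    "scramblekit",
                    "lox_site",
                    str(pos + 1),
                    str(pos + lox_len),
                    ".",
                    "+",
                    ".",
                    f"ID=lox_{idx}",
                ]
            )
        )
        gene_start = pos + lox_len
        gene_end = gene_start + len(seg)  # half-open
        gff.append(
            "\t".join(
                [
                    contig,
                    "scramblekit",
                    "gene",
                    str(gene_start + 1),
                    str(gene_end),
                    ".",
                    "+",
                    ".",
                    f"ID=gene_{seg.name};Name={seg.name};segment_id={seg.segment_id}",
                ]
            )
        )
        # 3'UTR: last 150 bp of the cassette plus 60 bp past the downstream lox
        utr_start = max(gene_start, gene_end - 150)
        utr_end = min(gene_end + lox_len + 60, module_start + len(module_seq))
        gff.append(
            "\t".join(
                [
                    contig,
                    "scramblekit",
                    "three_prime_UTR",
                    str(utr_start + 1),
                    str(utr_end),
                    ".",
                    "+",
                    ".",
                    f"ID=utr3_{seg.name};Parent=gene_{seg.name}",
                ]
            )
        )
        pos = gene_end
    gff.append(
        "\t".join(
            [
                contig,
                "scramblekit",
                "lox_site",
                str(pos + 1),
                str(pos + lox_len),
                ".",
                "+",
                ".",
                f"ID=lox_{design.n_segments}",
            ]
        )
    )

    # unrelated filler genes on their own contig
    if n_filler_genes > 0:
        filler_parts = []
        gene_coords = []
        cursor = 0
        for i in range(n_filler_genes):
            gap = random_segment_sequence(200, rng)
            gene = random_segment_sequence(600, rng)
            filler_parts.extend([gap, gene])
            gene_coords.append((cursor + 200, cursor + 800))
            cursor += 800
        filler_parts.append(random_segment_sequence(200, rng))
        contig = "filler"
        records.append(SeqRecord(Seq("".join(filler_parts)), id=contig, description=""))
        for i, (a, b) in enumerate(gene_coords):
            gff.append(
                "\t".join(
                    [
                        contig,
                        "scramblekit",
                        "gene",
                        str(a + 1),
                        str(b),
                        ".",
                        "+",
                        ".",
                        f"ID=filler_{i};Name=FIL{i + 1}",
                    ]
                )
            )
    return records, gff


# ---------------------------------------------------------------------------
# iterative rounds


def run_iterative_rounds(
    parental: Genotype,
    design: ModuleDesign,
    pool_config: PoolConfig,
    fitness_model: FitnessModel,
    n_rounds: int,
    generations: float = 20.0,
    top_k: int = 1,
    dead_carryover: float = 0.0,
    seed: int | None = None,
) -> tuple[list[Pool], list[dict]]:
    """Iterative SCRaMbLE: induce -> FACS gate -> selective growth, repeated.

    Each round re-induces the top_k genotypes of the previous round's pool
    (founders weighted by their abundance share).  Round RNG substreams are
    keyed by (seed, founder keys) -- common random numbers -- so two rounds
    starting from identical founders reproduce identically and round-to-round
    differences reflect founder changes, not resampling noise.

    Returns (per-round pools, per-round summary dicts with the dominant
    genotype, its frequency, and the mean dosage-gene copy number).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    base_seed = pool_config.seed if seed is None else seed
    founders: list[tuple[Genotype, float]] = [(parental, 1.0)]
    pools: list[Pool] = []
    summary: list[dict] = []
    for rnd in range(1, n_rounds + 1):
        founder_sig = ";".join(canonical_key(g) for g, _ in founders)
        rng = stage_rng(base_seed, "round", founder_sig)
        merged: dict[str, PoolEntry] = {}
        for founder, share in founders:
            cfg = replace(pool_config, n_cells=max(1, int(round(pool_config.n_cells * share))))
            sub = simulate_induction(founder, design, cfg, rng=rng)
            for key, e in sub.entries.items():
                slot = merged.setdefault(key, PoolEntry(0.0, 0.0))
                # abundance-weighted merge of GFP fractions
                tot = slot.abundance + e.abundance
                slot.gfp_positive_fraction = (
                    slot.gfp_positive_fraction * slot.abundance
                    + e.gfp_positive_fraction * e.abundance
                ) / tot
                slot.abundance = tot
        pool = grow_select(
            facs_gate(Pool(merged)), design, fitness_model, generations, dead_carryover
        )
        pools.append(pool)
        freqs = pool.frequencies()
        dom = pool.dominant(1)[0]
        summary.append(
            {
                "round": rnd,
                "dominant_key": dom,
                "dominant_frequency": freqs[dom],
                "mean_dosage_copy": pool.mean_copy_number(fitness_model.dosage_gene, design),
                "n_genotypes": len(pool),
            }
        )
        top = pool.dominant(top_k)
        top_mass = sum(freqs[k] for k in top)
        founders = [(Genotype.from_key(k), freqs[k] / top_mass) for k in top]
    return pools, summary
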