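"""Data model for loxPsym-segmented synthetic genome modules.

A module is an array of gene cassettes (segments) interleaved with loxPsym
sites and bracketed by fixed flanking sequences carrying the PCR primer
anchors::

    left_flank . lox . seg1 . lox . seg2 . ... . segN . lox . right_flank

Cre recombinase acting between any two loxPsym sites deletes, inverts or
(in trans) tandem-duplicates the intervening block of segments.  Because
loxPsym is palindromic, all three outcomes are possible regardless of
relative site orientation, and every outcome preserves the alternating
segment/lox layout.  lox sites are therefore represented implicitly: a
genotype is just a signed sequence of segment identifiers, the natural
signed-permutation-with-deletion-and-copy state space of SCRaMbLE.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "LOXPSYM",
    "SegmentSpec",
    "ModuleDesign",
    "Genotype",
    "RecombinationEvent",
    "EVENT_TYPES",
    "build_reference",
    "render_sequence",
    "apply_event",
    "applicable_events",
    "copy_numbers",
    "tu_count",
    "canonical_key",
    "his_module_design",
    "random_segment_sequence",
]

#: Canonical 34 bp loxPsym site: two 13 bp Cre-binding arms around a
#: palindromic 8 bp spacer, so the whole site is its own reverse complement.
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"
assert len(LOXPSYM) == 34
assert str(Seq(LOXPSYM).reverse_complement()) == LOXPSYM

EVENT_TYPES = ("deletion", "inversion", "duplication")

_DNA = set("ACGT")


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: sequence is empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what}: non-ACGT characters {sorted(bad)!r}")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SegmentSpec:
    """One cassette of the module: a promoter-CDS-terminator unit or a marker."""

    segment_id: int
    name: str
    sequence: str
    role: str = "gene_cassette"

    def __post_init__(self) -> None:
        if self.segment_id < 1:
            raise ValueError(f"segment_id must be >= 1, got {self.segment_id}")
        if self.role not in ("gene_cassette", "marker"):
            raise ValueError(f"unknown segment role {self.role!r}")
        _check_dna(self.sequence, f"segment {self.name}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModuleDesign:
    """A loxPsym-segmented construct plus the fixed flanks used as primer anchors."""

    segments: tuple[SegmentSpec, ...]
    lox_sequence: str = LOXPSYM
    left_flank: str = ""
    right_flank: str = ""
    landing_pad_length: int = 23
    marker_inside_lox_array: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("design needs at least one segment")
        ids = [s.segment_id for s in self.segments]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"segment_ids must be consecutive from 1, got {ids}")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        _check_dna(self.lox_sequence, "lox site")
        _check_dna(self.left_flank, "left flank")
        _check_dna(self.right_flank, "right flank")
        for s in self.segments:
            if self.lox_sequence in s.sequence or self.lox_sequence in revcomp(s.sequence):
                raise ValueError(f"lox site found inside segment {s.name}")
        ref = self.reference_sequence()
        for what, anchor in (("left", self.left_flank), ("right", self.right_flank)):
            if ref.count(anchor) != 1:
                raise ValueError(f"{what} flank anchor not unique in rendered reference")

    # -- lookups -----------------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_lox_sites(self) -> int:
        """lox-site count of the parental construct (= segment count + 1)."""
        return len(self.segments) + 1

    def segment(self, segment_id: int) -> SegmentSpec:
        try:
            seg = self.segments[segment_id - 1]
        except IndexError:
            raise KeyError(f"unknown segment_id {segment_id}") from None
        return seg

    def by_name(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment name {name}")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments if s.role == "gene_cassette")

    def parental_genotype(self) -> "Genotype":
        return Genotype(tuple((s.segment_id, +1) for s in self.segments))

    def reference_sequence(self) -> str:
        return render_sequence(self, self.parental_genotype())

    def amplicon_length(self, genotype: "Genotype") -> int:
        k = len(genotype)
        return (
            len(self.left_flank)
            + len(self.right_flank)
            + (k + 1) * len(self.lox_sequence)
            + sum(len(self.segment(sid)) for sid, _ in genotype.elements)
        )

    @property
    def min_amplicon_length(self) -> int:
        """Length of the fully deleted (empty-genotype) amplicon."""
        return len(self.left_flank) + len(self.right_flank) + 2 * len(self.lox_sequence)


@dataclass(frozen=True)
class Genotype:
    """A signed sequence of segment ids; copy number is implicit in repetition.

    Orientation +1 means the segment reads in reference strand order as seen
    from the left flank; -1 means reverse complement.  The empty tuple is the
    fully deleted module, which is a legal genotype.
    """

    elements: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for sid, sign in self.elements:
            if sign not in (+1, -1):
                raise ValueError(f"orientation must be +1/-1, got {sign}")
            if sid < 1:
                raise ValueError(f"bad segment_id {sid}")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def key(self) -> str:
        return canonical_key(self)

    @classmethod
    def from_key(cls, key: str) -> "Genotype":
        key = key.strip()
        if not key:
            return cls(())
        elems = []
        for tok in key.split(","):
            tok = tok.strip()
            sign = {"+": +1, "-": -1}.get(tok[0])
            if sign is None:
                raise ValueError(f"genotype key token {tok!r} must start with +/-")
            elems.append((int(tok[1:]), sign))
        return cls(tuple(elems))

    def validate(self, design: ModuleDesign) -> None:
        for sid, _ in self.elements:
            design.segment(sid)  # raises KeyError if unknown


@dataclass(frozen=True)
class RecombinationEvent:
    """One Cre recombination between lox sites i and j (0-based, i < j).

    Site k sits immediately left of element k+1; site m (for m elements) is
    the terminal site before the right flank.  The event acts on the block of
    elements strictly between the two sites.
    """

    event_type: str
    i: int
    j: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not (0 <= self.i < self.j):
            raise ValueError(f"need 0 <= i < j, got i={self.i}, j={self.j}")


# ---------------------------------------------------------------------------
# operations


def build_reference(
    layout_table: Iterable[Mapping],
    sequences: Mapping[str, str],
    *,
    lox_sequence: str = LOXPSYM,
    left_flank: str = "",
    right_flank: str = "",
    landing_pad_length: int = 23,
    marker_inside_lox_array: bool = False,
) -> ModuleDesign:
    """Assemble a validated ModuleDesign from a layout table plus sequences.

    ``layout_table`` rows need keys ``order``, ``segment_id``, ``name`` and
    ``role``; ``sequences`` maps segment name to its DNA sequence.
    """
    rows = sorted(layout_table, key=lambda r: int(r["order"]))
    segs = []
    for row in rows:
        name = str(row["name"])
        if name not in sequences:
            raise ValueError(f"no sequence supplied for segment {name}")
        segs.append(
            SegmentSpec(
                segment_id=int(row["segment_id"]),
                name=name,
                sequence=sequences[name].upper(),
                role=str(row.get("role", "gene_cassette")),
            )
        )
    return ModuleDesign(
        segments=tuple(segs),
        lox_sequence=lox_sequence,
        left_flank=left_flank,
        right_flank=right_flank,
        landing_pad_length=landing_pad_length,
        marker_inside_lox_array=marker_inside_lox_array,
    )


def render_sequence(design: ModuleDesign, genotype: Genotype) -> str:
    """Render the amplicon sequence of a genotype (flank-to-flank)."""
    genotype.validate(design)
    lox = design.lox_sequence
    parts = [design.left_flank, lox]
    for sid, sign in genotype.elements:
        seq = design.segment(sid).sequence
        parts.append(seq if sign == +1 else revcomp(seq))
        parts.append(lox)
    parts.append(design.right_flank)
    return "".join(parts)


def apply_event(genotype: Genotype, event: RecombinationEvent) -> Genotype:
    """Apply one Cre recombination event; returns a new genotype.

    deletion   -- the block between sites i and j is excised.
    inversion  -- the block is reversed and every orientation flipped.
    duplication-- a tandem copy of the block is inserted after it.
    """
    m = len(genotype)
    if event.j > m:
        raise ValueError(f"site index j={event.j} out of range for {m} elements")
    elems = genotype.elements
    block = elems[event.i : event.j]
    if event.event_type == "deletion":
        new = elems[: event.i] + elems[event.j :]
    elif event.event_type == "inversion":
        inverted = tuple((sid, -sign) for sid, sign in reversed(block))
        new = elems[: event.i] + inverted + elems[event.j :]
    else:  # duplication
        new = elems[: event.j] + block + elems[event.j :]
    return Genotype(new)


def applicable_events(
    genotype: Genotype, allowed_types: Sequence[str] = EVENT_TYPES
) -> list[RecombinationEvent]:
    """All events available to the current genotype, in deterministic order."""
    for t in allowed_types:
        if t not in EVENT_TYPES:
            raise ValueError(f"unknown event type {t!r}")
    m = len(genotype)
    return [
        RecombinationEvent(t, i, j)
        for t in allowed_types
        for i, j in itertools.combinations(range(m + 1), 2)
    ]


def copy_numbers(genotype: Genotype, design: ModuleDesign) -> np.ndarray:
    """Per-segment copy counts (orientation-insensitive), indexed segment_id-1."""
    genotype.validate(design)
    counts = np.zeros(design.n_segments, dtype=int)
    for sid, _ in genotype.elements:
        counts[sid - 1] += 1
    return counts


def tu_count(genotype: Genotype, design: ModuleDesign) -> int:
    """Transcription-unit count: total copies of gene_cassette segments."""
    counts = copy_numbers(genotype, design)
    return int(
        sum(counts[s.segment_id - 1] for s in design.segments if s.role == "gene_cassette")
    )


def canonical_key(genotype: Genotype) -> str:
    """Deterministic text form, e.g. ``'+1,-2'``; empty genotype is ``''``.

    Orientation is meaningful (the flanks fix the reading direction), so no
    reverse-complement collapsing is done.
    """
    return ",".join(f"{'+' if sign > 0 else '-'}{sid}" for sid, sign in genotype.elements)


# ---------------------------------------------------------------------------
# default construct


#: Approximate defragmented-cassette lengths (bp) for the seven HIS genes:
#: ~1 kb native promoter + CDS + ~0.5 kb terminator/3'UTR, totalling a
#: ~20 kb module once linkers and flanks are added.
_HIS_CASSETTE_LENGTHS = {
    "HIS1": 2400,
    "HIS2": 2510,
    "HIS3": 2160,
    "HIS4": 3900,
    "HIS5": 2650,
    "HIS6": 2290,
    "HIS7": 3160,
}


def random_segment_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def his_module_design(seed: int = 0, flank_length: int = 300) -> ModuleDesign:
    """The package's reference construct: a synthetic 7-gene HIS module.

    Seven gene cassettes named HIS1..HIS7 with realistic cassette lengths,
    eight loxPsym linkers and flanks carrying the long-range PCR primer
    anchors.  Sequences are random DNA (seeded); only lengths and layout
    matter to the statistics the package computes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D4F44]))
    sequences = {}
    layout = []
    for idx, (name, length) in enumerate(_HIS_CASSETTE_LENGTHS.items(), start=1):
        seq = random_segment_sequence(length, rng)
        while LOXPSYM in seq or LOXPSYM in revcomp(seq):  # pragma: no cover
            seq = random_segment_sequence(length, rng)
        sequences[name] = seq
        layout.append({"order": idx, "segment_id": idx, "name": name, "role": "gene_cassette"})
    left = random_segment_sequence(flank_length, rng)
    right = random_segment_sequence(flank_length, rng)
    return build_reference(
        layout, sequences, left_flank=left, right_flank=right
    )
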