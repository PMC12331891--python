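"""Explain a called genotype as segment-level structural events + gene impact.

The explanation is descriptive, not a minimal recombination history (the
number of Cre events that produced a genotype is unknowable from one
snapshot):

* a segment with copy number 0 is a **deletion**;
* a segment with copy number >= 2 is a **duplication** (copy_delta = copy-1);
* a maximal run of '-'-oriented elements whose ids descend consecutively in
  reference order is an **inversion_block** (an isolated '-' element is its
  own block).

Gene impact maps events onto an annotation: deleted / duplicated / inverted
directly from the events, plus **utr_disrupted** when a deletion or inversion
boundary (a loxPsym site in reference coordinates) falls strictly inside a
gene's annotated 3'UTR.  In loxPsym-bearing constructs the 3'UTR commonly
extends past the downstream lox site, so recombination there severs the
terminator from its gene even when the CDS is intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .design import Genotype, ModuleDesign, copy_numbers

__all__ = [
    "EventCall",
    "ImpactRecord",
    "diff_genotype",
    "annotate_gene_impact",
]


@dataclass(frozen=True)
class EventCall:
    event_type: str  # deletion | duplication | inversion_block
    segments: tuple[str, ...]  # segment names involved, reference order
    interval: tuple[int, int] | None = None  # element span in observed genotype
    copy_delta: int = 0


@dataclass(frozen=True)
class ImpactRecord:
    gene: str
    impact: frozenset[str]  # subset of {deleted, duplicated, inverted, utr_disrupted}
    evidence: str = ""

    @property
    def unaffected(self) -> bool:
        return not self.impact


def diff_genotype(reference_design: ModuleDesign, observed: Genotype) -> list[EventCall]:
    """Segment-level events distinguishing an observed genotype from parental."""
    observed.validate(reference_design)
    counts = copy_numbers(observed, reference_design)
    events: list[EventCall] = []
    for seg in reference_design.segments:
        c = counts[seg.segment_id - 1]
        if c == 0:
            events.append(EventCall("deletion", (seg.name,)))
        elif c >= 2:
            events.append(EventCall("duplication", (seg.name,), copy_delta=int(c) - 1))
    # maximal runs of '-' elements with consecutive-descending reference ids
    elems = observed.elements
    i = 0
    while i < len(elems):
        sid, sign = elems[i]
        if sign == -1:
            j = i + 1
            while j < len(elems) and elems[j][1] == -1 and elems[j][0] == elems[j - 1][0] - 1:
                j += 1
            ids = sorted(e[0] for e in elems[i:j])
            names = tuple(reference_design.segment(s).name for s in ids)
            events.append(EventCall("inversion_block", names, interval=(i, j)))
            i = j
        else:
            i += 1
    return events


def _boundary_lox_indices(events: Sequence[EventCall], design: ModuleDesign) -> set[int]:
    """Reference lox-site indices (0..n) at deletion/inversion boundaries."""
    name_to_id = {s.name: s.segment_id for s in design.segments}
    sites: set[int] = set()
    for ev in events:
        if ev.event_type == "duplication":
            continue
        ids = [name_to_id[n] for n in ev.segments]
        # block of reference segments [a..b] is bounded by lox a-1 and lox b
        sites.add(min(ids) - 1)
        sites.add(max(ids))
    return sites


def _reference_lox_positions(design: ModuleDesign, module_offset: int) -> list[int]:
    """0-based start of each reference lox site within the annotated contig."""
    lox_len = len(design.lox_sequence)
    positions = []
    pos = module_offset + len(design.left_flank)
    positions.append(pos)
    for seg in design.segments:
        pos += lox_len + len(seg)
        positions.append(pos)
    return positions


def _load_gff(gff3) -> gffutils.FeatureDB:
    if isinstance(gff3, gffutils.FeatureDB):
        return gff3
    path = Path(gff3)
    return gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )


def annotate_gene_impact(
    events: Sequence[EventCall],
    gff3,
    design: ModuleDesign,
) -> list[ImpactRecord]:
    """One impact record per annotated module gene.

    ``gff3`` is a path or a gffutils FeatureDB containing ``gene`` features
    whose Name matches a design segment (as written by make_genome_fixture),
    optionally with ``three_prime_UTR`` children.  When a gene has no 3'UTR
    feature, a 200 bp window downstream of the gene is used and the record is
    flagged as inferred.
    """
    db = _load_gff(gff3)
    gene_features = {}
    for feat in db.features_of_type("gene"):
        name = feat.attributes.get("Name", [feat.id])[0]
        gene_features[name] = feat
    segment_names = {s.name for s in design.segments}
    module_genes = set(gene_features) & segment_names
    if not module_genes:
        raise ValueError("GFF3 contains no gene features matching design segments")

    try:
        module = next(iter(db.features_of_type("region")))
        module_offset = module.start - 1
    except StopIteration:
        module_offset = 0
    lox_positions = _reference_lox_positions(design, module_offset)
    boundary_sites = _boundary_lox_indices(events, design)
    boundary_coords = [lox_positions[i] for i in sorted(boundary_sites)]

    by_gene: dict[str, set[str]] = {name: set() for name in sorted(module_genes)}
    evidence: dict[str, list[str]] = {name: [] for name in by_gene}
    for ev in events:
        label = {"deletion": "deleted", "duplication": "duplicated", "inversion_block": "inverted"}[
            ev.event_type
        ]
        for name in ev.segments:
            if name in by_gene:
                by_gene[name].add(label)
                evidence[name].append(f"{ev.event_type}:{','.join(ev.segments)}")

    lox_len = len(design.lox_sequence)
    records: list[ImpactRecord] = []
    for name in sorted(by_gene):
        feat = gene_features[name]
        utrs = [
            (u.start - 1, u.end)
            for u in db.children(feat, featuretype="three_prime_UTR")
        ]
        inferred = False
        if not utrs:
            utrs = [(feat.end, feat.end + 200)]  # fallback window downstream
            inferred = True
        impacts = set(by_gene[name])
        if "deleted" not in impacts:
            # a recombination junction is disrupting when a lox-site edge
            # [pos, pos+lox_len) falls strictly inside the UTR interval
            for a, b in utrs:
                if any(a < pos < b or a < pos + lox_len < b for pos in boundary_coords):
                    impacts.add("utr_disrupted")
                    evidence[name].append(
                        "boundary_in_3utr(inferred)" if inferred else "boundary_in_3utr"
                    )
                    break
        records.append(
            ImpactRecord(gene=name, impact=frozenset(impacts), evidence=";".join(evidence[name]))
        )
    return records
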