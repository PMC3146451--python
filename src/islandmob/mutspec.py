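"""Strain-pair mutation calling and spectrum classification.

Differences between two closely related genomes (given as a 2-row
alignment, reference first) are merged into events: maximal runs of
adjacent difference columns count once.  Single-base substitutions are
split into transitions and transversions; multi-base substitution runs are
multi-nucleotide polymorphisms (mnp); gap runs are insertions or deletions
relative to the reference row.  Coding effects are classified against CDS
annotations on the reference: frameshift (indel length not divisible by
3), synonymous, nonsynonymous (including in-frame indels), or truncation
(a new stop codon).
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .seqio import FeatureAnnotation, MultipleAlignment
from .selection import classify_substitution

KINDS = ("insertion", "deletion", "transition", "transversion", "mnp")
EFFECTS = ("frameshift", "synonymous", "nonsynonymous", "truncation",
           "intergenic")


@dataclass
class MutationEvent:
    position: int            # 0-based position on the ungapped reference
    kind: str
    length: int
    ref_allele: str
    alt_allele: str
    effect: str | None = None
    gene_id: str | None = None


@dataclass
class SpectrumSummary:
    n_events: int
    kind_fractions: dict[str, float]
    effect_fractions: dict[str, float]
    per_site_divergence: float


# ---------------------------------------------------------------------------

def _difference_runs(ref: str, alt: str) -> list[tuple[int, int]]:
    """Maximal runs [start, end) of alignment columns where the rows differ
    (columns where both rows are gaps never differ)."""
    runs = []
    start = None
    for j in range(len(ref)):
        differ = ref[j] != alt[j] and not (ref[j] == "-" and alt[j] == "-")
        if differ and start is None:
            start = j
        elif not differ and start is not None:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, len(ref)))
    return runs


def _classify_run(ref_seg: str, alt_seg: str) -> str:
    n_sub = sum(1 for a, b in zip(ref_seg, alt_seg)
                if a != "-" and b != "-" and a != b)
    n_gap = sum(1 for a, b in zip(ref_seg, alt_seg) if a == "-" or b == "-")
    if n_gap == 0:
        if len(ref_seg) == 1:
            return classify_substitution(ref_seg, alt_seg).change
        return "mnp"
    if n_sub > n_gap:
        return "mnp"
    # indel (majority gap, or tie -> indel); direction from the gap side
    ref_gaps = ref_seg.count("-")
    return "insertion" if ref_gaps >= n_gap - ref_gaps else "deletion"


def call_mutations(pair: MultipleAlignment,
                   features: list[FeatureAnnotation] | None = None
                   ) -> list[MutationEvent]:
    """Merge adjacent difference columns of a 2-row alignment into events
    and classify each; ``features`` are CDS annotations in ungapped
    reference (row 1) coordinates."""
    if pair.n_rows != 2:
        raise ValueError("expected a 2-row alignment")
    ref, alt = pair.rows
    # alignment column -> ungapped reference coordinate
    ref_pos = []
    p = 0
    for c in ref:
        ref_pos.append(p)
        p += c != "-"
    ref_len = p
    events = []
    for start, end in _difference_runs(ref, alt):
        ref_seg, alt_seg = ref[start:end], alt[start:end]
        kind = _classify_run(ref_seg, alt_seg)
        ev = MutationEvent(ref_pos[start], kind, end - start,
                           ref_seg.replace("-", ""), alt_seg.replace("-", ""))
        if features is not None:
            _attach_effect(ev, ref.replace("-", ""), features)
        events.append(ev)
    if features is not None:
        assert ref_len == len(ref.replace("-", ""))
    return events


def _attach_effect(ev: MutationEvent, ref_seq: str,
                   features: list[FeatureAnnotation]) -> None:
    ev_end = ev.position + len(ev.ref_allele)
    for f in features:
        if f.kind != "CDS":
            continue
        if f.start <= ev.position and max(ev_end, ev.position + 1) <= f.end:
            ev.gene_id = f.feature_id
            ev.effect = classify_effect(ev, ref_seq, f)
            return
        if f.start < max(ev_end, ev.position + 1) and ev.position < f.end:
            ev.gene_id = f.feature_id
            ev.effect = "intergenic"      # spans a CDS boundary
            return
    ev.effect = "intergenic"


def classify_effect(ev: MutationEvent, ref_seq: str,
                    cds: FeatureAnnotation) -> str:
    """Coding effect of one event fully inside a CDS."""
    indel = len(ev.ref_allele) != len(ev.alt_allele)
    if indel:
        shift = abs(len(ev.ref_allele) - len(ev.alt_allele)) % 3
        # in-frame indels fold into nonsynonymous for spectrum purposes
        return "frameshift" if shift else "nonsynonymous"
    # substitution run: rebuild the affected codons on the coding strand
    gene = ref_seq[cds.start:cds.end]
    mutated = (ref_seq[:ev.position] + ev.alt_allele
               + ref_seq[ev.position + len(ev.ref_allele):])
    gene_mut = mutated[cds.start:cds.end]
    if cds.strand == "-":
        gene = str(Seq(gene).reverse_complement())
        gene_mut = str(Seq(gene_mut).reverse_complement())
    n = len(gene) - len(gene) % 3
    aa_ref = str(Seq(gene[:n]).translate(table=11))
    aa_alt = str(Seq(gene_mut[:n]).translate(table=11))
    if aa_ref == aa_alt:
        return "synonymous"
    changed = [i for i, (a, b) in enumerate(zip(aa_ref, aa_alt)) if a != b]
    if any(aa_alt[i] == "*" for i in changed):
        return "truncation"
    return "nonsynonymous"


def summarize_spectrum(events: list[MutationEvent],
                       aligned_bp: int) -> SpectrumSummary:
    """Fractions of events by kind and by coding effect, plus events per
    aligned bp."""
    if aligned_bp <= 0:
        raise ValueError("aligned_bp must be positive")
    n = len(events)
    kinds = {k: 0 for k in KINDS}
    effects = {e: 0 for e in EFFECTS}
    for ev in events:
        kinds[ev.kind] += 1
        if ev.effect is not None:
            effects[ev.effect] += 1
    n_eff = sum(effects.values())
    return SpectrumSummary(
        n,
        {k: (v / n if n else 0.0) for k, v in kinds.items()},
        {e: (v / n_eff if n_eff else 0.0) for e, v in effects.items()},
        n / aligned_bp,
    )
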