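"""Locate ssrA, scan for direct repeats of its 3' tag, delineate tandem
genomic islands, and detect attL-adjacent integration modules.

Mobile elements that integrate at the single-copy tmRNA gene (*ssrA*)
duplicate its 3'-terminal tag at their far boundary; tandem integrations
leave a ladder of degenerate direct repeats downstream of *ssrA*.  Islands
are therefore the intervals between consecutive repeat ends, ordered by
distance from *ssrA* (order index 1 = attL at the *ssrA* tag itself).

Repeat matching is substitution-only (Hamming distance): observed repeat
degeneracy is substitution-type.  All scanning happens on the strand that
puts *ssrA* in forward orientation; use
:func:`normalize_orientation` first if the gene is annotated on '-'.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import FeatureAnnotation, GenomeRecord, revcomp

DEFAULT_TAG_LENGTH = 20
DEFAULT_SCAN_WINDOW = 100_000
DEFAULT_MAX_MISMATCHES = 3

MODULE_ROLE_ORDER = ("dsiB", "dsiA", "recF-like", "parB-like",
                     "mom-like", "rnap-domain")
#: attL-adjacency rule: first module CDS must start within this many bp of attL
ATTL_ADJACENT_BP = 500

_TABLE11 = unambiguous_dna_by_id[11]
_STOPS = frozenset(_TABLE11.stop_codons)
_STARTS = frozenset(("ATG", "GTG", "TTG"))


class SsrANotFoundError(ValueError):
    pass


class AmbiguousPlacementError(ValueError):
    pass


@dataclass(frozen=True)
class TmRNALocus:
    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str
    three_prime_tag: str

    def __post_init__(self):
        n = len(self.three_prime_tag)
        if self.sequence[-n:] != self.three_prime_tag:
            raise ValueError("tag must equal the 3'-terminal bases of ssrA")


@dataclass(frozen=True)
class RepeatHit:
    start: int                  # genomic start (ssrA-forward orientation)
    matched: str
    mismatches: int
    offset_from_ssrA_end: int   # bp from ssrA 3' end to repeat start

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


@dataclass(frozen=True)
class RoleMatch:
    role: str
    feature: FeatureAnnotation
    identity: float
    coverage: float


@dataclass
class IntegrationModule:
    gene_roles: list[str]
    gene_refs: list[FeatureAnnotation]
    matches: list[RoleMatch]
    trna_locus: tuple[int, int] | None = None
    trna_canonical_position: bool = False
    trna_mismatches: int | None = None
    rubredoxin_gene: FeatureAnnotation | None = None


@dataclass
class GenomicIsland:
    genome_id: str
    order_index: int
    attL: int                  # 0-based start of the island interval
    attR: int                  # 0-based end (= end of the bounding repeat)
    genes: list[FeatureAnnotation]
    has_integration_module: bool = False
    module: IntegrationModule | None = None

    @property
    def length(self) -> int:
        return self.attR - self.attL


# ---------------------------------------------------------------------------
# packaged reference fixtures (synthetic stand-ins, see data/ docstrings)

def _data_path(name):
    return resources.files("islandmob.data").joinpath(name)


def packaged_ssra() -> str:
    with _data_path("ssra_synthetic.fa").open() as fh:
        return str(next(SeqIO.parse(fh, "fasta")).seq).upper()


def packaged_module_proteins() -> dict[str, str]:
    with _data_path("integration_module_proteins_synthetic.faa").open() as fh:
        return {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}


def packaged_trna_consensus() -> str:
    with _data_path("trna_consensus_synthetic.fa").open() as fh:
        return str(next(SeqIO.parse(fh, "fasta")).seq).upper()


# ---------------------------------------------------------------------------
# ssrA location and orientation

def normalize_orientation(genome: GenomeRecord,
                          locus: TmRNALocus) -> tuple[GenomeRecord, TmRNALocus]:
    """Return (genome, locus) with ssrA on the forward strand so that
    'downstream of ssrA' always means increasing coordinate."""
    if locus.strand == "+":
        return genome, locus
    flipped = genome.reverse_complement()
    n = len(genome)
    return flipped, TmRNALocus(locus.genome_id, n - locus.end, n - locus.start,
                               "+", locus.sequence, locus.three_prime_tag)


def locate_ssrA(genome: GenomeRecord, reference_ssrA: str | None = None,
                tag_length: int = DEFAULT_TAG_LENGTH,
                min_identity: float = 0.80) -> TmRNALocus:
    """Find the single-copy ssrA locus.

    An annotated tmRNA feature wins; otherwise the reference gene is placed
    by local alignment (both strands) and accepted at >= ``min_identity``
    identity over the reference length.  Ties between equally good
    placements raise :class:`AmbiguousPlacementError`.
    """
    tmrnas = [f for f in genome.features if f.kind == "tmRNA"]
    if tmrnas:
        if len(tmrnas) > 1:
            raise AmbiguousPlacementError(
                f"{genome.id}: {len(tmrnas)} tmRNA features annotated")
        f = tmrnas[0]
        seq = genome.feature_seq(f)
        return TmRNALocus(genome.id, f.start, f.end, f.strand, seq,
                          seq[-tag_length:])
    if reference_ssrA is None:
        raise SsrANotFoundError(
            f"{genome.id}: no tmRNA annotation and no reference provided")

    aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-1)
    best = []
    for strand, target in (("+", genome.sequence),
                           ("-", revcomp(genome.sequence))):
        alns = aligner.align(target, reference_ssrA)
        if len(alns) == 0:
            continue
        best.append((alns.score, strand, alns[0]))
    if not best:
        raise SsrANotFoundError(f"{genome.id}: reference ssrA not alignable")
    best.sort(key=lambda t: -t[0])
    if len(best) == 2 and best[0][0] == best[1][0]:
        raise AmbiguousPlacementError(
            f"{genome.id}: two equally good ssrA placements")
    score, strand, aln = best[0]
    tstart, tend = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    ident = _alignment_identity(aln)
    if ident < min_identity:
        raise SsrANotFoundError(
            f"{genome.id}: best ssrA placement identity {ident:.2f} < "
            f"{min_identity:.2f}")
    if strand == "-":
        n = len(genome)
        tstart, tend = n - tend, n - tstart
    seq = genome.subseq(tstart, tend, strand)
    return TmRNALocus(genome.id, tstart, tend, strand, seq, seq[-tag_length:])


def _alignment_identity(aln) -> float:
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(aln.query)


def extract_tag(locus: TmRNALocus, tag_length: int = DEFAULT_TAG_LENGTH) -> str:
    """3'-terminal ``tag_length`` bases of the gene in reading orientation."""
    if len(locus.sequence) < tag_length:
        raise ValueError(
            f"ssrA length {len(locus.sequence)} < tag length {tag_length}")
    return locus.sequence[-tag_length:]


# ---------------------------------------------------------------------------
# direct-repeat scan

def hamming_scan(sequence: str, pattern: str, max_mismatches: int,
                 region_start: int = 0, region_end: int | None = None
                 ) -> list[tuple[int, int]]:
    """All (start, mismatches) placements of ``pattern`` in
    ``sequence[region_start:region_end]`` with Hamming distance <=
    ``max_mismatches``.  'N' never matches."""
    if region_end is None:
        region_end = len(sequence)
    sub = sequence[region_start:region_end]
    m = len(pattern)
    if len(sub) < m:
        return []
    arr = np.frombuffer(sub.encode(), np.uint8)
    pat = np.frombuffer(pattern.encode(), np.uint8)
    win = sliding_window_view(arr, m)
    # 'N' never matches: with an A/C/G/T pattern the != test already counts
    # it as a mismatch; 'N' in the pattern itself is rejected upstream.
    mism = (win != pat).sum(axis=1)
    keep = np.nonzero(mism <= max_mismatches)[0]
    return [(region_start + int(i), int(mism[i])) for i in keep]


def scan_direct_repeats(genome: GenomeRecord, locus: TmRNALocus, tag: str,
                        scan_window: int = DEFAULT_SCAN_WINDOW,
                        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                        merge_overlapping: bool = True) -> list[RepeatHit]:
    """Report degenerate copies of the ssrA 3' tag starting within
    ``scan_window`` bp downstream of the ssrA 3' end, sorted by offset.

    Hits closer than one tag length to each other are merged, keeping the
    lower-mismatch (then leftmost) hit.
    """
    if set(tag) - set("ACGT"):
        raise ValueError("tag must be non-degenerate (A/C/G/T only)")
    if locus.strand != "+":
        raise ValueError("normalize_orientation() before scanning")
    start = locus.end + 1           # offsets in (0, scan_window]
    end = locus.end + scan_window + len(tag)
    if end > len(genome):
        warnings.warn(f"{genome.id}: scan window truncated at contig end")
        end = len(genome)
    raw = hamming_scan(genome.sequence, tag, max_mismatches, start, end)
    raw = [(p, mm) for p, mm in raw if p - locus.end <= scan_window]
    if merge_overlapping:
        raw = _merge_close_hits(raw, len(tag))
    return [RepeatHit(p, genome.sequence[p:p + len(tag)], mm, p - locus.end)
            for p, mm in raw]


def _merge_close_hits(hits: list[tuple[int, int]], min_sep: int
                      ) -> list[tuple[int, int]]:
    """Group hits whose starts are < min_sep apart; keep the best of each
    group (fewest mismatches, then leftmost)."""
    merged = []
    group: list[tuple[int, int]] = []
    for p, mm in hits:
        if group and p - group[-1][0] < min_sep:
            group.append((p, mm))
        else:
            if group:
                merged.append(min(group, key=lambda t: (t[1], t[0])))
            group = [(p, mm)]
    if group:
        merged.append(min(group, key=lambda t: (t[1], t[0])))
    return merged


# ---------------------------------------------------------------------------
# island delineation

def delineate_islands(genome: GenomeRecord, locus: TmRNALocus,
                      hits: list[RepeatHit],
                      genes: list[FeatureAnnotation] | None = None
                      ) -> list[GenomicIsland]:
    """Partition [ssrA end, last repeat end) into tandem islands.

    Island *i* spans from the end of boundary *i-1* (boundary 0 = the ssrA
    3' end, whose final 20 bp are attL of island 1) to the end of repeat
    *i*.  Genes are assigned to the island containing their midpoint.
    """
    if genes is None:
        genes = genome.features
    if not hits:
        return []
    offsets = [h.offset_from_ssrA_end for h in hits]
    if offsets != sorted(offsets):
        raise ValueError("hits must be sorted by offset")
    boundaries = [locus.end] + [h.end for h in hits]
    islands = []
    for i in range(1, len(boundaries)):
        attL, attR = boundaries[i - 1], boundaries[i]
        members = [g for g in genes if attL <= g.midpoint() < attR
                   and g.kind == "CDS"]
        islands.append(GenomicIsland(genome.id, i, attL, attR, members))
    return _drop_duplicate_islands(islands)


def _drop_duplicate_islands(islands: list[GenomicIsland]) -> list[GenomicIsland]:
    """No duplicate islands (identical non-empty gene content) per genome."""
    seen, out = set(), []
    for isl in islands:
        key = tuple((g.length, g.strand, g.product) for g in isl.genes)
        if isl.genes and key in seen:
            continue
        seen.add(key)
        out.append(isl)
    for i, isl in enumerate(out, start=1):
        isl.order_index = i
    return out


# ---------------------------------------------------------------------------
# ORF fallback (bacterial translation table 11)

def call_orfs(genome: GenomeRecord, start: int, end: int,
              min_length: int = 150) -> list[FeatureAnnotation]:
    """Naive ORF caller on both strands within [start, end): ATG/GTG/TTG
    start to the next in-frame table-11 stop, >= min_length nt."""
    orfs = []
    region = genome.sequence[start:end]
    n = len(region)
    for strand in ("+", "-"):
        seq = region if strand == "+" else revcomp(region)
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                codon = seq[i:i + 3]
                if codon in _STARTS:
                    j = i + 3
                    while j + 3 <= n and seq[j:j + 3] not in _STOPS:
                        j += 3
                    if j + 3 <= n:  # found a stop
                        length = j + 3 - i
                        if length >= min_length:
                            if strand == "+":
                                s, e = start + i, start + j + 3
                            else:
                                s, e = start + n - (j + 3), start + n - i
                            orfs.append(FeatureAnnotation(
                                f"{genome.id}_orf_{s}_{strand}", "CDS",
                                s, e, strand, "predicted ORF"))
                        i = j + 3
                        continue
                i += 3
    orfs.sort(key=lambda f: f.start)
    return orfs


def translate_feature(genome: GenomeRecord, f: FeatureAnnotation) -> str:
    aa = str(Seq(genome.feature_seq(f)).translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# integration-module detection

_blosum62 = substitution_matrices.load("BLOSUM62")


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = _blosum62
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _identity_coverage(query: str, ref: str, aligner) -> tuple[float, float]:
    alns = aligner.align(query.replace("*", "X"), ref)
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    cols = sum(1 for x, y in zip(a, b) if x != "-" or y != "-")
    ref_span = int(aln.aligned[1][-1][1] - aln.aligned[1][0][0])
    return (matches / cols if cols else 0.0, ref_span / len(ref))


def detect_integration_module(genome: GenomeRecord, island: GenomicIsland,
                              reference_proteins: dict[str, str] | None = None,
                              min_identity: float = 0.25,
                              min_coverage: float = 0.5,
                              length_tolerance: float = 0.20
                              ) -> IntegrationModule | None:
    """Detect the six-gene, reverse-strand integration module adjacent to attL.

    A module is reported iff >= 5 of the 6 roles match in attL-proximal
    order, each by local protein alignment (BLOSUM62) at identity >=
    ``min_identity`` over coverage >= ``min_coverage``, the matched gene
    lengths within ``length_tolerance`` of the reference, and the
    attL-adjacent gene matches DsiB.  Returns ``None`` (with no side
    effects) when absent.
    """
    if reference_proteins is None:
        reference_proteins = packaged_module_proteins()
    cds = [g for g in island.genes if g.kind == "CDS" and g.strand == "-"]
    if not cds:
        cds = [f for f in call_orfs(genome, island.attL, island.attR)
               if f.strand == "-"]
    if not cds:
        return None
    cds.sort(key=lambda f: f.start)
    min_aa = (1 - length_tolerance) * min(len(p) for p in
                                          reference_proteins.values())
    candidates = [g for g in cds if g.length / 3 - 1 >= min_aa]
    aligner = _protein_aligner()
    matches: list[RoleMatch] = []
    gi = 0
    for role in MODULE_ROLE_ORDER:
        ref = reference_proteins[role]
        found = None
        for k in range(gi, len(candidates)):
            g = candidates[k]
            aa_len = g.length / 3 - 1
            if abs(aa_len - len(ref)) > length_tolerance * len(ref):
                continue
            ident, cov = _identity_coverage(translate_feature(genome, g), ref,
                                            aligner)
            if ident >= min_identity and cov >= min_coverage:
                found = (k, RoleMatch(role, g, ident, cov))
                break
        if found is not None:
            gi = found[0] + 1
            matches.append(found[1])
    if len(matches) < 5:
        return None
    if matches[0].role != "dsiB":
        return None
    if matches[0].feature.start - island.attL > ATTL_ADJACENT_BP:
        return None
    module = IntegrationModule([m.role for m in matches],
                               [m.feature for m in matches], matches)
    module.rubredoxin_gene = _find_rubredoxin(island, matches[-1].feature)
    return module


def _find_rubredoxin(island: GenomicIsland, last_module_gene: FeatureAnnotation
                     ) -> FeatureAnnotation | None:
    """First forward-strand CDS within 1 kb downstream of the module (the
    seventh, oppositely oriented module-associated gene)."""
    after = [g for g in island.genes
             if g.strand == "+" and g.kind == "CDS"
             and 0 <= g.start - last_module_gene.end <= 1000]
    return min(after, key=lambda g: g.start) if after else None


def locate_module_trna(genome: GenomeRecord, island: GenomicIsland,
                       module: IntegrationModule,
                       trna_consensus: str | None = None,
                       max_mismatches: int = 15,
                       search_bp: int = 300,
                       expected_offset: int = 4400,
                       offset_tolerance: int = 1500
                       ) -> tuple[tuple[int, int], bool, int] | None:
    """Best Hamming placement of the 76 bp tRNA-like consensus within the
    first ``search_bp`` of the fifth module gene (reading orientation).

    Returns ``((start, end), canonical_flag, mismatches)`` in genomic
    coordinates, or None if no placement is within ``max_mismatches``.
    The flag is set iff the placement starts within the first 150 bp of the
    gene and lies ``expected_offset`` +/- ``offset_tolerance`` bp from attL.
    """
    if trna_consensus is None:
        trna_consensus = packaged_trna_consensus()
    if "mom-like" not in module.gene_roles:
        return None
    gene = module.gene_refs[module.gene_roles.index("mom-like")]
    reading = genome.feature_seq(gene)[:search_bp]
    m = len(trna_consensus)
    if len(reading) < m:
        return None
    arr = np.frombuffer(reading.encode(), np.uint8)
    pat = np.frombuffer(trna_consensus.encode(), np.uint8)
    win = sliding_window_view(arr, m)
    mism = (win != pat).sum(axis=1)
    best = int(np.argmin(mism))
    if int(mism[best]) > max_mismatches:
        return None
    if gene.strand == "-":
        g_end = gene.end - best
        g_start = g_end - m
    else:
        g_start = gene.start + best
        g_end = g_start + m
    dist = g_start - island.attL
    flag = best < 150 and abs(dist - expected_offset) <= offset_tolerance
    module.trna_locus = (g_start, g_end)
    module.trna_canonical_position = flag
    module.trna_mismatches = int(mism[best])
    return (g_start, g_end), flag, int(mism[best])
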