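"""Seeded generators for genomes, alignments, strain pairs and clock trees
with recorded ground truth.

The island-genome generator emulates the structure the scanner assumes: a
host genome carrying a single-copy tmRNA gene (ssrA) whose 3'-terminal
20 bp tag is duplicated at island boundaries, tandem islands within
100 kbp downstream, a six-gene reverse-strand integration module adjacent
to attL with a 76 bp tRNA-like locus embedded in the fifth gene ~4.4 kbp
from attL, a degenerate 15 bp attachment motif immediately 5' of every
repeat, and a high-identity cargo gene whose leader accumulates
substitutions faster than its body (optionally nonsynonymous-only in the
body).  Background sequence is scrubbed of accidental near-copies of the
tag so planted boundaries are the only callable ones.

All generators are deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .att_analysis import IUPAC
from .island_scanner import hamming_scan, packaged_module_proteins, \
    packaged_ssra, packaged_trna_consensus, MODULE_ROLE_ORDER
from .seqio import FeatureAnnotation, GenomeRecord, MultipleAlignment, \
    PhyloTree, revcomp
from .selection import BASES, CODON_AA, STOP_CODONS

#: attachment-site motif planted 5' of every direct repeat (IUPAC-degenerate)
DEFAULT_ATT_MOTIF = "TTCAGRSMGMRKCCA"

_IUPAC_BASES = {code: sorted(bases) for bases, code in IUPAC.items()}

_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in CODON_AA.items():
    _AA_CODONS.setdefault(aa, []).append(codon)

#: module layout: attL offset of gene 1 and inter-gene spacer, tuned so the
#: fifth gene ends ~4.4 kbp from attL (matching the canonical tRNA position)
_MODULE_ATTL_OFFSET = 10
_MODULE_SPACER = 66
_TRNA_READING_OFFSET = 34        # tRNA start within gene 5, reading orientation


@dataclass
class CargoSpec:
    leader_bp: int = 129
    leader_sub_rate: float = 0.05
    body_sub_rate: float = 0.003
    body_nonsyn_only: bool = True


@dataclass
class IslandSpec:
    length: int = 12000
    has_module: bool = True
    module_divergence: float = 0.30
    repeat_mismatches: int = 0
    cargo: CargoSpec | None = field(default_factory=CargoSpec)


@dataclass
class IslandSimSpec:
    seed: int = 0
    genome_length: int = 60000
    gc: float = 0.47
    leading_bp: int = 1000
    ssra_sequence: str | None = None   # default: the packaged synthetic gene
    tag_length: int = 20
    islands: list[IslandSpec] = field(default_factory=lambda: [IslandSpec()])


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream analysis."""
    ssra_interval: tuple[int, int] | None = None
    tag: str | None = None
    island_boundaries: list[tuple[int, int]] = field(default_factory=list)
    repeat_positions: list[tuple[int, int]] = field(default_factory=list)
    module_genes: list[list[tuple[str, int, int]]] = field(default_factory=list)
    trna_positions: list[tuple[int, int] | None] = field(default_factory=list)
    att_motif_realizations: list[str] = field(default_factory=list)
    cargo_genes: list[tuple[int, int] | None] = field(default_factory=list)
    cargo_mutations: list[list[int]] = field(default_factory=list)
    mutation_events: list[tuple[int, str, int]] = field(default_factory=list)
    leader_positions: list[int] = field(default_factory=list)
    body_positions: list[int] = field(default_factory=list)
    tree_newick: str | None = None
    tree_height: float | None = None


# ---------------------------------------------------------------------------
# low-level sequence helpers

def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _substitute(rng: np.random.Generator, base: str) -> str:
    return rng.choice([b for b in BASES if b != base])


def _coding_substitute(rng: np.random.Generator, row: list[str], i: int) -> str:
    """A substitution at coding position i that does not create a stop."""
    ci = i // 3 * 3
    codon = "".join(row[ci:ci + 3])
    cands = [b for b in BASES if b != row[i]
             and codon[:i - ci] + b + codon[i - ci + 1:] not in STOP_CODONS]
    return rng.choice(cands) if cands else row[i]


def _mutate_protein(rng: np.random.Generator, aa_seq: str, rate: float) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(aa_seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = rng.choice([a for a in aas if a != out[i]])
    return "".join(out)


def back_translate(rng: np.random.Generator, aa_seq: str,
                   stop: str = "TAA") -> str:
    """Back-translation with uniform synonymous codon choice (table 11)."""
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in aa_seq) + stop


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    sense = [c for c in CODON_AA]
    return "".join(rng.choice(sense) for _ in range(n_codons))


def _realize_motif(rng: np.random.Generator, motif: str) -> str:
    return "".join(rng.choice(_IUPAC_BASES[c]) for c in motif)


def _degenerate_tag(rng: np.random.Generator, tag: str, n_mismatch: int) -> str:
    pos = rng.choice(len(tag), size=n_mismatch, replace=False)
    out = list(tag)
    for i in pos:
        out[i] = _substitute(rng, out[i])
    return "".join(out)


def scrub_near_matches(rng: np.random.Generator, sequence: list[str],
                       tag: str, protected: list[tuple[int, int]],
                       max_mismatches: int = 4) -> None:
    """Destroy accidental near-copies of the tag (in place) so only planted
    repeats are callable; windows overlapping protected intervals are left."""
    for _ in range(5):
        hits = hamming_scan("".join(sequence), tag, max_mismatches)
        dirty = False
        for start, _mm in hits:
            end = start + len(tag)
            if any(s < end and start < e for s, e in protected):
                continue
            free = [i for i in range(start, end)
                    if not any(s <= i < e for s, e in protected)]
            if not free:
                continue
            i = int(rng.choice(free))
            sequence[i] = _substitute(rng, sequence[i])
            dirty = True
        if not dirty:
            return


# ---------------------------------------------------------------------------
# reference cargo operon (deterministic, shared across simulated genomes)

_CARGO_CODONS = 520          # 1560 nt: 129 bp leader + 1431 bp body


def reference_cargo_cds() -> str:
    rng = np.random.default_rng(777)
    return _random_coding(rng, _CARGO_CODONS) + "TAA"


def _mutate_cargo(rng: np.random.Generator, cds: str, spec: CargoSpec
                  ) -> tuple[str, list[int]]:
    """Apply leader/body substitutions to one island's cargo copy."""
    out = list(cds)
    positions = []
    coding_len = len(cds) - 3          # exclude the stop codon
    for i in range(coding_len):
        rate = spec.leader_sub_rate if i < spec.leader_bp else spec.body_sub_rate
        if rng.random() >= rate:
            continue
        if i >= spec.leader_bp and spec.body_nonsyn_only:
            ci = i // 3 * 3
            codon = "".join(out[ci:ci + 3])
            alts = []
            for b in BASES:
                if b == out[i]:
                    continue
                alt = codon[:i - ci] + b + codon[i - ci + 1:]
                if alt not in STOP_CODONS and CODON_AA[alt] != CODON_AA.get(codon):
                    alts.append(b)
            if not alts:
                continue
            out[i] = rng.choice(alts)
        else:
            new = _coding_substitute(rng, out, i)
            if new == out[i]:
                continue
            out[i] = new
        positions.append(i)
    return "".join(out), positions


# ---------------------------------------------------------------------------
# island genome generator

def generate_island_genome(spec: IslandSimSpec
                           ) -> tuple[GenomeRecord, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    ssra = (spec.ssra_sequence or packaged_ssra()).upper()
    tag = ssra[-spec.tag_length:]
    truth = GroundTruth(tag=tag)
    refs = packaged_module_proteins()
    trna = packaged_trna_consensus()

    seq: list[str] = list(_random_nt(rng, spec.leading_bp, spec.gc))
    features: list[FeatureAnnotation] = []
    protected: list[tuple[int, int]] = []

    ssra_start = len(seq)
    seq.extend(ssra)
    ssra_end = len(seq)
    truth.ssra_interval = (ssra_start, ssra_end)
    features.append(FeatureAnnotation("ssrA", "tmRNA", ssra_start, ssra_end,
                                      "+", "transfer-messenger RNA"))
    protected.append((ssra_start, ssra_end))

    total_island_bp = sum(isl.length for isl in spec.islands)
    if total_island_bp > 100_000:
        raise ValueError("islands exceed the 100 kbp downstream window")

    for k, isl in enumerate(spec.islands):
        attL = len(seq)
        isl_seq, isl_feats, isl_truth = _build_island(
            rng, isl, attL, tag, refs, trna, spec.gc, k)
        seq.extend(isl_seq)
        attR = len(seq)
        truth.island_boundaries.append((attL, attR))
        truth.repeat_positions.append((attR - spec.tag_length,
                                       isl.repeat_mismatches))
        protected.append((attR - spec.tag_length, attR))
        features.extend(isl_feats)
        truth.module_genes.append(isl_truth["module_genes"])
        truth.trna_positions.append(isl_truth["trna"])
        truth.att_motif_realizations.append(isl_truth["motif"])
        truth.cargo_genes.append(isl_truth["cargo"])
        truth.cargo_mutations.append(isl_truth["cargo_mutations"])

    if len(seq) > spec.genome_length:
        raise ValueError(
            f"islands ({len(seq)} bp so far) overflow genome_length "
            f"{spec.genome_length}")
    seq.extend(_random_nt(rng, spec.genome_length - len(seq), spec.gc))

    scrub_near_matches(rng, seq, tag, protected)
    genome = GenomeRecord(f"sim{spec.seed}", "".join(seq), features)
    return genome, truth


def _build_island(rng, isl: IslandSpec, attL: int, tag: str,
                  refs: dict[str, str], trna: str, gc: float, index: int
                  ) -> tuple[str, list[FeatureAnnotation], dict]:
    n = isl.length
    body: list[str] = list(_random_nt(rng, n, gc))
    feats: list[FeatureAnnotation] = []
    info = {"module_genes": [], "trna": None, "motif": None, "cargo": None,
            "cargo_mutations": []}

    cursor = _MODULE_ATTL_OFFSET
    if isl.has_module:
        for role in MODULE_ROLE_ORDER:
            aa = _mutate_protein(rng, refs[role], isl.module_divergence)
            cds = back_translate(rng, aa)
            start, end = cursor, cursor + len(cds)
            body[start:end] = list(revcomp(cds))       # reverse strand
            feats.append(FeatureAnnotation(
                f"isl{index}_{role}", "CDS", attL + start, attL + end, "-",
                f"{role} homolog"))
            info["module_genes"].append((role, attL + start, attL + end))
            cursor = end + _MODULE_SPACER
        # tRNA-like locus inside the fifth gene (mom-like), reading orientation
        _, g5s, g5e = info["module_genes"][4]
        t_end = g5e - attL - _TRNA_READING_OFFSET
        t_start = t_end - len(trna)
        body[t_start:t_end] = list(revcomp(trna))
        info["trna"] = (attL + t_start, attL + t_end)
        feats.append(FeatureAnnotation(
            f"isl{index}_trna", "tRNA", attL + t_start, attL + t_end, "-",
            "tRNA-like locus"))
        # seventh, forward-strand rubredoxin-domain gene after the module
        rub = back_translate(
            rng, "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 54)))
        rs = cursor + 80
        body[rs:rs + len(rub)] = list(rub)
        feats.append(FeatureAnnotation(
            f"isl{index}_rubredoxin", "CDS", attL + rs, attL + rs + len(rub),
            "+", "rubredoxin domain protein"))
        cursor = rs + len(rub) + 50

    if isl.cargo is not None:
        cds, muts = _mutate_cargo(rng, reference_cargo_cds(), isl.cargo)
        cs = cursor + 100
        if cs + len(cds) > n - 200:
            raise ValueError("island too short for its cargo gene")
        body[cs:cs + len(cds)] = list(cds)
        feats.append(FeatureAnnotation(
            f"isl{index}_cargoA", "CDS", attL + cs, attL + cs + len(cds), "+",
            "reductive dehalogenase cargo"))
        info["cargo"] = (attL + cs, attL + cs + len(cds))
        info["cargo_mutations"] = [attL + cs + p for p in muts]

    # attachment motif + degenerate repeat close the island
    motif = _realize_motif(rng, DEFAULT_ATT_MOTIF)
    repeat = _degenerate_tag(rng, tag, isl.repeat_mismatches)
    body[n - len(tag):] = list(repeat)
    body[n - len(tag) - len(motif):n - len(tag)] = list(motif)
    info["motif"] = motif
    return "".join(body), feats, info


# ---------------------------------------------------------------------------
# cargo alignment generator

def generate_cargo_alignment(n_rows: int, length: int,
                             leader_bp: int = 129,
                             leader_rate: float = 0.05,
                             body_rate: float = 0.003,
                             body_nonsyn_only: bool = True,
                             seed: int = 0
                             ) -> tuple[MultipleAlignment, GroundTruth]:
    """Rows evolved from one coding ancestor with distinct leader/body
    substitution regimes (gapless alignment).

    Leader columns mutate independently per row at ``leader_rate``.  Body
    variant columns arise as shared substitution events: each selected
    column (at most one per codon) gets a single derived allele carried by
    a random proper subset of rows, and with ``body_nonsyn_only`` the
    derived allele is chosen to change the encoded amino acid -- so every
    pairwise body difference is nonsynonymous, as in a cargo gene under
    recent positive selection.
    """
    if length % 3:
        raise ValueError("length must be divisible by 3")
    if leader_bp % 3:
        raise ValueError("leader must end on a codon boundary")
    rng = np.random.default_rng(seed)
    ancestor = _random_coding(rng, length // 3)
    truth = GroundTruth()
    rows = [list(ancestor) for _ in range(n_rows)]
    # leader: independent per-row substitutions (kept stop-free)
    for r in rows:
        for i in range(min(leader_bp, length)):
            if rng.random() < leader_rate:
                new = _coding_substitute(rng, r, i)
                if new != r[i]:
                    r[i] = new
                    truth.leader_positions.append(i)
    # body: shared single-allele events, one variant column per codon
    body_codons = np.arange(leader_bp // 3, length // 3)
    n_events = int(rng.binomial(body_codons.size * 3, body_rate))
    if n_events > body_codons.size:
        raise ValueError("body substitution rate too high for "
                         "one-variant-per-codon events")
    for ci in rng.choice(body_codons, size=n_events, replace=False):
        codon = ancestor[ci * 3:ci * 3 + 3]
        offsets = list(rng.permutation(3))
        alt = None
        for off in offsets:
            cands = []
            for b in BASES:
                if b == codon[off]:
                    continue
                altc = codon[:off] + b + codon[off + 1:]
                if altc in STOP_CODONS:
                    continue
                if body_nonsyn_only and CODON_AA[altc] == CODON_AA[codon]:
                    continue
                cands.append((off, b))
            if cands:
                alt = cands[int(rng.integers(len(cands)))]
                break
        if alt is None:
            continue
        off, b = alt
        col = int(ci) * 3 + int(off)
        k = int(rng.integers(1, n_rows))     # derived allele in k of n rows
        for ri in rng.choice(n_rows, size=k, replace=False):
            rows[ri][col] = b
        truth.body_positions.append(col)
    names = [f"row{i+1}" for i in range(n_rows)]
    return MultipleAlignment(names, ["".join(r) for r in rows]), truth


def generate_two_regime_alignment(n_rows: int, length: int, boundary: int,
                                  left_identity: float = 0.75,
                                  right_identity: float = 0.99,
                                  seed: int = 0
                                  ) -> tuple[MultipleAlignment, GroundTruth]:
    """Gapless alignment with two identity regimes meeting at ``boundary``.

    Each column carries an exact number k of deviant rows (distinct
    non-consensus bases), giving per-column pairwise identity
    C(n-k, 2)/C(n, 2); the per-regime mix of k-levels is chosen by largest
    remainder so the realized region mean equals the planted identity up
    to rounding.
    """
    if n_rows < 4:
        raise ValueError("need >= 4 rows")
    rng = np.random.default_rng(seed)
    nt = list("ACGT")

    def ident_of(k):
        m = n_rows - k
        return (m * (m - 1) / 2) / (n_rows * (n_rows - 1) / 2)

    levels = [ident_of(k) for k in range(4)]

    def regime_levels(n_cols, target):
        if not levels[-1] <= target <= 1.0:
            raise ValueError(f"identity {target} outside attainable range")
        hi = max(k for k in range(4) if levels[k] >= target)
        lo = min(hi + 1, 3)
        if levels[hi] == target or hi == lo:
            frac_lo = 0.0
        else:
            frac_lo = (levels[hi] - target) / (levels[hi] - levels[lo])
        n_lo = int(round(n_cols * frac_lo))
        ks = [lo] * n_lo + [hi] * (n_cols - n_lo)
        return [ks[i] for i in rng.permutation(n_cols)]

    ks = regime_levels(boundary, left_identity) + \
        regime_levels(length - boundary, right_identity)
    cols = np.empty((length, n_rows), dtype="U1")
    for j, k in enumerate(ks):
        base = nt[rng.integers(0, 4)]
        cols[j] = base
        if k:
            others = [b for b in nt if b != base]
            dev_bases = rng.choice(others, size=k, replace=False)
            dev_rows = rng.choice(n_rows, size=k, replace=False)
            cols[j, dev_rows] = dev_bases
    rows = ["".join(cols[:, i]) for i in range(n_rows)]
    truth = GroundTruth()
    truth.body_positions = [boundary]     # planted changepoint
    return MultipleAlignment([f"r{i+1}" for i in range(n_rows)], rows), truth


# ---------------------------------------------------------------------------
# strain-pair generator

DEFAULT_KIND_FRACTIONS = {"deletion": 0.39, "insertion": 0.28,
                          "transition": 0.28, "transversion": 0.04}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_strain_pair(genome_length: int = 20000, n_events: int = 192,
                         kind_fractions: dict[str, float] | None = None,
                         seed: int = 0, max_indel: int = 3
                         ) -> tuple[MultipleAlignment,
                                    list[FeatureAnnotation], GroundTruth]:
    """A reference genome and a derived strain with exactly the requested
    number of planted mutation events (largest-remainder kind counts),
    separated by >= 2 matching bp, over a CDS tiling.

    ``kind_fractions`` may sum to less than 1 (the observed spectrum's four
    headline categories cover 99%); any remainder is planted as mnp events
    (adjacent-substitution runs).
    """
    if kind_fractions is None:
        kind_fractions = DEFAULT_KIND_FRACTIONS
    total = sum(kind_fractions.values())
    if total > 1 + 1e-9:
        raise ValueError("kind fractions must sum to at most 1")
    kind_fractions = dict(kind_fractions)
    if total < 1 - 1e-9:
        kind_fractions["mnp"] = kind_fractions.get("mnp", 0.0) + (1 - total)
    rng = np.random.default_rng(seed)
    counts = _largest_remainder(kind_fractions, n_events)
    min_gap = 6 + max_indel
    if n_events * min_gap > genome_length - 200:
        raise ValueError("events too dense for the genome length")

    ref = list(_random_nt(rng, genome_length, 0.47))
    # positions spaced >= min_gap apart, away from the ends
    slots = np.arange(100, genome_length - 100 - max_indel, min_gap)
    pos = np.sort(rng.choice(slots, size=n_events, replace=False))
    kinds = [k for k, c in counts.items() for _ in range(c)]
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]

    truth = GroundTruth()
    ref_row, alt_row = [], []
    prev = 0
    for p, kind in zip(pos, kinds):
        p = int(p)
        ref_row.append("".join(ref[prev:p]))
        alt_row.append("".join(ref[prev:p]))
        if kind == "mnp":
            length = 2
            seg = [ref[p], ref[p + 1]]
            ref_row.append("".join(seg))
            alt_row.append("".join(_substitute(rng, b) for b in seg))
            prev = p + 2
        elif kind in ("transition", "transversion"):
            base = ref[p]
            if kind == "transition":
                alt = _TRANSITION[base]
            else:
                alt = rng.choice([b for b in BASES
                                  if b != base and b != _TRANSITION[base]])
            ref_row.append(base)
            alt_row.append(alt)
            length, prev = 1, p + 1
        elif kind == "deletion":
            length = int(rng.integers(1, max_indel + 1))
            ref_row.append("".join(ref[p:p + length]))
            alt_row.append("-" * length)
            prev = p + length
        else:  # insertion
            length = int(rng.integers(1, max_indel + 1))
            ins = _random_nt(rng, length, 0.47)
            ref_row.append("-" * length)
            alt_row.append(ins)
            prev = p
        truth.mutation_events.append((p, kind, length))
    ref_row.append("".join(ref[prev:]))
    alt_row.append("".join(ref[prev:]))
    pair = MultipleAlignment(["reference", "derived"],
                             ["".join(ref_row), "".join(alt_row)])
    # CDS tiling on ungapped reference coordinates: 999 nt genes, 51 nt gaps
    feats = []
    g = 0
    start = 30
    while start + 999 <= genome_length - 30:
        feats.append(FeatureAnnotation(f"cds{g:04d}", "CDS", start,
                                       start + 999, "+", "tiled gene"))
        start += 1050
        g += 1
    return pair, feats, truth


# ---------------------------------------------------------------------------
# clock trees and sequence evolution

def generate_clock_tree(n_taxa: int, height: float, seed: int = 0
                        ) -> tuple[PhyloTree, GroundTruth]:
    """Random ultrametric (clock-like) tree of the given root height:
    recursive random bipartition with node depths drawn uniformly."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i+1}" for i in range(n_taxa)]

    def build(labels, h):
        """Newick for a subtree whose root sits at height h above the tips."""
        if len(labels) == 1:
            return labels[0]
        k = int(rng.integers(1, len(labels)))
        parts = []
        for sub in (labels[:k], labels[k:]):
            if len(sub) == 1:
                parts.append(f"{sub[0]}:{h:.10f}")
            else:
                hc = h * rng.uniform(0.2, 0.8)
                parts.append(f"{build(sub, hc)}:{h - hc:.10f}")
        return f"({','.join(parts)})"

    newick = build(taxa, height) + ";"
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    dtree.is_rooted = True
    tree = PhyloTree(dtree)
    truth = GroundTruth(tree_newick=newick, tree_height=height)
    return tree, truth


def simulate_on_tree(tree: PhyloTree, seq_length: int, seed: int = 0
                     ) -> MultipleAlignment:
    """Evolve sequences along the tree under Jukes-Cantor: per edge of
    length t, each site substitutes with probability (3/4)(1 - e^(-4t/3))
    to a uniformly random different base."""
    rng = np.random.default_rng(seed)
    nt = np.array(list("ACGT"))
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs = {}
    t = tree.tree
    states = {id(t.seed_node): root_seq}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        parent = states[id(node.parent_node)]
        bl = node.edge.length or 0.0
        p = 0.75 * (1.0 - np.exp(-4.0 * bl / 3.0))
        child = parent.copy()
        hits = np.nonzero(rng.random(seq_length) < p)[0]
        if hits.size:
            child[hits] = (child[hits] + rng.integers(1, 4, size=hits.size)) % 4
        states[id(node)] = child
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(nt[child])
    names = sorted(seqs)
    return MultipleAlignment(names, [seqs[n] for n in names])
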