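"""Variant-column accounting and pairwise Nei-Gojobori (1986) Ka/Ks,
implemented from first principles under bacterial translation table 11.

Site counting: at each codon position the synonymous fraction is the share
of one-step changes that preserve the amino acid, with changes that create
a stop codon excluded from both numerator and denominator, so each position
contributes exactly one site (s + n = 3 per codon).

Difference counting: for each codon pair the minimal substitution pathways
(all orderings of the differing positions) are enumerated; pathways passing
through a stop codon are excluded and synonymous/nonsynonymous step counts
are averaged over the remaining pathways.  Proportions are corrected with
the one-parameter Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

_T11 = unambiguous_dna_by_id[11]
BASES = "ACGT"
STOP_CODONS = frozenset(_T11.stop_codons)
CODON_AA = dict(_T11.forward_table)
SENSE_CODONS = tuple(sorted(CODON_AA))
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class KaKsError(ValueError):
    pass


@dataclass(frozen=True)
class RegionMask:
    name: str
    intervals: tuple[tuple[int, int], ...]   # 0-based half-open, on the sequence
    frame_anchor: int = 0

    def __post_init__(self):
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"mask {self.name}: overlapping intervals")

    def extract(self, seq: str) -> str:
        return "".join(seq[s:e] for s, e in sorted(self.intervals))


@dataclass
class VariantColumnReport:
    n_variant: int
    positions: list[int]
    n_substitution: int
    n_indel: int


@dataclass
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    status: str = "ok"          # ok | undefined_0_over_0 | infinite_Ks_zero
    n_codons: int = 0


# ---------------------------------------------------------------------------
# variant columns

def variant_columns(msa) -> VariantColumnReport:
    """Per-column variant accounting over an alignment.

    A column is variant iff it carries >= 2 distinct states, with the gap
    counted as a state (N is treated as missing).  Substitution columns are
    variant columns with no gaps; indel columns involve a gap.  Adjacent
    gap columns of one indel event still count per column.
    """
    positions, n_sub, n_indel = [], 0, 0
    for j in range(msa.length):
        states = {r[j] for r in msa.rows if r[j] != "N"}
        if len(states) < 2:
            continue
        positions.append(j)
        if "-" in states:
            n_indel += 1
        else:
            n_sub += 1
    return VariantColumnReport(len(positions), positions, n_sub, n_indel)


# ---------------------------------------------------------------------------
# NG86 sites

def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise KaKsError(f"stop codon {codon}")
    if codon not in CODON_AA:
        raise KaKsError(f"ambiguous or invalid codon {codon!r}")
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_AA[alt] == aa
        if valid:
            s += syn / valid
    return s, 3.0 - s


# ---------------------------------------------------------------------------
# NG86 pathway-averaged differences

def codon_pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over all minimal substitution
    pathways that avoid stop codons (all pathways if every one is blocked)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff):
        cur = c1
        syn = non = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                syn_step = False
            else:
                syn_step = CODON_AA.get(cur) == CODON_AA.get(nxt)
            (syn, non) = (syn + 1, non) if syn_step else (syn, non + 1)
            cur = nxt
        (blocked if through_stop else results).append((syn, non))
    use = results or blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def jc69_correct(p: float) -> float:
    """Jukes-Cantor correction of a raw proportion of differences."""
    if p < 0:
        raise KaKsError("negative proportion")
    if p >= 0.75:
        raise KaKsError(f"proportion {p:.3f} >= 3/4: correction undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_pair(seq1: str, seq2: str, mask: RegionMask | None = None) -> KaKsResult:
    """Pairwise NG86 Ka/Ks over two aligned in-frame coding sequences.

    Codons containing a gap or ambiguous base in either sequence are
    skipped entirely (sites and differences).  ``mask`` restricts the
    calculation to its intervals (their concatenation must stay in frame).
    """
    if mask is not None:
        seq1, seq2 = mask.extract(seq1), mask.extract(seq2)
    if len(seq1) != len(seq2):
        raise KaKsError("sequences differ in length")
    if len(seq1) % 3:
        raise KaKsError(f"length {len(seq1)} not divisible by 3")
    S1 = S2 = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3].upper(), seq2[i:i + 3].upper()
        if not (set(c1) <= set(BASES) and set(c2) <= set(BASES)):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise KaKsError(f"internal stop codon at nt {i}")
        s1, _ = ng86_sites(c1)
        s2, _ = ng86_sites(c2)
        S1 += s1
        S2 += s2
        sd, nd = codon_pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise KaKsError("no comparable codons")
    S = (S1 + S2) / 2
    N = 3.0 * n_codons - S
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    res = KaKsResult(S, N, Sd, Nd, pS, pN, None, None, None,
                     n_codons=n_codons)
    res.Ks = jc69_correct(pS)
    res.Ka = jc69_correct(pN)
    if Sd == 0 and Nd == 0:
        res.status = "undefined_0_over_0"
    elif res.Ks == 0:
        res.status = "infinite_Ks_zero"
    else:
        res.ratio = res.Ka / res.Ks
    return res


# ---------------------------------------------------------------------------
# substitution classification

@dataclass(frozen=True)
class SubstitutionClass:
    change: str                  # transition | transversion
    effect: str | None = None    # synonymous | nonsynonymous | truncation


def classify_substitution(ref_base: str, alt_base: str,
                          ref_codon: str | None = None,
                          alt_codon: str | None = None) -> SubstitutionClass:
    """Classify a single-base substitution; codon context adds the coding
    effect under translation table 11."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError("identical bases are not a substitution")
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError("bases must be A/C/G/T")
    same_class = ({ref_base, alt_base} <= PURINES
                  or {ref_base, alt_base} <= PYRIMIDINES)
    change = "transition" if same_class else "transversion"
    effect = None
    if ref_codon is not None and alt_codon is not None:
        ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
        if ref_codon == alt_codon:
            raise ValueError("identical codons are not a substitution")
        if alt_codon in STOP_CODONS:
            effect = "truncation"
        elif CODON_AA.get(ref_codon) == CODON_AA.get(alt_codon):
            effect = "synonymous"
        else:
            effect = "nonsynonymous"
    return SubstitutionClass(change, effect)
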