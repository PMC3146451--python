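"""Attachment-site analysis: flank windows around repeat boundaries, the
majority-rule consensus, the degenerate att motif, and the insertion point
in ssrA coordinates.

Every boundary (the ssrA 3' end itself, or a downstream direct-repeat end)
contributes one fixed-width window to a gapless flank alignment.  The
default window is 84 columns split 34 upstream + 20 repeat + 30 downstream.
Comparing direct-repeat rows with ssrA rows column-by-column localizes the
insertion point: the repeat is the longest ssrA 3'-suffix whose columns all
agree between the two groups, and the first upstream column of conserved
disagreement marks the last ssrA base before the insertion.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .island_scanner import RepeatHit, TmRNALocus
from .seqio import GenomeRecord, MultipleAlignment

DEFAULT_WIDTH = 84
DEFAULT_UPSTREAM = 34
DEFAULT_REPEAT = 20

#: minimal IUPAC code for each base set
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class FlankSource:
    genome_id: str
    kind: str          # "ssrA" or "DR"
    label: str         # e.g. "VS_02"
    boundary_end: int  # 0-based end of the repeat (or of ssrA)


@dataclass
class FlankSet:
    windows: MultipleAlignment
    sources: list[FlankSource]
    upstream: int = DEFAULT_UPSTREAM
    repeat_length: int = DEFAULT_REPEAT

    @property
    def width(self) -> int:
        return self.windows.length

    def rows_of_kind(self, kind: str) -> list[str]:
        return [r for r, s in zip(self.windows.rows, self.sources)
                if s.kind == kind]


@dataclass
class ConsensusResult:
    consensus: str
    threshold: float
    disagreement_columns: list[int]
    per_row_disagreements: dict[str, list[int]] = field(default_factory=dict)

    def n_consensus_columns(self) -> int:
        return sum(1 for c in self.consensus if c != ".")


@dataclass
class AttMotif:
    motif: str
    length: int
    position: tuple[int, int]    # column interval immediately 5' of repeat


@dataclass
class InsertionSite:
    five_prime_pos: int                 # 1-based ssrA coord of last base pre-insertion
    repeat_span: tuple[int, int]        # 1-based inclusive ssrA coords
    diagnostic_column: int | None       # 1-based flank-alignment column
    degenerate: bool = False


# ---------------------------------------------------------------------------

def extract_flanks(entries: list[tuple[GenomeRecord, FlankSource]],
                   width: int = DEFAULT_WIDTH,
                   upstream: int = DEFAULT_UPSTREAM,
                   repeat_length: int = DEFAULT_REPEAT) -> FlankSet:
    """Cut one ``width``-column window per boundary: ``upstream`` columns
    before the repeat, the repeat itself, and the remaining columns
    downstream.  Windows falling off the contig are dropped with a warning.
    """
    downstream = width - upstream - repeat_length
    if downstream < 0:
        raise ValueError("width must cover upstream + repeat")
    names, rows, kept = [], [], []
    for genome, src in entries:
        start = src.boundary_end - repeat_length - upstream
        end = src.boundary_end + downstream
        if start < 0 or end > len(genome):
            warnings.warn(f"{src.label}: window off contig, row dropped")
            continue
        names.append(src.label)
        rows.append(genome.sequence[start:end])
        kept.append(src)
    if len(rows) < 2:
        raise ValueError("fewer than 2 flank windows extracted")
    return FlankSet(MultipleAlignment(names, rows), kept, upstream,
                    repeat_length)


def flank_sources_from_scan(genome: GenomeRecord, locus: TmRNALocus,
                            hits: list[RepeatHit]
                            ) -> list[tuple[GenomeRecord, FlankSource]]:
    """Boundary list for one genome: the ssrA 3' end plus every repeat end,
    labelled `<genome>_01, _02, ...` in downstream order."""
    entries = [(genome, FlankSource(genome.id, "ssrA", f"{genome.id}_01",
                                    locus.end))]
    for i, h in enumerate(hits, start=2):
        entries.append((genome, FlankSource(genome.id, "DR",
                                            f"{genome.id}_{i:02d}", h.end)))
    return entries


# ---------------------------------------------------------------------------

def _column_counts(rows: list[str], col: int) -> Counter:
    """Base counts at a column; gaps and N excluded from the denominator."""
    return Counter(r[col] for r in rows if r[col] in "ACGT")


def consensus(msa: MultipleAlignment | FlankSet,
              threshold: float = 0.75) -> ConsensusResult:
    """Majority-rule consensus: a column shows its modal base iff that
    base's frequency among non-gap, non-N rows is >= ``threshold``;
    sub-threshold (and all-gap) columns show '.'."""
    if isinstance(msa, FlankSet):
        msa = msa.windows
    cons = []
    for j in range(msa.length):
        counts = _column_counts(msa.rows, j)
        total = sum(counts.values())
        if total == 0:
            cons.append(".")
            continue
        base, n = counts.most_common(1)[0]
        cons.append(base if n / total >= threshold else ".")
    cons = "".join(cons)
    per_row: dict[str, list[int]] = {}
    disagree = set()
    for name, row in zip(msa.names, msa.rows):
        cols = [j for j in range(msa.length)
                if cons[j] != "." and row[j] in "ACGT" and row[j] != cons[j]]
        per_row[name] = cols
        disagree.update(cols)
    return ConsensusResult(cons, threshold, sorted(disagree), per_row)


def derive_att_motif(flanks: FlankSet, motif_length: int = 15,
                     inclusion_fraction: float = 0.10) -> AttMotif:
    """Degenerate motif over the ``motif_length`` columns immediately 5' of
    the repeat, from direct-repeat rows only: each column gets the minimal
    IUPAC code covering every base with frequency > ``inclusion_fraction``."""
    dr_rows = flanks.rows_of_kind("DR")
    if len(dr_rows) < 3:
        raise ValueError("need >= 3 direct-repeat rows for a motif")
    if flanks.upstream < motif_length:
        raise ValueError(
            f"only {flanks.upstream} columns 5' of the repeat available")
    lo, hi = flanks.upstream - motif_length, flanks.upstream
    motif = []
    for j in range(lo, hi):
        counts = _column_counts(dr_rows, j)
        total = sum(counts.values())
        if total == 0:
            motif.append("N")
            continue
        included = frozenset(b for b, n in counts.items()
                             if n / total > inclusion_fraction)
        motif.append(IUPAC[included])
    return AttMotif("".join(motif), motif_length, (lo, hi))


# ---------------------------------------------------------------------------

def _between_group_identity(a_rows: list[str], b_rows: list[str],
                            col: int) -> float | None:
    """Mean identity over all cross-group row pairs at one column; gap/N
    comparisons excluded.  None when no valid pair exists."""
    match = valid = 0
    for ra in a_rows:
        x = ra[col]
        if x not in "ACGT":
            continue
        for rb in b_rows:
            y = rb[col]
            if y not in "ACGT":
                continue
            valid += 1
            match += x == y
    return match / valid if valid else None


def infer_insertion_site(flanks: FlankSet, ssra_length: int,
                         identity_threshold: float = 0.9,
                         column_floor: float = 0.5,
                         consensus_threshold: float = 0.75) -> InsertionSite:
    """Locate the insertion point in the ssrA gene.

    The repeat span is the longest ssrA 3'-suffix over which the mean
    between-group (direct repeat vs ssrA) per-column identity stays >=
    ``identity_threshold``; extension also stops at the first column that
    disagrees outright (identity < ``column_floor``, i.e. a column that
    does not align well between the groups).  The last ssrA base before
    the insertion is ``ssra_length - span``.

    Also reports the attL-proximal conserved-disagreement column: the
    column nearest the repeat where both groups are internally conserved
    (modal frequency >= ``consensus_threshold``) yet their modal bases
    differ.
    """
    ssr = flanks.rows_of_kind("ssrA")
    dr = flanks.rows_of_kind("DR")
    if not ssr or not dr:
        raise ValueError("flank set must contain both ssrA and DR rows")
    repeat_end_col = flanks.upstream + flanks.repeat_length
    idents: list[float] = []
    for col in range(repeat_end_col - 1, -1, -1):
        ident = _between_group_identity(ssr, dr, col)
        if ident is None or ident < column_floor:
            break
        idents.append(ident)
    span = 0
    total = 0.0
    for k, ident in enumerate(idents, start=1):
        total += ident
        if total / k >= identity_threshold:
            span = k
    if span < 5:
        raise ValueError("no repeat structure: suffix agreement < 5 bp")
    degenerate = span == repeat_end_col
    five_prime = ssra_length - span
    diag = _diagnostic_column(ssr, dr, repeat_end_col - span,
                              consensus_threshold)
    return InsertionSite(five_prime, (five_prime + 1, ssra_length),
                         diag, degenerate)


def _diagnostic_column(ssr: list[str], dr: list[str], repeat_start_col: int,
                       threshold: float) -> int | None:
    for col in range(repeat_start_col - 1, -1, -1):
        modal = []
        for rows in (ssr, dr):
            counts = _column_counts(rows, col)
            total = sum(counts.values())
            if total == 0:
                modal.append(None)
                continue
            base, n = counts.most_common(1)[0]
            modal.append(base if n / total >= threshold else None)
        if modal[0] and modal[1] and modal[0] != modal[1]:
            return col + 1      # 1-based column in reports
    return None
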