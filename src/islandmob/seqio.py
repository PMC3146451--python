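"""Readers/writers for external formats and the shared primitive types.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open ``[start, end)``.  1-based
inclusive coordinates appear only in user-facing reports; :func:`to_report`
and :func:`from_report` convert between the two and are mutual inverses.

Genome alphabet is restricted to ``{A, C, G, T, N}``.  ``N`` is tolerated in
sequences (metagenome gap filler) but downstream statistics exclude it.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

VALID_NT = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "tmRNA", "tRNA", "other")


class ParseError(ValueError):
    """A file could not be parsed as the requested format."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


def to_report(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (for reports only)."""
    return start + 1, end


def from_report(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_id: str
    kind: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id}: need 0 <= start < end, "
                f"got ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.feature_id}: bad strand")

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValidationError(
                f"genome {self.id}: invalid characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"feature {f.feature_id} ({f.start},{f.end}) outside "
                    f"sequence of length {n}")
        self.features = sorted(self.features,
                               key=lambda f: (f.start, f.end, f.feature_id))

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        s = self.sequence[start:end]
        return revcomp(s) if strand == "-" else s

    def feature_seq(self, f: FeatureAnnotation) -> str:
        """Feature sequence in reading orientation."""
        return self.subseq(f.start, f.end, f.strand)

    def reverse_complement(self) -> "GenomeRecord":
        """Same genome on the opposite strand, features remapped."""
        n = len(self.sequence)
        feats = [replace(f, start=n - f.end, end=n - f.start,
                         strand="-" if f.strand == "+" else "+")
                 for f in self.features]
        feats.sort(key=lambda f: f.start)
        return GenomeRecord(self.id, revcomp(self.sequence), feats)


@dataclass
class MultipleAlignment:
    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValidationError("names/rows length mismatch")
        if len(self.rows) < 2:
            raise ValidationError("alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"ragged alignment rows: lengths {sorted(lengths)}")
        for name, r in zip(self.names, self.rows):
            bad = set(r) - VALID_NT - {"-"}
            if bad:
                raise ValidationError(f"row {name}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """(n_rows, length) uint8 matrix of ASCII codes."""
        return np.frombuffer("".join(self.rows).encode(), np.uint8).reshape(
            self.n_rows, self.length)

    def slice_columns(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(list(self.names), [r[start:end] for r in self.rows])


@dataclass
class PhyloTree:
    """Thin wrapper over a dendropy tree (leaf-labelled, branch lengths
    in expected substitutions per site)."""
    tree: dendropy.Tree

    def __post_init__(self):
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValidationError("duplicate leaf names")
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValidationError("negative branch length")

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# genome I/O

_GFF_KIND = {"CDS": "CDS", "tmRNA": "tmRNA", "tRNA": "tRNA"}


def _parse_gff3(path: str, genome_id: str) -> list[FeatureAnnotation]:
    import gffutils

    try:
        db = gffutils.create_db(path, dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: not parseable as GFF3: {exc}") from exc
    feats = []
    for i, f in enumerate(db.all_features()):
        kind = _GFF_KIND.get(f.featuretype, "other")
        fid = f.id or f"{genome_id}_f{i}"
        product = ";".join(f.attributes.get("product", []))
        strand = f.strand if f.strand in ("+", "-") else "+"
        # GFF3 is 1-based inclusive
        feats.append(FeatureAnnotation(fid, kind, f.start - 1, f.end, strand, product))
    feats.sort(key=lambda f: f.start)
    return feats


def _parse_feature_table(path: str) -> list[FeatureAnnotation]:
    """Simplified flat feature table: feature_id, kind, start, end, strand,
    product -- tab-separated, 1-based inclusive coordinates."""
    cols = ["feature_id", "kind", "start", "end", "strand", "product"]
    try:
        df = pd.read_csv(path, sep="\t", names=cols, comment="#", dtype=str,
                         keep_default_na=False)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except Exception as exc:
        raise ParseError(f"{path}: malformed feature table: {exc}") from exc
    feats = []
    for row in df.itertuples(index=False):
        s, e = from_report(row.start, row.end)
        feats.append(FeatureAnnotation(row.feature_id, row.kind, s, e,
                                       row.strand, row.product))
    feats.sort(key=lambda f: f.start)
    return feats


def read_genome(fasta_path: str, features_path: str | None = None,
                fmt: str = "fasta+gff3") -> GenomeRecord:
    """Read a genome (single-record FASTA) plus optional feature annotations.

    ``fmt`` selects the feature format: ``fasta+gff3`` or ``genbank-table``
    (the simplified tab-separated feature table).  Feature coordinates are
    normalized to 0-based half-open.
    """
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records found")
    if len(records) > 1:
        raise ParseError(f"{fasta_path}: expected a single record, "
                         f"found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    feats: list[FeatureAnnotation] = []
    if features_path is not None:
        if fmt == "fasta+gff3":
            feats = _parse_gff3(features_path, rec.id)
        elif fmt == "genbank-table":
            feats = _parse_feature_table(features_path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return GenomeRecord(rec.id, seq, feats)


def write_genome(genome: GenomeRecord, fasta_path: str,
                 gff3_path: str | None = None, line_width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), line_width):
            fh.write(genome.sequence[i:i + line_width] + "\n")
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
            for f in genome.features:
                first, last = to_report(f.start, f.end)
                ftype = f.kind if f.kind != "other" else "misc_feature"
                attrs = f"ID={f.feature_id}"
                if f.product:
                    attrs += f";product={f.product}"
                fh.write("\t".join([genome.id, "islandmob", ftype, str(first),
                                    str(last), ".", f.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# alignment I/O

def read_alignment(path: str) -> MultipleAlignment:
    """Read an aligned FASTA file; rows must be equal length."""
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) < 2:
        raise ParseError(f"{path}: alignment needs >= 2 sequences")
    return MultipleAlignment([r.id for r in records],
                             [str(r.seq).upper() for r in records])


def write_alignment(msa: MultipleAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# tree I/O

def read_tree(source: str) -> PhyloTree:
    """Read a Newick tree from a path (or a literal Newick string)."""
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=True)
    try:
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = True   # treat the seed node as the root
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | None = None) -> str:
    text = tree.tree.as_string(schema="newick", suppress_rooting=True,
                               unquoted_underscores=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
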