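"""Alignment / tree / partition-table I/O.

Alignment parsing is delegated to Bio.AlignIO (FASTA, NEXUS ``DATA`` block,
relaxed PHYLIP); this module adds the pipeline's validation and
normalization contract: bases upper-cased, ``U`` mapped to ``T``, only
nucleotide symbols, IUPAC ambiguity codes, ``-`` and ``?`` accepted.
Missing taxa are never gap-padded — a concatenation over loci with unequal
taxon sets is an error, because silent padding corrupts downstream
parsimony-informative-site counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import Tree, tree_from_newick

__all__ = [
    "Alignment",
    "Locus",
    "PartitionTable",
    "SeqIOError",
    "LOCUS_CLASSES",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "concatenate",
    "read_partition_table",
    "write_partition_table",
]

IUPAC = set("ACGT") | set("RYSWKMBDHVN") | {"-", "?"}
MISSING = {"-", "?", "N"}

#: states an ambiguity code stands for (used by the likelihood engine)
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}

LOCUS_CLASSES = ("nuclear_noncoding", "mt_protein", "mt_rRNA", "mt_tRNA", "mt_CR")

_FORMATS = {"fasta": "fasta", "phylip_relaxed": "phylip-relaxed", "nexus": "nexus"}


class SeqIOError(ValueError):
    """Raised on malformed sequence/tree/partition input."""


@dataclass(frozen=True)
class Alignment:
    """An aligned nucleotide matrix: ordered unique labels, equal-length rows."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise SeqIOError("labels and rows differ in count")
        if len(self.labels) < 2:
            raise SeqIOError("alignment needs at least 2 sequences")
        if len(set(self.labels)) != len(self.labels):
            dups = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise SeqIOError(f"duplicate labels: {dups}")
        length = len(self.rows[0])
        for label, row in zip(self.labels, self.rows):
            if len(row) != length:
                raise SeqIOError(
                    f"ragged alignment: record '{label}' has length "
                    f"{len(row)}, expected {length}"
                )
            bad = set(row) - IUPAC
            if bad:
                col = next(i for i, ch in enumerate(row) if ch in bad)
                raise SeqIOError(
                    f"unknown character {row[col]!r} in record '{label}' "
                    f"at column {col + 1}"
                )

    @staticmethod
    def from_pairs(pairs: Sequence[tuple[str, str]]) -> "Alignment":
        labels, rows = zip(*pairs) if pairs else ((), ())
        rows = tuple(r.upper().replace("U", "T") for r in rows)
        return Alignment(tuple(labels), rows)

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "Alignment":
        return Alignment(tuple(labels), tuple(self.row(l) for l in labels))

    def columns(self, idx: Sequence[int]) -> "Alignment":
        rows = tuple("".join(r[i] for i in idx) for r in self.rows)
        return Alignment(self.labels, rows)


@dataclass(frozen=True)
class Locus:
    """One named marker with its alignment and broad class."""

    name: str
    alignment: Alignment
    locus_class: str = "nuclear_noncoding"

    def __post_init__(self):
        if self.locus_class not in LOCUS_CLASSES:
            raise SeqIOError(
                f"unknown locus class {self.locus_class!r}; "
                f"expected one of {LOCUS_CLASSES}"
            )


@dataclass
class PartitionTable:
    """Ordered, contiguous, non-overlapping 1-based inclusive column ranges."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        expect = 1
        for name, start, end in self.entries:
            if start != expect or end < start:
                raise SeqIOError(
                    f"partition '{name}' range {start}-{end} breaks "
                    f"contiguous coverage (expected start {expect})"
                )
            expect = end + 1

    @property
    def n_cols(self) -> int:
        return self.entries[-1][2] if self.entries else 0


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

def _normalize(records) -> Alignment:
    pairs = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise SeqIOError(f"duplicate label: {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq)))
    if not pairs:
        raise SeqIOError("no sequences found")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) > 1:
        ref = len(pairs[0][1])
        offender = next(name for name, s in pairs if len(s) != ref)
        raise SeqIOError(
            f"unequal sequence lengths: record '{offender}' has "
            f"{len(dict(pairs)[offender])} columns, first record has {ref}"
        )
    return Alignment.from_pairs(pairs)


def read_alignment(path_or_handle, format: str = "fasta") -> Alignment:
    if format not in _FORMATS:
        raise SeqIOError(f"unknown alignment format {format!r}")
    try:
        if format == "fasta":
            # tolerate ragged input so we can report the offending record
            from Bio import SeqIO as _SeqIO

            records = list(_SeqIO.parse(path_or_handle, "fasta"))
            return _normalize(records)
        msa = AlignIO.read(path_or_handle, _FORMATS[format])
    except SeqIOError:
        raise
    except Exception as exc:
        raise SeqIOError(f"failed to parse {format}: {exc}") from None
    return _normalize(msa)


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    if format not in _FORMATS:
        raise SeqIOError(f"unknown alignment format {format!r}")
    records = [
        SeqRecord(Seq(row), id=label, description="")
        for label, row in zip(alignment.labels, alignment.rows)
    ]
    msa = MultipleSeqAlignment(records)
    if format == "nexus":
        for rec in msa:
            rec.annotations["molecule_type"] = "DNA"
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, _FORMATS[format])


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def read_tree(path_or_text) -> Tree:
    """Read a Newick tree from a path, handle, or literal string."""
    text = path_or_text
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    elif isinstance(path_or_text, (str, Path)) and os.path.exists(str(path_or_text)):
        text = Path(path_or_text).read_text()
    return tree_from_newick(str(text))


def write_tree(tree: Tree, path, include_support: bool = True) -> None:
    Path(path).write_text(
        tree.to_newick(include_support=include_support) + "\n"
    )


# --------------------------------------------------------------------------
# concatenation & partitions
# --------------------------------------------------------------------------

def concatenate(
    loci: Sequence[Locus], taxon_order: Optional[Sequence[str]] = None
) -> tuple[Alignment, PartitionTable]:
    """Append loci column-wise into one supermatrix plus its partition table.

    All loci must share one identical taxon set; the error message names the
    taxa missing from each offending locus.
    """
    if not loci:
        raise SeqIOError("no loci to concatenate")
    ref = set(loci[0].alignment.labels)
    problems = []
    for locus in loci:
        have = set(locus.alignment.labels)
        if have != ref:
            missing = sorted(ref - have)
            extra = sorted(have - ref)
            problems.append(f"{locus.name}: missing={missing} extra={extra}")
    if problems:
        raise SeqIOError("taxon sets differ across loci: " + "; ".join(problems))
    order = list(taxon_order) if taxon_order is not None else list(loci[0].alignment.labels)
    if set(order) != ref:
        raise SeqIOError("taxon_order does not match the loci's taxon set")
    rows = {t: [] for t in order}
    entries = []
    pos = 1
    for locus in loci:
        aln = locus.alignment
        for t in order:
            rows[t].append(aln.row(t))
        entries.append((locus.name, pos, pos + aln.n_cols - 1))
        pos += aln.n_cols
    combined = Alignment(tuple(order), tuple("".join(rows[t]) for t in order))
    return combined, PartitionTable(entries)


def write_partition_table(table: PartitionTable, path) -> None:
    with open(path, "w") as fh:
        for name, start, end in table.entries:
            fh.write(f"DNA, {name} = {start}-{end}\n")


def read_partition_table(path) -> PartitionTable:
    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            head, rng = line.split("=")
            _, name = head.split(",", 1)
            start, end = rng.strip().split("-")
            entries.append((name.strip(), int(start), int(end)))
        except ValueError:
            raise SeqIOError(f"bad partition line {lineno}: {line!r}") from None
    return PartitionTable(entries)
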