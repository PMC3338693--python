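"""Per-locus sequence characterization.

Reproduces the standard marker-description statistics for each alignment:
aligned length, variable and parsimony-informative (PI) site counts, and
mean pairwise distance (uncorrected p or Kimura two-parameter), plus a
coding-integrity screen used to flag nuclear copies of mitochondrial genes
(numts) by premature stop codons / frame-breaking lengths.

Conventions (documented because source descriptions of such tables rarely
state them): distances use pairwise deletion — for each pair, any site where
either member carries a gap or ambiguity code is excluded; PI counting
ignores ambiguity codes entirely, so a partially ambiguous observation never
counts toward the two-copies rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from Bio.Data import CodonTable

from .seqio import Alignment, Locus

__all__ = [
    "CharacterizationRow",
    "count_parsimony_informative",
    "count_variable",
    "pairwise_distance_matrix",
    "characterize_locus",
    "coding_integrity_check",
    "CodingIntegrityReport",
]

_UNAMBIG = "ACGT"
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class CharacterizationRow:
    """One row of the per-locus characterization table."""

    locus: str
    aligned_length: int
    pi_sites: int
    variable_sites: int
    mean_pairwise_distance: float
    model_id: Optional[str] = None
    p_inv: Optional[float] = None
    alpha: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.pi_sites <= self.variable_sites <= self.aligned_length):
            raise ValueError(
                "PI <= variable <= length violated: "
                f"{self.pi_sites}/{self.variable_sites}/{self.aligned_length}"
            )
        if not (0.0 <= self.mean_pairwise_distance <= 1.0):
            raise ValueError("mean pairwise distance outside [0, 1]")


def _state_counts(alignment: Alignment) -> np.ndarray:
    """(4, n_cols) counts of unambiguous A/C/G/T per column."""
    mat = np.frombuffer(
        "".join(alignment.rows).encode(), dtype="S1"
    ).reshape(alignment.n_taxa, alignment.n_cols)
    counts = np.empty((4, alignment.n_cols), dtype=np.int64)
    for i, base in enumerate(_UNAMBIG):
        counts[i] = (mat == base.encode()).sum(axis=0)
    return counts


def count_variable(alignment: Alignment) -> int:
    """Columns with >=2 distinct unambiguous states present."""
    counts = _state_counts(alignment)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def count_parsimony_informative(alignment: Alignment) -> int:
    """Columns with >=2 distinct unambiguous states each in >=2 rows."""
    counts = _state_counts(alignment)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def pairwise_distance_matrix(
    alignment: Alignment, metric: str = "p_distance"
) -> np.ndarray:
    """Symmetric distance matrix under pairwise deletion.

    ``p_distance`` is the mismatch fraction; ``k2p`` applies the Kimura
    two-parameter correction from transition/transversion fractions.
    """
    if metric not in ("p_distance", "k2p"):
        raise ValueError(f"unknown metric {metric!r}")
    n = alignment.n_taxa
    mat = np.frombuffer(
        "".join(alignment.rows).encode(), dtype="S1"
    ).reshape(n, alignment.n_cols)
    good = np.isin(mat, [b"A", b"C", b"G", b"T"])
    purine = np.isin(mat, [b"A", b"G"])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = good[i] & good[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites for pair "
                    f"({alignment.labels[i]!r}, {alignment.labels[j]!r})"
                )
            diff = both & (mat[i] != mat[j])
            if metric == "p_distance":
                d = diff.sum() / m
            else:
                transition = diff & (purine[i] == purine[j])
                p = transition.sum() / m
                q = (diff.sum() - transition.sum()) / m
                arg1 = 1.0 - 2.0 * p - q
                arg2 = 1.0 - 2.0 * q
                if arg1 <= 0 or arg2 <= 0:
                    raise ValueError(
                        "K2P undefined (saturated) for pair "
                        f"({alignment.labels[i]!r}, {alignment.labels[j]!r})"
                    )
                d = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
            dist[i, j] = dist[j, i] = d
    return dist


def mean_pairwise_distance(alignment: Alignment, metric: str = "p_distance") -> float:
    d = pairwise_distance_matrix(alignment, metric)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def characterize_locus(
    locus: Locus,
    metric: str = "p_distance",
    model_id: Optional[str] = None,
    p_inv: Optional[float] = None,
    alpha: Optional[float] = None,
) -> CharacterizationRow:
    aln = locus.alignment
    return CharacterizationRow(
        locus=locus.name,
        aligned_length=aln.n_cols,
        pi_sites=count_parsimony_informative(aln),
        variable_sites=count_variable(aln),
        mean_pairwise_distance=mean_pairwise_distance(aln, metric),
        model_id=model_id,
        p_inv=p_inv,
        alpha=alpha,
    )


@dataclass(frozen=True)
class CodingIntegrityReport:
    clean: bool
    internal_stops: tuple[int, ...]  # 1-based codon indices
    length_multiple_of_three: bool
    terminal_stop: bool


_CODE_IDS = {"vertebrate_mt": 2, "standard": 1}


def coding_integrity_check(
    sequence: str, genetic_code: str = "vertebrate_mt", reading_frame: int = 1
) -> CodingIntegrityReport:
    """Screen a putative protein-coding sequence for numt-like defects.

    Flags internal stop codons and an ungapped length that is not a multiple
    of three (a frameshifting indel signature). ``clean`` is true iff
    neither occurs before the final codon.
    """
    if genetic_code not in _CODE_IDS:
        raise ValueError(f"unknown genetic code {genetic_code!r}")
    if reading_frame not in (1, 2, 3):
        raise ValueError(f"reading frame must be 1, 2 or 3, got {reading_frame!r}")
    table = CodonTable.unambiguous_dna_by_id[_CODE_IDS[genetic_code]]
    stops = set(table.stop_codons)
    seq = "".join(ch for ch in sequence.upper().replace("U", "T") if ch not in "-?")
    seq = seq[reading_frame - 1 :]
    if len(seq) < 3:
        raise ValueError("fewer than 3 ungapped bases in frame")
    n_codons = len(seq) // 3
    internal = []
    terminal_stop = False
    for k in range(n_codons):
        codon = seq[3 * k : 3 * k + 3]
        if codon in stops:
            if k == n_codons - 1:
                terminal_stop = True
            else:
                internal.append(k + 1)
    mult3 = len(seq) % 3 == 0
    return CodingIntegrityReport(
        clean=not internal and mult3,
        internal_stops=tuple(internal),
        length_multiple_of_three=mult3,
        terminal_stop=terminal_stop,
    )
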