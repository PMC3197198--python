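"""Scaffoldin motif analysis: translation, dockerin repeats, conservation.

Dockerin modules are ~70-residue protein modules built around a duplicated
~22-amino-acid repeat.  This module translates trimmed ORFs, detects the
duplicated repeat by scanning all pairs of 22-residue windows whose
start-to-start spacing keeps both repeats inside roughly 70 residues and
scoring each pair with a substitution matrix (BLOSUM62), and profiles
per-column conservation of a supplied multiple alignment to quantify the
conserved-cohesin / variable-second-repeat contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from scatyper.errors import InvalidParameterError, ScatyperError

REPEAT_LENGTH = 22
#: Start-to-start spacing window keeping both repeats within a ~70-aa module.
DEFAULT_SPACING = (22, 48)
#: Default acceptance score: roughly the BLOSUM62 score of a 22-mer pair with
#: ~40% identical positions (9 x ~5 on the diagonal, 13 x ~ -1 off it).
DEFAULT_SCORE_THRESHOLD = 30.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TranslationError(ScatyperError, ValueError):
    """Internal stop codon; ``codon_index`` is 0-based."""

    def __init__(self, message: str, codon_index: int):
        super().__init__(message)
        self.codon_index = codon_index


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str  # 20-letter alphabet plus X; no internal stops
    source_id: str | None = None
    frame: int = 0


@dataclass(frozen=True)
class DockerinHit:
    """A detected duplicated 22-residue repeat pair (0-based half-open)."""

    repeat1: tuple[int, int]
    repeat2: tuple[int, int]
    spacing: int  # start-to-start distance
    score: float
    passed: bool


@dataclass(frozen=True)
class TooShort:
    """Protein too short to host two spaced 22-mers."""

    id: str
    length: int


def translate_orf(record) -> ProteinRecord:
    """Translate a trimmed ORF with the standard genetic code.

    Codons containing ambiguity (N) translate to X.  A trailing stop codon is
    dropped; an internal stop raises :class:`TranslationError` naming the
    0-based codon index.
    """
    seq = record.sequence.upper()
    if len(seq) % 3 != 0:
        raise InvalidParameterError(
            f"{record.id}: length {len(seq)} not divisible by 3"
        )
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise TranslationError(
            f"{record.id}: internal stop at codon {aa.index('*')}", aa.index("*")
        )
    return ProteinRecord(
        id=record.id, sequence=aa, source_id=record.id, frame=0
    )


def _window_score(a: str, b: str, matrix) -> float:
    score = 0.0
    for x, y in zip(a, b):
        try:
            score += matrix[x, y]
        except (KeyError, IndexError):
            score += 0.0  # X or other non-standard residue: neutral
    return score


def find_dockerin_repeats(
    protein: ProteinRecord,
    spacing: tuple[int, int] = DEFAULT_SPACING,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    matrix=None,
) -> DockerinHit | TooShort | None:
    """Detect the duplicated 22-aa dockerin repeat in a protein.

    Scans every pair of 22-residue windows whose start-to-start spacing lies
    in ``spacing`` (inclusive), scores each pair by summed substitution-matrix
    similarity, and returns the best-scoring pair if it reaches
    ``score_threshold``; returns None when no pair qualifies and a
    :class:`TooShort` marker when the protein cannot host two spaced repeats.
    """
    lo, hi = spacing
    if lo < REPEAT_LENGTH:
        raise InvalidParameterError(
            f"minimum spacing must be >= {REPEAT_LENGTH} (repeats must not overlap)"
        )
    matrix = matrix if matrix is not None else _BLOSUM62
    seq = protein.sequence
    if len(seq) < REPEAT_LENGTH + lo:
        return TooShort(id=protein.id, length=len(seq))

    best: DockerinHit | None = None
    for start1 in range(0, len(seq) - REPEAT_LENGTH - lo + 1):
        w1 = seq[start1 : start1 + REPEAT_LENGTH]
        for gap in range(lo, hi + 1):
            start2 = start1 + gap
            if start2 + REPEAT_LENGTH > len(seq):
                break
            w2 = seq[start2 : start2 + REPEAT_LENGTH]
            score = _window_score(w1, w2, matrix)
            if best is None or score > best.score:
                best = DockerinHit(
                    repeat1=(start1, start1 + REPEAT_LENGTH),
                    repeat2=(start2, start2 + REPEAT_LENGTH),
                    spacing=gap,
                    score=score,
                    passed=score >= score_threshold,
                )
    if best is not None and best.passed:
        return best
    return None


def conservation_profile(alignment: list[str]) -> np.ndarray:
    """Per-column conservation of an aligned set of protein sequences.

    Conservation = frequency of the modal non-gap residue among non-gap rows;
    all-gap columns are NaN.  Rows must have equal length.
    """
    if not alignment:
        raise InvalidParameterError("empty alignment")
    lengths = {len(row) for row in alignment}
    if len(lengths) != 1:
        raise InvalidParameterError(f"ragged alignment (lengths {sorted(lengths)})")
    n_cols = lengths.pop()
    profile = np.empty(n_cols)
    for j in range(n_cols):
        residues = [row[j] for row in alignment if row[j] not in "-."]
        if not residues:
            profile[j] = np.nan
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        profile[j] = max(counts.values()) / len(residues)
    return profile


def region_conservation_contrast(
    profile: np.ndarray, regions: dict[str, tuple[int, int]]
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Mean conservation per labeled region and all pairwise differences.

    Regions are 0-based half-open column intervals; NaN (all-gap) columns are
    ignored in the means.
    """
    means = {}
    for name, (lo, hi) in regions.items():
        if not (0 <= lo < hi <= len(profile)):
            raise InvalidParameterError(f"region {name!r} outside the profile")
        values = profile[lo:hi]
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise InvalidParameterError(f"region {name!r} has no defined columns")
        means[name] = float(values.mean())
    names = list(regions)
    diffs = {
        (a, b): means[a] - means[b]
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return means, diffs
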