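"""Greedy percent-identity clustering of scaC clone libraries.

Clone sequences are trimmed to their open reading frames, compared by global
pairwise alignment identity, and binned greedily: records are processed in
input order and each joins the first existing bin whose *founder* it matches
at or above the identity threshold, else founds a new bin (named after its
founder clone id).  Sweeping the threshold from 99% down to 40% and attaching
richness/diversity estimates to the resulting bin-size distributions yields
the strain-typing summary; scaC-types observed in every animal are the
"universal" types.

Identity is computed on nucleotides by default (an amino-acid mode is
available), from a global alignment with affine gap penalties; alignment
columns inside leading/trailing gap runs are excluded from the identity,
since trimmed clones have ragged ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from scatyper.errors import ConsistencyError, InvalidParameterError

_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_THRESHOLDS = (99.0, 90.0, 80.0, 70.0, 60.0, 50.0, 40.0)


@dataclass(frozen=True)
class SeqRecord:
    """A clone sequence; ``sample_id`` links it to the sampling design."""

    id: str
    sequence: str
    sample_id: str | None = None


@dataclass(frozen=True)
class Rejection:
    """A record that failed ORF trimming, with the reason."""

    id: str
    reason: str


def read_fasta(path) -> list[SeqRecord]:
    """Read clones from FASTA; sample ids are parsed from ``<sample>_c###``-style
    ids when present (text before the last ``_c`` serial)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        sid = rec.id.rsplit("_c", 1)[0] if "_c" in rec.id else None
        records.append(SeqRecord(id=rec.id, sequence=seq, sample_id=sid))
    return records


def trim_to_orf(
    record: SeqRecord,
    min_length: int = 60,
    start_codons: tuple[str, ...] = ("ATG",),
    frames: tuple[int, ...] = (0, 1, 2),
) -> SeqRecord | Rejection:
    """Trim a clone to its longest open reading frame.

    Scans the requested forward frames for the longest span running from a
    start codon through the codon preceding a stop (or the in-frame sequence
    end).  Records yielding no ORF of at least ``min_length`` nt are returned
    as :class:`Rejection` rather than raising.  Idempotent on already-trimmed
    ORFs.
    """
    seq = record.sequence.upper()
    best: tuple[int, int] | None = None  # (start, end) nt coordinates
    for frame in frames:
        i = frame
        open_start = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if open_start is None and codon in start_codons:
                open_start = i
            elif open_start is not None and codon in _STOPS:
                if best is None or i - open_start > best[1] - best[0]:
                    best = (open_start, i)
                open_start = None
            i += 3
        if open_start is not None:
            end = open_start + 3 * ((len(seq) - open_start) // 3)
            if best is None or end - open_start > best[1] - best[0]:
                best = (open_start, end)
    if best is None:
        return Rejection(record.id, "no open reading frame found")
    if best[1] - best[0] < min_length:
        return Rejection(
            record.id,
            f"longest ORF ({best[1] - best[0]} nt) below minimum {min_length} nt",
        )
    return SeqRecord(
        id=record.id, sequence=seq[best[0] : best[1]], sample_id=record.sample_id
    )


def _make_aligner(protein: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if protein:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    # end-gap runs extend cheaply (but still open at full cost) so that a
    # shorter sequence aligns as one contiguous overhang instead of one of
    # many co-optimal alignments with scattered internal gaps
    aligner.extend_left_gap_score = -0.5
    aligner.extend_right_gap_score = -0.5
    return aligner


_NT_ALIGNER = _make_aligner(protein=False)
_AA_ALIGNER = _make_aligner(protein=True)


def pairwise_identity(a: str, b: str, protein: bool = False) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Identity = matching columns / alignment columns, excluding columns that
    belong to leading or trailing gap runs in either sequence (end-gap
    exclusion, since trimmed clones have ragged ends).  Scoring: match +1 /
    mismatch -1 (BLOSUM62 in protein mode), gap open -5, gap extend -2.
    Symmetric in its arguments.
    """
    if not a or not b:
        raise InvalidParameterError("empty sequence")
    if a == b:
        return 1.0
    aligner = _AA_ALIGNER if protein else _NT_ALIGNER
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # exclude end-gap runs: keep columns between the last of the two starts
    # and the first of the two ends of the ungapped cores
    start = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    end = min(len(ga.rstrip("-")), len(gb.rstrip("-")))
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(ga[start:end], gb[start:end]) if x == y and x != "-")
    return matches / (end - start)


class IdentityCache:
    """Memoized symmetric pairwise identities keyed by record id."""

    def __init__(self, protein: bool = False):
        self._cache: dict[tuple[str, str], float] = {}
        self.protein = protein

    def identity(self, a: SeqRecord, b: SeqRecord) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        value = self._cache.get(key)
        if value is None:
            value = pairwise_identity(a.sequence, b.sequence, protein=self.protein)
            self._cache[key] = value
        return value


@dataclass
class Bin:
    name: str  # the founder's clone id
    founder: SeqRecord
    member_ids: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSet:
    threshold: float  # percent identity
    bins: list  # ordered by creation

    @property
    def s_obs(self) -> int:
        return len(self.bins)

    @property
    def sizes(self) -> list[int]:
        return [b.size for b in self.bins]

    def membership(self) -> dict[str, str]:
        return {m: b.name for b in self.bins for m in b.member_ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"bin": b.name, "founder": b.founder.id, "member": m,
                 "threshold": self.threshold}
                for b in self.bins
                for m in b.member_ids
            ]
        )


def greedy_cluster(
    records: list[SeqRecord],
    threshold: float,
    protein: bool = False,
    cache: IdentityCache | None = None,
) -> ClusterSet:
    """FastGroup-style greedy binning at one percent-identity threshold.

    Records are processed in input order; each is compared against the bin
    founders in bin-creation order and joins the *first* bin whose founder
    identity (x100) is >= ``threshold``, else founds a new bin named by its
    own id.  Deterministic for a fixed input order.
    """
    if not 0.0 < threshold <= 100.0:
        raise InvalidParameterError("threshold must be in (0, 100]")
    cache = cache or IdentityCache(protein=protein)
    bins: list[Bin] = []
    for rec in records:
        for b in bins:
            if 100.0 * cache.identity(rec, b.founder) >= threshold:
                b.member_ids.append(rec.id)
                break
        else:
            bins.append(Bin(name=rec.id, founder=rec, member_ids=[rec.id]))
    return ClusterSet(threshold=threshold, bins=bins)


def threshold_sweep(
    records: list[SeqRecord],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    protein: bool = False,
) -> tuple[pd.DataFrame, dict[float, ClusterSet]]:
    """Cluster at every threshold (shared identity cache) and attach
    richness/diversity estimates per threshold.

    Returns the summary table (threshold, n_sequences, S_obs, classic and
    bias-corrected Chao1, Shannon) and the per-threshold ClusterSets.
    """
    from scatyper import diversity

    if not records:
        raise InvalidParameterError("no records to cluster")
    cache = IdentityCache(protein=protein)
    rows = []
    clusters = {}
    for t in thresholds:
        cs = greedy_cluster(records, t, protein=protein, cache=cache)
        clusters[t] = cs
        v = diversity.AbundanceVector(cs.sizes)
        rows.append(
            {
                "threshold": t,
                "n_sequences": len(records),
                "s_obs": cs.s_obs,
                "chao1": diversity.chao1(v),
                "chao1_bias_corrected": diversity.chao1(v, bias_corrected=True),
                "shannon": diversity.shannon(v),
            }
        )
    return pd.DataFrame(rows), clusters


@dataclass
class UniversalTypeSummary:
    counts_by_animal: pd.DataFrame  # types x animals, clone counts
    universal: list  # type names observed in every animal
    universal_share_by_animal: pd.Series  # fraction of each animal's clones
    counts_by_factor: dict  # factor name -> types x levels count table


def universal_types(
    clusters: ClusterSet, clone_meta: pd.DataFrame
) -> UniversalTypeSummary:
    """Summarize type occurrence across animals and the other design factors.

    ``clone_meta`` is indexed by clone id with columns ``animal``, ``week``,
    ``hour`` and ``fraction``.  A type is *universal* iff it is observed in
    every animal present in the metadata.
    """
    membership = clusters.membership()
    unmapped = [m for m in membership if m not in clone_meta.index]
    if unmapped:
        raise ConsistencyError(f"clones without metadata: {unmapped[:10]}")

    df = clone_meta.loc[list(membership)].copy()
    df["type"] = [membership[m] for m in df.index]

    by_animal = (
        df.groupby(["type", "animal"]).size().unstack(fill_value=0)
    )
    # keep bin-creation order for rows
    order = [b.name for b in clusters.bins if b.name in by_animal.index]
    by_animal = by_animal.loc[order]

    universal = [t for t in by_animal.index if (by_animal.loc[t] > 0).all()]
    totals = by_animal.sum(axis=0)
    universal_share = by_animal.loc[universal].sum(axis=0) / totals

    counts_by_factor = {
        factor: df.groupby(["type", factor]).size().unstack(fill_value=0).loc[order]
        for factor in ("week", "hour", "fraction")
        if factor in df.columns
    }
    return UniversalTypeSummary(
        counts_by_animal=by_animal,
        universal=universal,
        universal_share_by_animal=universal_share,
        counts_by_factor=counts_by_factor,
    )
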