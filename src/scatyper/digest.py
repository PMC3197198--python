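"""In-silico PCR and restriction digestion for T-RFLP.

Terminal restriction fragment length polymorphism (T-RFLP) sizes only the
fluorescently labeled terminal fragment of a digested amplicon, so community
profiles can be interpreted by digesting reference sequences *in silico*:
find the amplicon delimited by the (degenerate) primer pair, locate every
restriction site, and measure the distance from each labeled 5' end to the
first cut.  A phylogenetic-assignment step then matches observed fragment
sizes against the predicted terminal restriction fragments (TRFs) of a
reference library, requiring consensus across all enzymes used.

Coordinates are 0-based and half-open throughout; TRF lengths are measured
from the labeled 5' base and include the primer, matching how capillary size
calls include the labeled primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scatyper.errors import FormatError, InvalidParameterError, NoAmpliconError

# IUPAC nucleotide ambiguity codes -> the set of unambiguous bases matched.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC codes supported)."""
    try:
        return sequence.upper().translate(_COMPLEMENT)[::-1]
    except KeyError:  # pragma: no cover - translate never raises
        raise FormatError(f"invalid nucleotide in {sequence!r}")


@dataclass(frozen=True)
class Primer:
    """A PCR primer; ``label`` is the attached fluorophore (dye) or None."""

    name: str
    sequence: str
    label: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"primer {self.name}: empty sequence")
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise FormatError(
                f"primer {self.name}: invalid IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with its recognition site and top-strand cut offset."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise InvalidParameterError(
                f"{self.name}: cut_offset {self.cut_offset} outside site"
            )


#: Built-in enzymes (REBASE sites; ^ marks the cut encoded by cut_offset).
ENZYMES = {
    "AluI": Enzyme("AluI", "AGCT", 2),  # AG^CT
    "HhaI": Enzyme("HhaI", "GCGC", 3),  # GCG^C
    "MspI": Enzyme("MspI", "CCGG", 1),  # C^CGG
    "HaeIII": Enzyme("HaeIII", "GGCC", 2),  # GG^CC
    "RsaI": Enzyme("RsaI", "GTAC", 2),  # GT^AC
}

#: Built-in primer pairs per marker; NED labels the forward primer, 6FAM the
#: reverse, so each dye channel reads out one amplicon end.
PRIMERS = {
    "16S": (
        Primer("8F", "AGAGTTTGATCCTGGCTCAG", "NED"),
        Primer("926R", "CCGTCAATTCCTTTRAGTTT", "6FAM"),
    ),
    "scaC": (
        Primer("ScaFwd", "AGACARGRTATAATHAAAGGGGC", "NED"),
        Primer("ScaRev", "GGGTTTKTATTCCTTTGTAAG", "6FAM"),
    ),
}

#: Enzyme panels used for each marker.
ENZYME_PANELS = {
    "16S": ("AluI", "HhaI", "MspI"),
    "scaC": ("AluI", "HaeIII", "MspI", "RsaI"),
}


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited amplicon with labeled-end annotation.

    ``sequence`` runs 5'->3' from the first base of the forward primer to the
    last base of the reverse-primer binding site.  ``multiple`` is set when
    more than one candidate amplicon existed (the shortest is returned).
    """

    sequence: str
    forward_label: str | None = None
    reverse_label: str | None = None
    multiple: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrfPrediction:
    """Predicted labeled-end fragment lengths for one amplicon/enzyme."""

    reference_id: str
    enzyme: str
    forward_trf: int
    reverse_trf: int
    forward_uncut: bool = False
    reverse_uncut: bool = False


def _compatible(primer_base: str, template_base: str) -> bool:
    # One-directional degeneracy: primer codes expand, template N matches all.
    try:
        pset = IUPAC[primer_base]
        tset = IUPAC[template_base]
    except KeyError as exc:
        raise FormatError(f"invalid IUPAC character {exc.args[0]!r}")
    return bool(pset & tset)


def match_degenerate_primer(
    sequence: str, primer: Primer, max_mismatches: int = 0
) -> list[int]:
    """Positions (0-based) where ``primer`` matches the given strand.

    A primer base matches a template base when their IUPAC sets intersect;
    at most ``max_mismatches`` incompatible positions are tolerated.  Only
    the given strand is scanned — the caller reverse-complements for the
    opposite orientation.
    """
    if max_mismatches < 0:
        raise InvalidParameterError("max_mismatches must be >= 0")
    seq = sequence.upper()
    p = primer.sequence
    hits = []
    for start in range(len(seq) - len(p) + 1):
        mismatches = 0
        for i, pb in enumerate(p):
            if not _compatible(pb, seq[start + i]):
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            hits.append(start)
    return hits


def extract_amplicon(
    sequence: str,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 0,
) -> Amplicon:
    """Extract the (shortest) amplicon delimited by a primer pair.

    The reverse primer is matched as its reverse complement on the given
    strand; the amplicon spans from the 5' end of the forward match to the
    3' end of the reverse-primer site.

    Raises
    ------
    NoAmpliconError
        If either primer has no match; ``.primer`` names the failing end.
    """
    seq = sequence.upper()
    fwd_hits = match_degenerate_primer(seq, fwd, max_mismatches)
    if not fwd_hits:
        raise NoAmpliconError(f"no match for forward primer {fwd.name}", fwd.name)
    rev_rc = Primer(rev.name, reverse_complement(rev.sequence))
    rev_hits = match_degenerate_primer(seq, rev_rc, max_mismatches)
    if not rev_hits:
        raise NoAmpliconError(f"no match for reverse primer {rev.name}", rev.name)

    candidates = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + len(rev.sequence)
            if end - f >= len(fwd.sequence) + len(rev.sequence):
                candidates.append((end - f, f, end))
    if not candidates:
        raise NoAmpliconError(
            f"primers {fwd.name}/{rev.name} do not face each other", rev.name
        )
    length, f, end = min(candidates)
    return Amplicon(
        sequence=seq[f:end],
        forward_label=fwd.label,
        reverse_label=rev.label,
        multiple=len(candidates) > 1,
    )


def cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """Sorted 0-based between-base cut coordinates of ``enzyme`` on ``sequence``.

    Every (possibly overlapping) occurrence of the recognition site yields one
    cut at ``site_start + cut_offset``.  All built-in sites are palindromic,
    so scanning the top strand covers both.
    """
    seq = sequence.upper()
    site = enzyme.recognition_site
    cuts = []
    start = seq.find(site)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = seq.find(site, start + 1)
    return cuts


def predict_trf(amplicon: Amplicon, enzyme: Enzyme, reference_id: str = "") -> TrfPrediction:
    """Predict both labeled-end TRFs of an amplicon for one enzyme.

    The forward TRF is the distance from the labeled 5' base of the forward
    primer to the first cut; the reverse TRF likewise on the
    reverse-complemented amplicon.  An end with no cut reports the full
    amplicon length and is flagged uncut rather than dropped.
    """
    if len(amplicon) == 0:
        raise InvalidParameterError("empty amplicon")
    n = len(amplicon)
    fwd_cuts = cut_positions(amplicon.sequence, enzyme)
    rev_cuts = cut_positions(reverse_complement(amplicon.sequence), enzyme)
    forward_trf = min(fwd_cuts) if fwd_cuts else n
    reverse_trf = min(rev_cuts) if rev_cuts else n
    return TrfPrediction(
        reference_id=reference_id,
        enzyme=enzyme.name,
        forward_trf=forward_trf,
        reverse_trf=reverse_trf,
        forward_uncut=not fwd_cuts,
        reverse_uncut=not rev_cuts,
    )


@dataclass
class AssignmentResult:
    """Outcome of fragment-to-taxon matching for one sample profile."""

    fragment_taxa: dict  # (enzyme, dye, size) -> frozenset of taxa (may be empty)
    consensus_taxa: frozenset  # taxa matched in every enzyme used
    matched_fraction: float  # fraction of fragments matching >= 1 reference
    tolerance_bp: float = 1.0
    per_enzyme_taxa: dict = field(default_factory=dict)


def assign_fragments(
    observed: list[tuple[str, str, float]],
    library: dict[str, list[TrfPrediction]],
    tolerance_bp: float = 1.0,
    forward_dyes: tuple[str, ...] = ("NED",),
) -> AssignmentResult:
    """Match observed fragments to a predicted-TRF reference library.

    ``observed`` is a list of ``(enzyme, dye, size_bp)`` fragments from one
    sample profile; ``library`` maps taxon -> its TrfPredictions.  A fragment
    matches a taxon when ``|observed - predicted| <= tolerance_bp`` for that
    enzyme and labeled end (dyes in ``forward_dyes`` read the forward TRF,
    anything else the reverse TRF).  A taxon enters the consensus set only if
    it is matched under every enzyme present in the profile; fragments with
    no match stay unclassified (empty taxon set), and ties within tolerance
    keep all candidate taxa.
    """
    if not library:
        raise InvalidParameterError("empty reference library")
    if tolerance_bp < 0:
        raise InvalidParameterError("tolerance_bp must be >= 0")

    # taxon -> enzyme -> predicted (forward, reverse)
    predicted: dict[str, dict[str, TrfPrediction]] = {}
    for taxon, preds in library.items():
        predicted[taxon] = {p.enzyme: p for p in preds}

    fragment_taxa = {}
    per_enzyme: dict[str, set[str]] = {}
    n_matched = 0
    for enzyme, dye, size in observed:
        taxa = set()
        for taxon, by_enz in predicted.items():
            pred = by_enz.get(enzyme)
            if pred is None:
                continue
            value = pred.forward_trf if dye in forward_dyes else pred.reverse_trf
            if abs(size - value) <= tolerance_bp:
                taxa.add(taxon)
        fragment_taxa[(enzyme, dye, size)] = frozenset(taxa)
        per_enzyme.setdefault(enzyme, set()).update(taxa)
        if taxa:
            n_matched += 1

    enzymes_used = {enzyme for enzyme, _, _ in observed}
    consensus = (
        frozenset.intersection(*(frozenset(per_enzyme.get(e, set())) for e in enzymes_used))
        if enzymes_used
        else frozenset()
    )
    matched_fraction = n_matched / len(observed) if observed else 0.0
    return AssignmentResult(
        fragment_taxa=fragment_taxa,
        consensus_taxa=consensus,
        matched_fraction=matched_fraction,
        tolerance_bp=tolerance_bp,
        per_enzyme_taxa={e: frozenset(t) for e, t in per_enzyme.items()},
    )
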