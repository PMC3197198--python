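"""Synthetic rumen scaC communities, clone libraries and electropherograms.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the package can be exercised end to end without
external data:

* a fully crossed sampling design — 3 animals x 3 weeks x 2 hours post-feed
  x 2 fractions (fiber-adherent vs planktonic/liquid) = 36 samples;
* K distinct scaC-types whose base abundances follow a geometric series
  (a few types dominate), perturbed multiplicatively by per-type
  fraction-enrichment log-fold effects, per-type week-succession multipliers
  and per-animal random (gamma) factors, then renormalized to the simplex;
* type sequences derived from one base amplicon: primer sites intact, a
  conserved N-terminal region (cohesin plus first dockerin repeat) mutating
  at one tenth of the between-type rate, and a variable region (second
  dockerin repeat and flanks) carrying most of the divergence;
* multinomial clone sampling per sample with per-site substitution errors;
* peak tables derived from predicted terminal restriction fragments with
  Gaussian size jitter, lognormal height noise and spurious baseline peaks.

Every operation is a pure function of its arguments including the seed;
independent named substreams keep operations decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scatyper import digest
from scatyper.errors import ConsistencyError, InvalidParameterError
from scatyper.profiles import PeakTable

ANIMALS = (8, 64, 71)
WEEKS = (2, 5, 8)
HOURS = (1, 9)
FRACTIONS = ("fiber", "liquid")

_STOPS = {"TAA", "TAG", "TGA"}

# Fixed substream tags so that operations sharing one master seed do not
# consume from each other's random streams.
_STREAMS = {
    "community": 101,
    "sequences": 202,
    "clones": 303,
    "peaks": 404,
    "reference": 505,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def sample_id(animal: int, week: int, hour: int, fraction: str) -> str:
    return f"{animal}_w{week}_h{hour}_{fraction}"


def full_design(
    animals=ANIMALS, weeks=WEEKS, hours=HOURS, fractions=FRACTIONS
) -> pd.DataFrame:
    """The full factor crossing as a DataFrame indexed by sample id."""
    rows = [
        {"sample_id": sample_id(a, w, h, f), "animal": a, "week": w, "hour": h,
         "fraction": f}
        for a in animals for w in weeks for h in hours for f in fractions
    ]
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class Effects:
    """Effect sizes used by :func:`simulate_community`.

    geometric_decay
        Ratio of the geometric base-abundance series; 0.7 gives realistic
        dominance (the top type holds roughly 30% of a community).
    fraction_logfold_sd
        Per-type fraction-enrichment log-fold factors are drawn from
        N(0, sd); a type with log-fold ``b`` is multiplied by ``exp(+b/2)``
        in fiber samples and ``exp(-b/2)`` in liquid samples.
    fraction_logfold
        Optional explicit per-type log-fold factors (overrides the draw).
    week_logmult_sd
        Per-type succession: log-multiplier per week step drawn from
        N(0, sd), applied as ``exp(m * step)`` with step 0, 1, 2 over weeks.
    animal_concentration
        Per-animal, per-type gamma factors with shape=rate=c (mean 1,
        variance 1/c); smaller c means stronger animal individuality.
    """

    geometric_decay: float = 0.7
    fraction_logfold_sd: float = 2.5
    fraction_logfold: np.ndarray | None = None
    week_logmult_sd: float = 0.5
    week_logmult: np.ndarray | None = None
    animal_concentration: float = 5.0


@dataclass
class CommunityTruth:
    """Ground-truth per-sample type abundances plus the generating effects."""

    types: list[str]
    abundance: pd.DataFrame  # samples x types, rows on the simplex
    design: pd.DataFrame  # indexed by sample id: animal, week, hour, fraction
    effects: dict = field(default_factory=dict)
    seed: int = 0


def simulate_community(
    k_types: int,
    design: pd.DataFrame | None = None,
    effects: Effects | None = None,
    seed: int = 0,
) -> CommunityTruth:
    """Simulate ground-truth relative abundances for every sample.

    Base abundances follow a geometric series (decay ``effects.geometric_decay``)
    over types; fraction, week and animal effects act multiplicatively on the
    simplex followed by renormalization, so the per-sample abundances always
    sum to one.
    """
    if k_types < 1:
        raise InvalidParameterError("k_types must be >= 1")
    effects = effects or Effects()
    if design is None:
        design = full_design()
    rng = _rng(seed, "community")

    types = [f"T{i:03d}" for i in range(k_types)]
    base = effects.geometric_decay ** np.arange(k_types)
    base /= base.sum()

    if effects.fraction_logfold is not None:
        frac_lf = np.asarray(effects.fraction_logfold, dtype=float)
        if frac_lf.shape != (k_types,):
            raise InvalidParameterError("fraction_logfold must have length k_types")
    else:
        frac_lf = rng.normal(0.0, effects.fraction_logfold_sd, size=k_types)
    if effects.week_logmult is not None:
        week_lm = np.asarray(effects.week_logmult, dtype=float)
    else:
        week_lm = rng.normal(0.0, effects.week_logmult_sd, size=k_types)
    if not (np.all(np.isfinite(frac_lf)) and np.all(np.isfinite(week_lm))):
        raise InvalidParameterError("effects must be finite")

    animals = sorted(design["animal"].unique())
    c = effects.animal_concentration
    animal_gamma = {
        a: rng.gamma(shape=c, scale=1.0 / c, size=k_types) for a in animals
    }

    weeks = sorted(design["week"].unique())
    week_step = {w: i for i, w in enumerate(weeks)}

    rows = []
    for sid, meta in design.iterrows():
        sign = 0.5 if meta["fraction"] == "fiber" else -0.5
        w = base * np.exp(frac_lf * sign)
        w = w * np.exp(week_lm * week_step[meta["week"]])
        w = w * animal_gamma[meta["animal"]]
        rows.append(w / w.sum())
    abundance = pd.DataFrame(rows, index=design.index, columns=types)

    return CommunityTruth(
        types=types,
        abundance=abundance,
        design=design.copy(),
        effects={
            "fraction_logfold": frac_lf,
            "week_logmult": week_lm,
            "animal_gamma": animal_gamma,
            "geometric_decay": effects.geometric_decay,
            "animal_concentration": c,
        },
        seed=seed,
    )


@dataclass(frozen=True)
class TypeSequenceModel:
    """Sequence model from which the K type sequences are derived.

    ``base_sequence`` is a complete amplicon: it begins with a realization of
    the forward primer and ends with the reverse complement of the reverse
    primer.  ``conserved_span`` (the N-terminal cohesin region and first
    dockerin repeat) mutates at one tenth of ``between_type_substitution_rate``;
    ``variable_span`` (the second dockerin repeat and its flanks) at the full
    rate; primer sites never mutate.
    """

    base_sequence: str
    conserved_span: tuple[int, int]
    variable_span: tuple[int, int]
    between_type_substitution_rate: float = 0.5
    within_type_error_rate: float = 0.002
    #: ORF coordinates (start codon to the base before the stop codon);
    #: when set, between-type substitution is codon-aware — it never breaks
    #: the start codon or introduces internal stops, since diverged strains
    #: of a real gene remain coding.
    orf_span: tuple[int, int] | None = None
    #: Nucleotide positions inside ``variable_span`` that nevertheless mutate
    #: at the low (rate/10) rate — the dockerin consensus residues of the
    #: second repeat, which stay recognizable even in diverged strains.
    anchor_sites: tuple[int, ...] = ()
    forward_primer: digest.Primer = digest.PRIMERS["scaC"][0]
    reverse_primer: digest.Primer = digest.PRIMERS["scaC"][1]

    def __post_init__(self):
        n = len(self.base_sequence)
        for name, (lo, hi) in (
            ("conserved_span", self.conserved_span),
            ("variable_span", self.variable_span),
        ):
            if not (0 <= lo < hi <= n):
                raise InvalidParameterError(f"{name} outside the amplicon")
        c, v = self.conserved_span, self.variable_span
        if max(c[0], v[0]) < min(c[1], v[1]):
            raise InvalidParameterError("conserved and variable spans overlap")
        for rate in (self.between_type_substitution_rate, self.within_type_error_rate):
            if not 0.0 <= rate <= 0.5:
                raise InvalidParameterError("rates must lie in [0, 0.5]")
        if not digest.match_degenerate_primer(self.base_sequence, self.forward_primer):
            raise InvalidParameterError("base_sequence does not begin with the forward primer")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """``n`` random codons avoiding stop codons."""
    bases = "ACGT"
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _realize(rng: np.random.Generator, iupac_seq: str) -> str:
    """Pick one concrete base for each (possibly degenerate) primer position."""
    return "".join(rng.choice(sorted(digest.IUPAC[b])) for b in iupac_seq)


def default_type_model(seed: int = 0, **overrides) -> TypeSequenceModel:
    """Build the default scaC-like amplicon model.

    Layout (nucleotide coordinates within the amplicon):

    * forward primer (23 nt, ScaFwd realization), 1 pad base;
    * ORF: ATG + 8 cohesin codons + 22-codon dockerin repeat 1 (conserved),
      then 10 linker codons + 22-codon repeat 2 (initially a duplicate of
      repeat 1) + 80 tail codons (variable) + TAA;
    * 1 pad base, reverse primer site (21 nt).

    The variable span covers ~70% of the amplicon so that, at the default
    between-type rate of 0.5, distinct types sit near 50-60% pairwise
    nucleotide identity, well below a 70% typing threshold — matching the plateau structure real scaC types show
    under a threshold sweep — while the conserved cohesin/repeat-1 region
    stays >95% identical between types.
    """
    rng = _rng(seed, "sequences")
    fwd = _realize(rng, digest.PRIMERS["scaC"][0].sequence)
    rev_site = digest.reverse_complement(_realize(rng, digest.PRIMERS["scaC"][1].sequence))
    pad1 = pad2 = "C"
    cohesin = _random_codons(rng, 8)
    repeat1 = _random_codons(rng, 22)
    linker = _random_codons(rng, 10)
    repeat2 = repeat1  # dockerin duplication
    tail = _random_codons(rng, 80)
    orf = "ATG" + cohesin + repeat1 + linker + repeat2 + tail + "TAA"
    base = fwd + pad1 + orf + pad2 + rev_site

    orf_start = len(fwd) + 1
    conserved = (orf_start, orf_start + 3 * (1 + 8 + 22))  # ATG..repeat1 end
    variable = (conserved[1], conserved[1] + 3 * (10 + 22 + 80))
    # dockerin consensus anchors: every other codon of the second repeat
    repeat2_start = conserved[1] + 3 * 10
    anchors = tuple(
        repeat2_start + 3 * c + k for c in range(0, 22, 2) for k in range(3)
    )
    kwargs = dict(
        base_sequence=base,
        conserved_span=conserved,
        variable_span=variable,
        orf_span=(orf_start, orf_start + len(orf) - 3),
        anchor_sites=anchors,
    )
    kwargs.update(overrides)
    return TypeSequenceModel(**kwargs)


def _mutable_rates(model: TypeSequenceModel, rate: float) -> np.ndarray:
    """Per-site substitution probabilities (0 on primer sites)."""
    n = len(model.base_sequence)
    rates = np.full(n, rate / 10.0)
    lo, hi = model.variable_span
    rates[lo:hi] = rate
    if model.anchor_sites:
        rates[list(model.anchor_sites)] = rate / 10.0
    rates[: len(model.forward_primer.sequence)] = 0.0
    rates[n - len(model.reverse_primer.sequence):] = 0.0
    return rates


def _substitute(rng: np.random.Generator, seq: str, site_rates: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(seq)) < site_rates
    if hit.any():
        bases = np.array([b"A", b"C", b"G", b"T"])
        for i in np.flatnonzero(hit):
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _repair_orf(seq: str, orf_span: tuple[int, int]) -> str:
    """Restore coding structure after substitution: keep the start codon ATG
    and the terminating stop, and rewrite any internal stop codon's third
    base (TAA/TAG -> TAC, TGA -> TGC)."""
    lo, hi = orf_span
    s = list(seq)
    s[lo : lo + 3] = "ATG"
    for i in range(lo + 3, hi - 2, 3):
        if "".join(s[i : i + 3]) in _STOPS:
            s[i + 2] = "C"
    if hi + 3 <= len(s) and "".join(s[hi : hi + 3]) not in _STOPS:
        s[hi : hi + 3] = "TAA"
    return "".join(s)


def simulate_type_sequences(
    model: TypeSequenceModel, k_types: int, seed: int = 0
) -> dict[str, str]:
    """Derive ``k_types`` type sequences from the model's base amplicon.

    Each type differs from the base only by substitutions drawn at the
    between-type rate inside ``variable_span`` (one tenth of it elsewhere,
    never in the primer sites).  When the model declares an ``orf_span`` the
    substitutions are codon-aware: the start codon and the absence of
    internal stops are preserved.
    """
    if k_types < 1:
        raise InvalidParameterError("k_types must be >= 1")
    rng = _rng(seed, "sequences")
    rates = _mutable_rates(model, model.between_type_substitution_rate)
    out = {}
    for i in range(k_types):
        seq = _substitute(rng, model.base_sequence, rates)
        if model.orf_span is not None:
            seq = _repair_orf(seq, model.orf_span)
        out[f"T{i:03d}"] = seq
    return out


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    sample_id: str
    sequence: str
    true_type: str


def simulate_clone_library(
    truth: CommunityTruth,
    type_seqs: dict[str, str],
    depth: int,
    seed: int = 0,
    error_rate: float | None = None,
    model: TypeSequenceModel | None = None,
) -> list[CloneRecord]:
    """Sample ``depth`` clones per sample, multinomially by true abundance.

    Per-site substitution errors (PCR/sequencing noise) are applied at
    ``error_rate`` (default: the model's ``within_type_error_rate``, or 0.002
    when no model is given); primer sites are kept intact when a model is
    supplied.  Clone ids encode the sample id as ``<sample_id>_c<serial>``.
    """
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    missing = [t for t in truth.types if t not in type_seqs]
    if missing:
        raise ConsistencyError(f"types without sequences: {missing}")
    if error_rate is None:
        error_rate = model.within_type_error_rate if model else 0.002
    rng = _rng(seed, "clones")

    if model is not None:
        site_rates = {
            t: np.minimum(
                np.full(len(s), error_rate),
                np.where(_mutable_rates(model, 1.0) > 0, error_rate, 0.0),
            )
            for t, s in type_seqs.items()
        }
    else:
        site_rates = {t: np.full(len(s), error_rate) for t, s in type_seqs.items()}

    clones = []
    for sid in truth.abundance.index:
        probs = truth.abundance.loc[sid].to_numpy()
        counts = rng.multinomial(depth, probs)
        serial = 0
        for type_idx in np.repeat(np.arange(len(probs)), counts):
            t = truth.types[type_idx]
            seq = type_seqs[t]
            if error_rate > 0:
                seq = _substitute(rng, seq, site_rates[t])
            clones.append(CloneRecord(f"{sid}_c{serial:04d}", sid, seq, t))
            serial += 1
    return clones


@dataclass(frozen=True)
class NoiseModel:
    """Electropherogram noise: size jitter (bp sd), lognormal height noise
    (sd of log height), spurious baseline peaks (expected count per trace),
    and the total fluorescence budget per sample (RFU)."""

    size_jitter_sd: float = 0.3
    height_lognormal_sd: float = 0.3
    baseline_rate: float = 5.0
    total_fluorescence: float = 50_000.0

    def __post_init__(self):
        for v in (self.size_jitter_sd, self.height_lognormal_sd,
                  self.baseline_rate, self.total_fluorescence):
            if v < 0:
                raise InvalidParameterError("noise parameters must be >= 0")


def simulate_peak_tables(
    truth: CommunityTruth,
    trfs: dict[str, digest.TrfPrediction],
    enzyme: str,
    noise: NoiseModel | None = None,
    seed: int = 0,
    forward_dye: str = "NED",
    reverse_dye: str = "6FAM",
) -> list[PeakTable]:
    """Render noisy peak tables from predicted TRFs and true abundances.

    Two tables per sample are emitted, one per dye channel (forward and
    reverse labeled ends).  Expected peak height is abundance x total
    fluorescence; observed size is the true TRF plus Gaussian jitter; spurious
    near-baseline peaks are added at the configured Poisson rate.  Heights are
    positive integers.
    """
    noise = noise or NoiseModel()
    missing = [t for t in truth.types if t not in trfs]
    if missing:
        raise ConsistencyError(f"no TRF prediction ({enzyme}) for types: {missing}")
    bad = [t for t, p in trfs.items() if p.enzyme != enzyme]
    if bad:
        raise ConsistencyError(f"TRF predictions not from enzyme {enzyme}: {bad}")
    rng = _rng(seed, "peaks")

    max_size = max(
        max(p.forward_trf for p in trfs.values()),
        max(p.reverse_trf for p in trfs.values()),
    )
    tables = []
    for sid in truth.abundance.index:
        abund = truth.abundance.loc[sid]
        for dye, attr in ((forward_dye, "forward_trf"), (reverse_dye, "reverse_trf")):
            peaks = []
            for t in truth.types:
                a = abund[t]
                if a == 0:
                    continue
                true_size = float(getattr(trfs[t], attr))
                size = true_size + (
                    rng.normal(0.0, noise.size_jitter_sd)
                    if noise.size_jitter_sd > 0 else 0.0
                )
                h = a * noise.total_fluorescence
                if noise.height_lognormal_sd > 0:
                    h *= rng.lognormal(0.0, noise.height_lognormal_sd)
                peaks.append((size, max(1, round(h))))
            if noise.baseline_rate > 0:
                for _ in range(rng.poisson(noise.baseline_rate)):
                    size = rng.uniform(30.0, max_size + 20.0)
                    height = int(rng.integers(1, 80))
                    peaks.append((size, height))
            peaks.sort()
            tables.append(PeakTable(sample_id=sid, dye=dye, enzyme=enzyme, peaks=peaks))
    return tables


_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "TM7", "Actinobacteria")


def simulate_reference_library(n_taxa: int, length: int = 900, seed: int = 0):
    """Random 16S-like reference records carrying the 8F/926R primer sites.

    Returns Biopython SeqRecords whose descriptions carry Greengenes-style
    taxonomy strings, suitable for in-silico digestion and PAT-style
    assignment.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if n_taxa < 1:
        raise InvalidParameterError("n_taxa must be >= 1")
    fwd, rev = digest.PRIMERS["16S"]
    core_len = length - len(fwd.sequence) - len(rev.sequence)
    if core_len < 0:
        raise InvalidParameterError("length shorter than the primer pair")
    rng = _rng(seed, "reference")
    records = []
    for i in range(n_taxa):
        fwd_site = _realize(rng, fwd.sequence)
        rev_site = digest.reverse_complement(_realize(rng, rev.sequence))
        core = "".join(rng.choice(list("ACGT"), size=core_len))
        phylum = _PHYLA[int(rng.integers(0, len(_PHYLA)))]
        records.append(
            SeqRecord(
                Seq(fwd_site + core + rev_site),
                id=f"ref{i:03d}",
                description=f"k__Bacteria; p__{phylum}; g__taxon{i:03d}",
            )
        )
    return records
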