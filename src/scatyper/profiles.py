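"""Peak-table I/O, profile normalization and cross-sample fragment binning.

Capillary T-RFLP traces are size-called into peak tables (fragment size in
bp, peak height in relative fluorescence units).  Because loading differs
between capillaries, profiles are normalized before comparison: every
sample's peak heights are scaled by the ratio of the smallest per-sample
total fluorescence to its own total, peaks falling below the 25-RFU
theoretical detection limit after scaling are removed, and relative peak
heights are computed against the new totals.  Fragments are then aligned
across samples by fixed-width binning into a samples x fragment-bins
relative-abundance matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scatyper.errors import FormatError, InvalidParameterError

#: Theoretical limit of detection on the capillary, in RFU.
DEFAULT_CUTOFF_RFU = 25.0

CSV_COLUMNS = ("sample_id", "dye", "enzyme", "size_bp", "height_rfu")


@dataclass
class PeakTable:
    """Size-called peaks for one sample / dye channel / enzyme."""

    sample_id: str
    dye: str
    enzyme: str
    peaks: list[tuple[float, float]]  # (size_bp, height_rfu)

    def __post_init__(self):
        for size, height in self.peaks:
            if not (math.isfinite(size) and size > 0):
                raise FormatError(
                    f"{self.sample_id}: fragment size must be finite and > 0, got {size}"
                )
            if not (math.isfinite(height) and height >= 0):
                raise FormatError(
                    f"{self.sample_id}: peak height must be >= 0, got {height}"
                )

    @property
    def total_fluorescence(self) -> float:
        return float(sum(h for _, h in self.peaks))

    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.dye, self.enzyme)


@dataclass
class FeatureMatrix:
    """Samples x features relative-abundance matrix with provenance."""

    data: pd.DataFrame  # rows: sample ids, columns: feature ids
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path):
        self.data.to_csv(path)
        sidecar = Path(path).with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))


def write_peak_tables(tables: list[PeakTable], path) -> None:
    rows = [
        {"sample_id": t.sample_id, "dye": t.dye, "enzyme": t.enzyme,
         "size_bp": size, "height_rfu": height}
        for t in tables
        for size, height in t.peaks
    ]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def read_peak_table(path) -> list[PeakTable]:
    """Read peak tables from CSV (columns: sample_id, dye, enzyme, size_bp,
    height_rfu); one PeakTable per (sample, dye, enzyme) in file order.

    Raises :class:`FormatError` with a 1-based line number on missing columns
    or non-numeric sizes/heights.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    grouped: dict[tuple, list] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            size = float(row["size_bp"])
            height = float(row["height_rfu"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {line}: non-numeric size_bp/height_rfu "
                f"({row['size_bp']!r}, {row['height_rfu']!r})"
            )
        if not (math.isfinite(size) and math.isfinite(height)):
            raise FormatError(f"{path}: line {line}: non-finite value")
        key = (row["sample_id"], row["dye"], row["enzyme"])
        grouped.setdefault(key, []).append((size, height))
    return [
        PeakTable(sample_id=k[0], dye=k[1], enzyme=k[2], peaks=v)
        for k, v in grouped.items()
    ]


@dataclass
class NormalizationReport:
    reference_total: float
    ratios: dict  # table key -> adjustment ratio
    removed_counts: dict  # table key -> peaks removed by the cutoff
    excluded: list  # keys of zero-total samples, dropped with a warning
    cutoff_rfu: float = DEFAULT_CUTOFF_RFU


def normalize_profiles(
    tables: list[PeakTable], cutoff_rfu: float = DEFAULT_CUTOFF_RFU
) -> tuple[list[PeakTable], NormalizationReport]:
    """Single-pass profile normalization with a detection cutoff.

    Steps: (1) total fluorescence per sample; (2) the minimum total is the
    reference; (3) each sample's adjustment ratio = reference / own total;
    (4) all heights scaled by the ratio; (5) scaled heights below
    ``cutoff_rfu`` removed; (6) new totals; (7) relative peak height =
    scaled height / new total.  Samples with zero total fluorescence are
    excluded and reported.  Output peak heights are the relative heights
    (rows effectively sum to 1).
    """
    if not tables:
        raise InvalidParameterError("no peak tables supplied")
    totals = {t.key(): t.total_fluorescence for t in tables}
    excluded = [k for k, v in totals.items() if v == 0]
    live = [t for t in tables if totals[t.key()] > 0]
    if not live:
        raise InvalidParameterError("all samples have zero total fluorescence")

    reference = min(totals[t.key()] for t in live)
    ratios = {t.key(): reference / totals[t.key()] for t in live}

    out = []
    removed_counts = {}
    for t in live:
        ratio = ratios[t.key()]
        scaled = [(size, h * ratio) for size, h in t.peaks]
        kept = [(size, h) for size, h in scaled if h >= cutoff_rfu]
        removed_counts[t.key()] = len(scaled) - len(kept)
        new_total = sum(h for _, h in kept)
        if new_total > 0:
            kept = [(size, h / new_total) for size, h in kept]
        out.append(
            PeakTable(sample_id=t.sample_id, dye=t.dye, enzyme=t.enzyme, peaks=kept)
        )
    report = NormalizationReport(
        reference_total=reference,
        ratios=ratios,
        removed_counts=removed_counts,
        excluded=excluded,
        cutoff_rfu=cutoff_rfu,
    )
    return out, report


def build_feature_matrix(
    tables: list[PeakTable], bin_width_bp: float = 1.0
) -> FeatureMatrix:
    """Bin normalized profiles into a samples x fragment-bins matrix.

    Fragment sizes fall into half-open bins [k*w, (k+1)*w); relative heights
    are summed within a bin; the feature set is the union of occupied bins
    across samples (absent bins are 0) and rows are re-normalized to sum to 1.
    One row per input PeakTable, indexed by sample id.
    """
    if bin_width_bp <= 0:
        raise InvalidParameterError("bin_width_bp must be > 0")
    rows = {}
    for t in tables:
        binned: dict[int, float] = {}
        for size, h in t.peaks:
            k = int(math.floor(size / bin_width_bp))
            binned[k] = binned.get(k, 0.0) + h
        if t.sample_id in rows:
            for k, h in binned.items():
                rows[t.sample_id][k] = rows[t.sample_id].get(k, 0.0) + h
        else:
            rows[t.sample_id] = binned

    all_bins = sorted({k for binned in rows.values() for k in binned})
    columns = [f"{k * bin_width_bp:g}" for k in all_bins]
    data = pd.DataFrame(
        [[rows[sid].get(k, 0.0) for k in all_bins] for sid in rows],
        index=list(rows),
        columns=columns,
    )
    sums = data.sum(axis=1)
    nonzero = sums > 0
    data.loc[nonzero] = data.loc[nonzero].div(sums[nonzero], axis=0)
    enzymes = sorted({t.enzyme for t in tables})
    dyes = sorted({t.dye for t in tables})
    return FeatureMatrix(
        data=data,
        provenance={"bin_width_bp": bin_width_bp, "enzymes": enzymes, "dyes": dyes},
    )
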