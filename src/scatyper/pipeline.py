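"""End-to-end workflows: T-RFLP community analysis and clone-library typing.

``run_trflp_pipeline`` takes peak tables plus sample metadata and produces,
per week and per enzyme, the normalized feature matrix, Bray-Curtis distance
matrix, NMDS ordination, ANOSIM tables for the design factors (individual
animal with pairwise breakdown, hour post-feed, fraction) and the SIMPER
top-10 fragment listing for the fiber/liquid contrast.

``run_clone_pipeline`` takes clone sequences plus metadata and chains ORF
trimming, the clustering threshold sweep with diversity estimates, the
universal-type summary at the typing threshold, and translation plus dockerin
repeat detection of each type representative.

``upgma_tree`` provides a deterministic UPGMA dendrogram (Newick) used to
order heatmap rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from skbio import DistanceMatrix

from scatyper import clustering, digest, motifs, profiles, stats
from scatyper.errors import ConsistencyError, InvalidParameterError

#: Default permutation counts per marker.
DEFAULT_PERMUTATIONS = {"16S": 10_000, "scaC": 999}


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    marker: str = "scaC"
    enzymes: tuple[str, ...] | None = None  # default: the marker's panel
    cutoff_rfu: float = profiles.DEFAULT_CUTOFF_RFU
    bin_width_bp: float = 1.0
    thresholds: tuple[float, ...] = clustering.DEFAULT_THRESHOLDS
    type_threshold: float = 70.0
    n_permutations: int | None = None  # default: per-marker
    nmds_starts: int = 200
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.marker not in digest.ENZYME_PANELS:
            raise InvalidParameterError(f"unknown marker {self.marker!r}")
        if self.enzymes is None:
            self.enzymes = digest.ENZYME_PANELS[self.marker]
        unknown = [e for e in self.enzymes if e not in digest.ENZYMES]
        if unknown:
            raise InvalidParameterError(f"unknown enzymes {unknown}")
        if self.n_permutations is None:
            self.n_permutations = DEFAULT_PERMUTATIONS[self.marker]
        if self.n_permutations < 99:
            raise InvalidParameterError("n_permutations must be >= 99")


def _feature_matrix_for(
    tables: list[profiles.PeakTable], bin_width_bp: float
) -> profiles.FeatureMatrix:
    """Per-enzyme matrix with dye-qualified fragment bins as features."""
    by_dye: dict[str, list[profiles.PeakTable]] = {}
    for t in tables:
        by_dye.setdefault(t.dye, []).append(t)
    parts = []
    for dye in sorted(by_dye):
        fm = profiles.build_feature_matrix(by_dye[dye], bin_width_bp)
        fm.data.columns = [f"{dye}:{c}" for c in fm.data.columns]
        parts.append(fm.data)
    data = pd.concat(parts, axis=1).fillna(0.0)
    sums = data.sum(axis=1)
    data = data.div(sums.where(sums > 0, 1.0), axis=0)
    return profiles.FeatureMatrix(
        data=data, provenance={"bin_width_bp": bin_width_bp, "dyes": sorted(by_dye)}
    )


@dataclass
class TrflpBundle:
    feature_matrices: dict  # (week, enzyme) -> FeatureMatrix
    distance_matrices: dict  # (week, enzyme) -> DistanceMatrix
    nmds_results: dict  # (week, enzyme) -> NmdsResult
    anosim_table: pd.DataFrame  # Tables-1/2-shaped: week, factor, enzyme, R, p
    simper_top10: dict  # (week, enzyme) -> SimperResult
    normalization_report: object
    manifest: dict = field(default_factory=dict)


def run_trflp_pipeline(
    tables: list[profiles.PeakTable],
    metadata: pd.DataFrame,
    config: RunConfig | None = None,
) -> TrflpBundle:
    """The T-RFLP community workflow over all weeks and enzymes.

    ``metadata`` is indexed by sample id with columns animal, week, hour and
    fraction.  Profiles are normalized across all samples per enzyme, binned
    per week into per-enzyme feature matrices (square-root transformed), and
    analyzed by Bray-Curtis + NMDS + one-way ANOSIM per factor (animal with
    pairwise sub-results) + SIMPER on the fiber/liquid contrast.
    """
    config = config or RunConfig()
    sample_ids = {t.sample_id for t in tables}
    missing = sorted(sample_ids - set(metadata.index))
    if missing:
        raise ConsistencyError(f"samples without metadata: {missing}")

    feature_matrices = {}
    distance_matrices = {}
    nmds_results = {}
    simper_top10 = {}
    anosim_rows = []
    report = None

    weeks = sorted(metadata["week"].unique())
    for enzyme in config.enzymes:
        enz_tables = [t for t in tables if t.enzyme == enzyme]
        if not enz_tables:
            raise ConsistencyError(f"no peak tables for enzyme {enzyme}")
        normalized, report = profiles.normalize_profiles(enz_tables, config.cutoff_rfu)
        for week in weeks:
            week_samples = set(metadata.index[metadata["week"] == week])
            week_tables = [t for t in normalized if t.sample_id in week_samples]
            if not week_tables:
                continue
            fm = stats.sqrt_transform(
                _feature_matrix_for(week_tables, config.bin_width_bp)
            )
            dm = stats.bray_curtis(fm)
            feature_matrices[(week, enzyme)] = fm
            distance_matrices[(week, enzyme)] = dm
            nmds_results[(week, enzyme)] = stats.nmds(
                dm, n_starts=config.nmds_starts, seed=config.seed
            )
            grouping = {
                "individual": metadata.loc[list(dm.ids), "animal"].astype(str),
                "hour": metadata.loc[list(dm.ids), "hour"].astype(str),
                "fraction": metadata.loc[list(dm.ids), "fraction"].astype(str),
            }
            for factor, labels in grouping.items():
                res = stats.anosim(
                    dm,
                    labels,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                    pairwise=factor == "individual",
                )
                anosim_rows.append(
                    {"week": week, "factor": factor, "enzyme": enzyme,
                     "R": res.R, "p": res.p}
                )
                for a, b, sub in res.pairwise:
                    anosim_rows.append(
                        {"week": week, "factor": f"pairwise ({a}, {b})",
                         "enzyme": enzyme, "R": sub.R, "p": sub.p}
                    )
            simper_top10[(week, enzyme)] = stats.simper(
                fm, metadata.loc[list(dm.ids), "fraction"], ("fiber", "liquid")
            )

    anosim_table = pd.DataFrame(anosim_rows)
    bundle = TrflpBundle(
        feature_matrices=feature_matrices,
        distance_matrices=distance_matrices,
        nmds_results=nmds_results,
        anosim_table=anosim_table,
        simper_top10=simper_top10,
        normalization_report=report,
        manifest=_manifest(config, n_tables=len(tables)),
    )
    if config.outdir:
        _write_trflp(bundle, config)
    return bundle


@dataclass
class CloneBundle:
    trim_report: pd.DataFrame  # clone id, status, reason
    sweep_table: pd.DataFrame  # threshold, s_obs, chao1, shannon, ...
    clusters: dict  # threshold -> ClusterSet
    typing_clusters: clustering.ClusterSet  # at the typing threshold
    universal: clustering.UniversalTypeSummary | None
    motif_table: pd.DataFrame  # per-representative dockerin hits
    manifest: dict = field(default_factory=dict)


def run_clone_pipeline(
    records: list[clustering.SeqRecord],
    clone_meta: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> CloneBundle:
    """The clone-library typing workflow.

    Chains ORF trimming -> greedy-clustering threshold sweep with Chao1 and
    Shannon per threshold -> universal-type summary at the typing threshold
    (when clone metadata is given) -> translation and dockerin-repeat
    detection of each type representative (founder).
    """
    config = config or RunConfig()
    if not records:
        raise InvalidParameterError("empty clone library")

    trimmed = []
    trim_rows = []
    for rec in records:
        out = clustering.trim_to_orf(rec)
        if isinstance(out, clustering.Rejection):
            trim_rows.append({"clone": rec.id, "status": "rejected", "reason": out.reason})
        else:
            trimmed.append(out)
            trim_rows.append({"clone": rec.id, "status": "kept", "reason": ""})
    trim_report = pd.DataFrame(trim_rows)
    if not trimmed:
        raise InvalidParameterError("all sequences rejected at ORF trimming")

    sweep_table, clusters = clustering.threshold_sweep(trimmed, config.thresholds)
    if config.type_threshold in clusters:
        typing = clusters[config.type_threshold]
    else:
        typing = clustering.greedy_cluster(trimmed, config.type_threshold)

    universal = None
    if clone_meta is not None:
        universal = clustering.universal_types(typing, clone_meta)

    motif_rows = []
    for b in typing.bins:
        prot = motifs.translate_orf(b.founder)
        hit = motifs.find_dockerin_repeats(prot)
        row = {"type": b.name, "n_members": b.size, "protein_length": len(prot.sequence)}
        if isinstance(hit, motifs.DockerinHit):
            row.update(
                detected=True, repeat1_start=hit.repeat1[0],
                repeat2_start=hit.repeat2[0], spacing=hit.spacing, score=hit.score,
            )
        else:
            row.update(detected=False, repeat1_start=-1, repeat2_start=-1,
                       spacing=-1, score=float("nan"))
        motif_rows.append(row)

    bundle = CloneBundle(
        trim_report=trim_report,
        sweep_table=sweep_table,
        clusters=clusters,
        typing_clusters=typing,
        universal=universal,
        motif_table=pd.DataFrame(motif_rows),
        manifest=_manifest(config, n_records=len(records)),
    )
    if config.outdir:
        _write_clones(bundle, config)
    return bundle


def upgma_tree(dm: DistanceMatrix) -> str:
    """UPGMA dendrogram of a distance matrix as a Newick string.

    Standard average-linkage agglomeration with ultrametric heights; ties in
    the minimum distance are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labeled by its smallest leaf id), so the
    result is deterministic.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise InvalidParameterError("need at least 2 leaves")
    d = {frozenset((a, b)): dm[a, b] for i, a in enumerate(ids) for b in ids[i + 1:]}
    clusters = {i: {"leaves": [i], "newick": str(i), "height": 0.0, "label": i}
                for i in ids}
    while len(clusters) > 1:
        keys = list(clusters)
        best = min(
            (
                (d[frozenset((a, b))], tuple(sorted((clusters[a]["label"],
                                                     clusters[b]["label"])))[0],
                 tuple(sorted((clusters[a]["label"], clusters[b]["label"])))[1],
                 a, b)
                for i, a in enumerate(keys) for b in keys[i + 1:]
            ),
        )
        dist, _, _, a, b = best
        ca, cb = clusters.pop(a), clusters.pop(b)
        if str(cb["label"]) < str(ca["label"]):  # smaller label renders first
            ca, cb = cb, ca
        height = dist / 2.0
        newick = (
            f"({ca['newick']}:{height - ca['height']:.10g},"
            f"{cb['newick']}:{height - cb['height']:.10g})"
        )
        label = min(ca["label"], cb["label"])
        merged = {
            "leaves": ca["leaves"] + cb["leaves"],
            "newick": newick,
            "height": height,
            "label": label,
        }
        na, nb = len(ca["leaves"]), len(cb["leaves"])
        for other in clusters:
            # UPGMA update: size-weighted average of the two merged clusters
            d_oa = _lookup(d, ca, clusters[other])
            d_ob = _lookup(d, cb, clusters[other])
            d[frozenset((label, clusters[other]["label"]))] = (
                (na * d_oa + nb * d_ob) / (na + nb)
            )
        clusters[label] = merged
    (root,) = clusters.values()
    return root["newick"] + ";"


def _lookup(d, cluster_a, cluster_b):
    return d[frozenset((cluster_a["label"], cluster_b["label"]))]


def _manifest(config: RunConfig, **inputs) -> dict:
    cfg = {k: v for k, v in vars(config).items()}
    cfg["enzymes"] = list(config.enzymes)
    cfg["thresholds"] = list(config.thresholds)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "inputs": inputs,
        "seed": config.seed,
    }


def _write_trflp(bundle: TrflpBundle, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.anosim_table.to_csv(out / "anosim.csv", index=False)
    for (week, enzyme), fm in bundle.feature_matrices.items():
        fm.to_csv(out / f"features_w{week}_{enzyme}.csv")
    for (week, enzyme), res in bundle.nmds_results.items():
        res.coordinates.assign(stress=res.stress).to_csv(
            out / f"nmds_w{week}_{enzyme}.csv"
        )
    for (week, enzyme), sim in bundle.simper_top10.items():
        sim.top10.assign(
            average_dissimilarity=sim.average_dissimilarity
        ).to_csv(out / f"simper_w{week}_{enzyme}.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, default=str)
    )


def _write_clones(bundle: CloneBundle, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.trim_report.to_csv(out / "trim_report.csv", index=False)
    bundle.sweep_table.to_csv(out / "cluster_sweep.csv", index=False)
    bundle.typing_clusters.to_frame().to_csv(out / "cluster_members.csv", index=False)
    bundle.motif_table.to_csv(out / "dockerin_hits.csv", index=False)
    if bundle.universal is not None:
        bundle.universal.counts_by_animal.to_csv(out / "type_counts_by_animal.csv")
        pd.Series(bundle.universal.universal, name="type").to_csv(
            out / "universal_types.csv", index=False
        )
        bundle.universal.universal_share_by_animal.rename("share").to_csv(
            out / "universal_share_by_animal.csv"
        )
        for factor, table in bundle.universal.counts_by_factor.items():
            table.to_csv(out / f"type_counts_by_{factor}.csv")
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, default=str)
    )
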