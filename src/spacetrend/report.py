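"""Cohort-level trend tables and the end-to-end pipeline.

For every measurement, the subjects with a BH-significant trend class are
counted and their per-phase direction relative to the pre-flight baseline is
coded on the normalized scale: the flight phase F averages the 33/82/132 d
bins, the return phase R is the 165 d bin, and the post-return phase PR
averages the 195/225 d bins.  A phase mean above +epsilon codes as an
up-arrow, below -epsilon as a down-arrow, and within the deadband as a dash;
the cohort trend per phase is the majority code over significant subjects,
with a secondary triple reported when a sufficient fraction of subjects
share a different one.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import spacetrend
from spacetrend import cluster, network, preprocess, spectral, synthetic, visibility
from spacetrend.grid import TimeGrid

UP, DOWN, FLAT = "↑", "↓", "−"

#: Deadband on the normalized scale inside which a phase codes as flat.
DEFAULT_EPSILON = 0.1
#: A different trend triple shared by at least this fraction is reported
#: as the secondary trend.
DEFAULT_SECONDARY_FRACTION = 0.25

#: Phase definitions as bin labels (days).
PHASES = {"F": (33.0, 82.0, 132.0), "R": (165.0,), "PR": (195.0, 225.0)}


def phase_code(values: np.ndarray, grid: TimeGrid, epsilon: float) -> str:
    """F/R/PR direction triple of one normalized series, e.g. '↑−↓'."""
    labels = list(grid.labels)
    codes = []
    for bins in PHASES.values():
        idx = [labels.index(b) for b in bins]
        phase_values = np.asarray(values, dtype=float)[idx]
        present = phase_values[~np.isnan(phase_values)]
        mean = present.mean() if present.size else np.nan
        if np.isnan(mean):
            codes.append(FLAT)
        elif mean > epsilon:
            codes.append(UP)
        elif mean < -epsilon:
            codes.append(DOWN)
        else:
            codes.append(FLAT)
    return "".join(codes)


def summarize_trends(
    classification: pd.DataFrame,
    normalized: pd.DataFrame,
    grid: TimeGrid | None = None,
    epsilon: float = DEFAULT_EPSILON,
    secondary_fraction: float = DEFAULT_SECONDARY_FRACTION,
) -> pd.DataFrame:
    """Aggregate per-subject classifications into a cohort trend table.

    One row per measurement with at least one significant subject, sorted by
    subject count (descending, ties by measurement id): columns
    measurement_id, n_subjects, trend (majority F/R/PR triple), secondary
    (a different triple shared by >= secondary_fraction of the significant
    subjects, else empty).
    """
    grid = grid or TimeGrid()
    significant = classification[
        classification["significant"] & (classification["kind"] != spectral.NO_TREND)
    ]
    rows = []
    for mid, chunk in significant.groupby("measurement_id", sort=True):
        triples = []
        for sid in chunk["subject_id"]:
            values = normalized.loc[(sid, mid)].to_numpy(dtype=float)
            triples.append(phase_code(values, grid, epsilon))
        counts = pd.Series(triples).value_counts()
        primary = counts.index[0]
        secondary = ""
        for triple, c in counts.iloc[1:].items():
            if c >= secondary_fraction * len(triples):
                secondary = triple
                break
        rows.append((mid, len(triples), primary, secondary))
    table = pd.DataFrame(rows, columns=["measurement_id", "n_subjects", "trend", "secondary"])
    return table.sort_values(
        ["n_subjects", "measurement_id"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run.  Every random stage derives its seed
    from ``seed``, so identical configs give byte-identical outputs."""

    out_dir: str = "spacetrend_run"
    cohort_csv: str | None = None          # use an existing cohort instead of simulating
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    min_bins: int = preprocess.DEFAULT_MIN_BINS
    n_boot: int = spectral.DEFAULT_N_BOOT
    level: float = spectral.DEFAULT_LEVEL
    alpha: float = 0.05
    radius_level: float = network.DEFAULT_RADIUS_LEVEL
    n_signals: int = network.DEFAULT_N_SIGNALS
    n_pairs: int = network.DEFAULT_N_PAIRS
    consensus_runs: int = 1000
    k_mode: str = "auto"
    k: int | None = None
    embedding_dim: int = 2
    epsilon: float = DEFAULT_EPSILON
    secondary_fraction: float = DEFAULT_SECONDARY_FRACTION
    seed: int = 0


def _cohort_manifest(cohort: synthetic.CohortConfig) -> dict:
    """JSON-safe dump of a cohort config (tuple keys flattened)."""
    d = asdict(cohort)
    d["assignment"] = {
        f"block{b}:{m}": spec for (b, m), spec in d["assignment"].items()
    }
    return d


@dataclass
class PipelineResult:
    records: pd.DataFrame
    truth: synthetic.GroundTruth | None
    prep: preprocess.PreprocessResult
    classification: pd.DataFrame
    clusters: pd.DataFrame
    visibility: list[dict]
    adjacency: pd.DataFrame
    graph: "object"
    labeling: network.CommunityLabeling | None
    summary: pd.DataFrame
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole pipeline and write all artifacts to ``out_dir``."""
    grid = TimeGrid()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.cohort_csv is not None:
            records = synthetic.read_cohort(config.cohort_csv)
            truth = None
        else:
            cohort_cfg = config.cohort
            if cohort_cfg.seed != config.seed:
                from dataclasses import replace
                cohort_cfg = replace(cohort_cfg, seed=config.seed)
            records, truth = synthetic.generate_cohort(cohort_cfg, grid)
            truth.to_json(out / "ground_truth.json")
        synthetic.write_cohort(records, out / "cohort.csv")

        stage = "preprocess"
        prep = preprocess.preprocess_cohort(records, grid, config.min_bins)
        preprocess.write_matrix(prep.binned, out / "binned.tsv")
        preprocess.write_matrix(prep.normalized, out / "normalized.tsv")
        prep.drop_log.to_csv(out / "drop_log.tsv", sep="\t", index=False)

        stage = "classify"
        classification, _ = spectral.classify_cohort(
            prep.normalized, grid, n_boot=config.n_boot, level=config.level,
            alpha=config.alpha, seed=config.seed,
        )
        classification.to_csv(out / "classification.tsv", sep="\t", index=False)

        stage = "cluster"
        clusters = cluster.cluster_cohort(classification, prep.normalized, grid)
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)

        stage = "visibility"
        vis_records = []
        for (sid, label, g_idx, s_idx), chunk in clusters.groupby(
            ["subject_id", "class_label", "group", "subgroup"], sort=True
        ):
            members = prep.normalized.loc[
                [(sid, m) for m in chunk["measurement_id"]]
            ].to_numpy(dtype=float)
            signal = visibility.median_group_signal(members)
            if np.sum(~np.isnan(signal)) < 2:
                continue
            summary = visibility.summarize_visibility(signal, np.asarray(grid.labels))
            summary.update(subject_id=sid, class_label=label,
                           group=int(g_idx), subgroup=int(s_idx))
            vis_records.append(summary)
        (out / "visibility.json").write_text(json.dumps(vis_records, indent=1, sort_keys=True))

        stage = "network"
        pgrams = network.cohort_periodograms(prep.normalized, grid)
        dists, roster = network.periodogram_distances(pgrams)
        pool = prep.normalized.to_numpy(dtype=float).ravel()
        radius = network.similarity_radius(
            pool, grid, n_signals=config.n_signals, level=config.radius_level,
            n_pairs=config.n_pairs, seed=spectral.subject_seed(config.seed, 10_000),
        )
        adjacency, graph, edge_meas = network.restricted_adjacency(dists, radius, roster)
        labeling = None
        if len(roster) >= 2 and config.consensus_runs > 0:
            labeling = network.consensus_communities(
                adjacency, dim=config.embedding_dim, k_mode=config.k_mode,
                k=config.k, n_runs=config.consensus_runs,
                seed=spectral.subject_seed(config.seed, 20_000),
            )
            (out / "communities.json").write_text(json.dumps(
                network.community_report(labeling, edge_meas), indent=1, sort_keys=True
            ))
        network.write_graphml(graph, labeling, out / "network.graphml")
        network.write_edgelist(graph, out / "network_edges.tsv")

        stage = "summarize"
        summary = summarize_trends(
            classification, prep.normalized, grid,
            epsilon=config.epsilon, secondary_fraction=config.secondary_fraction,
        )
        summary.to_csv(out / "trend_summary.tsv", sep="\t", index=False)

        manifest = {
            "package": "spacetrend",
            "version": spacetrend.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "parameters": {
                k: v for k, v in asdict(config).items() if k != "cohort"
            },
            "cohort": _cohort_manifest(config.cohort) if config.cohort_csv is None else None,
            "radius": asdict(radius),
            "n_series_kept": int(len(prep.normalized)),
            "n_subjects": len(roster),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )
    except Exception as exc:  # noqa: BLE001 - annotate failing stage, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        records=records, truth=truth, prep=prep, classification=classification,
        clusters=clusters, visibility=vis_records, adjacency=adjacency,
        graph=graph, labeling=labeling, summary=summary, out_dir=out,
    )
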