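"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
statistics -> graphs -> report.

A run is driven by a :class:`RunConfig` (YAML-loadable) and a single seed;
identical config + seed produce byte-identical TSV outputs.  Per contrast
(task vs baseline) the run emits the edge-test table, the significance
graph's vertex/graph metrics, and threshold-swept binarized-graph summaries
of the group-mean correlation matrices; per participant it emits QC JSON.
A JSON manifest lists every output with the config echo, package and
library versions, the seed, and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from micnet.connectivity import ConnectivityMatrix, crosscorr_matrix, threshold_graph, zscore_matrices
from micnet.graphstats import graph_summary, vertex_metrics_table
from micnet.inference import edge_test_results, significant_subgraph
from micnet.paradigm import SessionSpec, build_schedule, standard_montage
from micnet.preprocess import (
    BASELINE_LABEL,
    EpochSet,
    QCReport,
    RejectionThresholds,
    bandpass_notch,
    epoch,
    reject_artifacts,
)
from micnet.synthgen import ArtifactModel, LatentSourceModel, Recording, simulate_recording

__all__ = [
    "RunConfig",
    "StudyResult",
    "compute_study",
    "run_pipeline",
    "concat_epochs",
    "participant_connectivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs.

    ``input_prefixes`` may list saved recording prefixes (one per
    participant-session); when empty, recordings are simulated from
    ``spec``/``model``/``artifacts``.
    """

    spec: SessionSpec = field(default_factory=SessionSpec)
    model: LatentSourceModel = field(default_factory=LatentSourceModel)
    artifacts: ArtifactModel = field(default_factory=ArtifactModel)
    thresholds: RejectionThresholds = field(default_factory=RejectionThresholds)
    input_prefixes: tuple[str, ...] = ()
    max_lag: int = 0
    target_variance: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    top_k: int = 19
    r_thresholds: tuple[float, ...] = (0.7, 0.8, 0.9)
    seed: int = 0
    out_dir: str = "micnet_out"

    def __post_init__(self) -> None:
        if list(self.r_thresholds) != sorted(self.r_thresholds):
            raise ValueError("r_thresholds must be sorted ascending")
        if any(not 0.0 < t < 1.0 for t in self.r_thresholds):
            raise ValueError("r_thresholds must lie in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [unpack(v) for v in obj]
            if isinstance(obj, dict):
                return {k: unpack(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return unpack(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs = {}
        if "spec" in raw:
            kwargs["spec"] = SessionSpec(**raw.pop("spec"))
        if "model" in raw:
            model = raw.pop("model")
            if "coupling_edges" in model:
                model["coupling_edges"] = tuple(tuple(e) for e in model["coupling_edges"])
            if "bands" in model:
                model["bands"] = tuple(tuple(b) for b in model["bands"])
            kwargs["model"] = LatentSourceModel(**model)
        if "artifacts" in raw:
            kwargs["artifacts"] = ArtifactModel(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.pop("artifacts").items()
            })
        if "thresholds" in raw:
            thr = raw.pop("thresholds")
            if "emg_band_hz" in thr:
                thr["emg_band_hz"] = tuple(thr["emg_band_hz"])
            kwargs["thresholds"] = RejectionThresholds(**thr)
        if "r_thresholds" in raw:
            raw["r_thresholds"] = tuple(raw["r_thresholds"])
        if "input_prefixes" in raw:
            raw["input_prefixes"] = tuple(raw["input_prefixes"])
        kwargs.update(raw)
        return cls(**kwargs)


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets of one participant (e.g. across sessions)."""
    parts = [p for p in parts if len(p)]
    if not parts:
        raise ValueError("no epochs to concatenate")
    offsets = np.cumsum([0] + [int(p.trial_index.max()) + 1 if p.trial_index is not None
                               and len(p.trial_index) else len(p) for p in parts[:-1]])
    trial_index = np.concatenate(
        [
            (p.trial_index if p.trial_index is not None else np.arange(len(p))) + off
            for p, off in zip(parts, offsets)
        ]
    )
    return EpochSet(
        epochs=np.concatenate([p.epochs for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        participant_id=parts[0].participant_id,
        kept_mask=np.concatenate([p.kept_mask for p in parts]),
        eog=np.concatenate([p.eog for p in parts]) if parts[0].eog is not None else None,
        trial_index=trial_index,
    )


def participant_connectivity(
    epochs: EpochSet,
    conditions: tuple[str, ...],
    max_lag: int = 0,
    target_variance: float = 1.0,
) -> dict[str, ConnectivityMatrix]:
    """Per-condition z-normalized adjacency matrices for one participant.

    Returns matrices for baseline plus every condition, jointly normalized
    with one affine map per participant.
    """
    raw = [
        crosscorr_matrix(epochs, cond, max_lag=max_lag)
        for cond in (BASELINE_LABEL, *conditions)
    ]
    normalized = zscore_matrices(raw, target_variance=target_variance)
    return {m.condition: m for m in normalized}


def _preprocess_participant(
    recordings: list[Recording], thresholds: RejectionThresholds
) -> tuple[EpochSet, QCReport]:
    parts = []
    reports = []
    for rec in recordings:
        filtered = bandpass_notch(rec)
        eps = epoch(filtered)
        eps, rep = reject_artifacts(eps, thresholds=thresholds,
                                    sample_rate_hz=rec.sample_rate_hz)
        parts.append(eps)
        reports.append(rep)
    pooled = concat_epochs(parts)
    n_total = sum(r.n_trials for r in reports)
    eog = sum(r.pct_eog_rejected * r.n_trials for r in reports) / max(n_total, 1)
    emg = sum(r.pct_emg_rejected * r.n_trials for r in reports) / max(n_total, 1)
    report = QCReport(
        n_trials=n_total,
        pct_eog_rejected=round(eog, 1),
        pct_emg_rejected=round(emg, 1),
    )
    return pooled, report


@dataclass
class StudyResult:
    """In-memory result of a full study run (no file output).

    ``contrasts`` maps each task label to its per-edge test results, the
    significance graph, and the report table.
    """

    qc: dict
    raw_r: dict[str, list[ConnectivityMatrix]]
    z_matrices: dict[str, list[ConnectivityMatrix]]
    contrasts: dict[str, dict]


def compute_study(config: RunConfig) -> StudyResult:
    """Simulate (or load), preprocess, and run every condition contrast."""
    spec = config.spec
    montage = standard_montage()
    conditions = spec.task_labels

    per_participant: dict[int, list[Recording]] = {}
    if config.input_prefixes:
        for prefix in config.input_prefixes:
            rec = Recording.load(prefix, spec=spec)
            pid = rec.schedule.participants[0]
            per_participant.setdefault(pid, []).append(rec)
    else:
        schedule = build_schedule(spec, seed=config.seed)
        for pid in schedule.participants:
            per_participant[pid] = [
                simulate_recording(
                    schedule.subset(participant_id=pid, session_index=ses),
                    model=config.model,
                    artifacts=config.artifacts,
                    seed=config.seed,
                )
                for ses in schedule.subset(participant_id=pid).sessions
            ]

    qc_all = {}
    z_matrices: dict[str, list[ConnectivityMatrix]] = {
        c: [] for c in (BASELINE_LABEL, *conditions)
    }
    raw_r: dict[str, list[ConnectivityMatrix]] = {
        c: [] for c in (BASELINE_LABEL, *conditions)
    }
    for pid, recs in sorted(per_participant.items()):
        pooled, report = _preprocess_participant(recs, config.thresholds)
        qc_all[pid] = report.to_dict()
        for cond in (BASELINE_LABEL, *conditions):
            raw_r[cond].append(crosscorr_matrix(pooled, cond, max_lag=config.max_lag))
        normalized = zscore_matrices(
            [raw_r[c][-1] for c in (BASELINE_LABEL, *conditions)],
            target_variance=config.target_variance,
        )
        for m in normalized:
            z_matrices[m.condition].append(m)

    contrasts = {}
    for k, cond in enumerate(conditions):
        results = edge_test_results(
            z_matrices[cond],
            z_matrices[BASELINE_LABEL],
            n_perm=config.n_perm,
            seed=(int(config.seed) * 1000 + 7 * k + 1) & 0x7FFFFFFF,
            n_channels=len(montage),
        )
        graph, report = significant_subgraph(
            results, alpha=config.alpha, top_k=config.top_k, montage=montage
        )
        contrasts[cond] = {"results": results, "graph": graph, "report": report}
    return StudyResult(qc=qc_all, raw_r=raw_r, z_matrices=z_matrices,
                       contrasts=contrasts)


def _group_mean_r(matrices: list[ConnectivityMatrix], condition: str) -> ConnectivityMatrix:
    """Fisher-z mean of per-participant correlation matrices."""
    z = np.mean(
        [np.arctanh(np.clip(m.values, -0.999999, 0.999999)) for m in matrices], axis=0
    )
    values = np.tanh(z)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values=values, kind="r", condition=condition,
                              participant_id="group")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    On failure every file created by this run is removed before the
    exception propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def emit(path: Path) -> Path:
        created.append(path)
        return path

    try:
        return _run(config, out_dir, emit, created)
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out_dir: Path, emit, created: list[Path]) -> dict:
    spec = config.spec
    montage = standard_montage()
    conditions = spec.task_labels
    logger.info("run seed=%d config_hash=%s", config.seed, config.config_hash())

    study = compute_study(config)
    raw_r = study.raw_r

    qc_path = emit(out_dir / "qc.json")
    qc_path.write_text(json.dumps(study.qc, indent=2))

    # --- group matrices + threshold sweep --------------------------------
    outputs: dict[str, list[str] | str] = {"qc": str(qc_path)}
    sweep_rows = []
    matrix_paths = []
    for cond in (BASELINE_LABEL, *conditions):
        group = _group_mean_r(raw_r[cond], cond)
        path = emit(out_dir / f"connectivity_{cond}_group_r.tsv")
        group.to_tsv(path, montage)
        matrix_paths.append(str(path))
        for thr in config.r_thresholds:
            g = threshold_graph(group, thr)
            sweep_rows.append({
                "condition": cond,
                "r_threshold": thr,
                **graph_summary(g),
            })
    sweep_path = emit(out_dir / "threshold_sweep.tsv")
    pd.DataFrame(sweep_rows).to_csv(sweep_path, sep="\t", index=False,
                                    float_format="%.6g")
    outputs["group_matrices"] = matrix_paths
    outputs["threshold_sweep"] = str(sweep_path)

    # --- per-contrast inference -----------------------------------------
    contrast_outputs = {}
    for cond in conditions:
        results = study.contrasts[cond]["results"]
        graph = study.contrasts[cond]["graph"]
        report = study.contrasts[cond]["report"]
        test_path = emit(out_dir / f"edge_tests_{cond}.tsv")
        pd.DataFrame(
            [
                {
                    "edge_i": r.edge[0], "edge_j": r.edge[1],
                    "t": r.t_stat, "p": r.p_perm, "q": r.q_fdr,
                    "d": r.cohens_d, "direction": r.direction,
                }
                for r in results
            ]
        ).to_csv(test_path, sep="\t", index=False, float_format="%.6g")
        report_path = emit(out_dir / f"significant_{cond}.tsv")
        report.to_csv(report_path, sep="\t", index=False, float_format="%.6g")
        metrics_path = emit(out_dir / f"graph_metrics_{cond}.tsv")
        vertex_metrics_table(graph, montage).to_csv(
            metrics_path, sep="\t", index=False, float_format="%.6g"
        )
        summary_path = emit(out_dir / f"graph_summary_{cond}.json")
        summary = graph_summary(graph)
        summary["hemisphere_counts"] = report.attrs["hemisphere_counts"]
        summary_path.write_text(json.dumps(summary, indent=2))
        contrast_outputs[cond] = {
            "edge_tests": str(test_path),
            "significant_edges": str(report_path),
            "graph_metrics": str(metrics_path),
            "graph_summary": str(summary_path),
            "n_significant": int(graph.n_edges),
        }
    outputs["contrasts"] = contrast_outputs

    import scipy

    import micnet

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "versions": {
            "micnet": micnet.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    manifest_path = emit(out_dir / "manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
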