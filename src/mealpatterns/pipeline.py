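"""End-to-end orchestration: diaries in, cluster report out.

Stages run in a fixed order — validate days, build eating occasions,
filter low-protein items, extract series, DTW dissimilarity matrix,
Ward.D2 linkage, cut at k, silhouette scan, classical MDS, cluster
summaries — and each stage's outputs are written so stages can be
re-run or inspected independently.  The whole pipeline is a pure
function of (inputs, config, seed): re-running on identical inputs
produces identical artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as ck
from . import intake, stats
from .composition import read_composition
from .dtw import distance_matrix

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "scan_k"]

log = logging.getLogger("mealpatterns")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PipelineConfig:
    diary_csv: str
    composition_csv: str
    participants_csv: str
    out_dir: str
    k: int = 3
    k_scan_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    thresholds: stats.ThresholdConfig = field(default_factory=stats.ThresholdConfig)
    min_item_protein_g: float = intake.DEFAULT_MIN_ITEM_PROTEIN_G
    filter_after_tid: bool = False
    mds_dims: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")

    def validate_paths(self) -> None:
        for name in ("diary_csv", "composition_csv", "participants_csv"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise PipelineError("config", f"{name} not found: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, t0: float, detail: str) -> None:
    log.info("%-12s %6.2fs  %s", name, time.perf_counter() - t0, detail)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the artifact manifest.

    Artifacts (all CSV/JSON) land under ``cfg.out_dir``; the manifest
    records each with a SHA-256 checksum.  Any stage failure raises
    :class:`PipelineError` naming the stage, after writing a partial
    manifest.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest_path = out / "manifest.json"

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest_path.write_text(
            json.dumps({"status": f"failed at {stage}", "artifacts": artifacts},
                       indent=2)
        )
        return PipelineError(stage, str(exc))

    t0 = time.perf_counter()
    try:
        diary = pd.read_csv(
            cfg.diary_csv, dtype={"participant_id": str, "food_id": str},
            keep_default_na=False, na_values=[],
        )
        composition = read_composition(cfg.composition_csv)
        participants = pd.read_csv(cfg.participants_csv, dtype={"participant_id": str})
    except Exception as exc:  # noqa: BLE001
        raise fail("load", exc) from exc
    _stage("load", t0, f"{len(diary)} diary records, {len(participants)} participants")

    t0 = time.perf_counter()
    try:
        clean, excluded = intake.validate_days(diary)
        excluded.to_csv(out / "excluded_days.csv", index=False)
        record("excluded_days", out / "excluded_days.csv")
    except Exception as exc:  # noqa: BLE001
        raise fail("validate", exc) from exc
    _stage("validate", t0, f"{len(excluded)} individual.days excluded")

    t0 = time.perf_counter()
    try:
        # pre-filter universe for coverage accounting
        _, items_all = intake.build_eos(clean, composition, min_item_protein_g=0.0)
        eos, items = intake.build_eos(
            clean, composition,
            min_item_protein_g=cfg.min_item_protein_g,
            filter_after_tid=cfg.filter_after_tid,
        )
        coverage = intake.coverage_report(items_all, items)
        eos.to_csv(out / "eo_table.csv", index=False)
        record("eo_table", out / "eo_table.csv")
        series = intake.to_series(eos)
        if len(series) < 2:
            raise ValueError(f"only {len(series)} retained series; need >= 2")
        (out / "series_manifest.json").write_text(
            json.dumps(
                {
                    "n_series": len(series),
                    "series_ids": [s.series_id for s in series],
                    "coverage": coverage,
                },
                indent=2,
            )
        )
        record("series_manifest", out / "series_manifest.json")
    except Exception as exc:  # noqa: BLE001
        raise fail("eos", exc) from exc
    _stage("eos", t0, f"{len(eos)} EOs -> {len(series)} series; "
           f"cohort coverage {coverage['cohort_pct']}")

    t0 = time.perf_counter()
    try:
        dm = distance_matrix(series)
        dm.to_csv(out / "distance_matrix.csv")
        record("distance_matrix", out / "distance_matrix.csv")
    except Exception as exc:  # noqa: BLE001
        raise fail("dtw", exc) from exc
    _stage("dtw", t0, f"{dm.n}x{dm.n} normalized DTW matrix")

    t0 = time.perf_counter()
    try:
        model = ck.WardClustering(n_clusters=cfg.k).fit(dm)
        tree = model.linkage_
        tree.to_frame().to_csv(out / "linkage.csv", index=False)
        record("linkage", out / "linkage.csv")
        mean_protein = np.array([s.values.mean() for s in series])
        labels = ck.renumber_by_value(model.labels_, mean_protein)
        labels_df = pd.DataFrame({"series_id": dm.labels, "cluster": labels})
        labels_df.to_csv(out / "labels.csv", index=False)
        record("labels", out / "labels.csv")
    except Exception as exc:  # noqa: BLE001
        raise fail("cluster", exc) from exc
    _stage("cluster", t0,
           f"k={cfg.k}, sizes {np.bincount(labels)[1:].tolist()}")

    t0 = time.perf_counter()
    try:
        k_range = [k for k in cfg.k_scan_range if 2 <= k <= dm.n - 1]
        sil = ck.silhouette_scan(dm, tree, k_range)
        sil.to_csv(out / "silhouette.csv", index=False)
        record("silhouette", out / "silhouette.csv")
    except Exception as exc:  # noqa: BLE001
        raise fail("silhouette", exc) from exc
    _stage("silhouette", t0,
           f"argmax k={int(sil.loc[sil['is_best'], 'k'].iloc[0])}")

    t0 = time.perf_counter()
    try:
        mds = ck.classical_mds(dm, dims=cfg.mds_dims)
        emb = mds.to_frame(dm.labels)
        emb.index.name = "series_id"
        emb.to_csv(out / "embedding.csv")
        record("embedding", out / "embedding.csv")
        (out / "eigenvalues.json").write_text(
            json.dumps(
                {
                    "eigenvalues": mds.eigenvalues.tolist(),
                    "variance_fraction": mds.variance_fraction.tolist(),
                },
                indent=2,
            )
        )
        record("eigenvalues", out / "eigenvalues.json")
    except Exception as exc:  # noqa: BLE001
        raise fail("mds", exc) from exc
    _stage("mds", t0,
           "variance fractions " + str(np.round(mds.variance_fraction, 3).tolist()))

    t0 = time.perf_counter()
    try:
        labels_map = dict(zip(labels_df["series_id"], labels_df["cluster"]))
        report = stats.cluster_summary(
            labels_map, eos, participants, cfg=cfg.thresholds
        )
        report.contribution = stats.foodgroup_contribution(items, labels_map)
        report.hourly = stats.hourly_profile(eos, labels_map)
        report.extras = {
            "coverage": coverage,
            "silhouette_argmax_k": int(sil.loc[sil["is_best"], "k"].iloc[0]),
            "mds_variance_fraction": mds.variance_fraction.tolist(),
            "n_excluded_days": int(len(excluded)),
        }
        for name, path in report.write(out).items():
            record(name, Path(path))
    except Exception as exc:  # noqa: BLE001
        raise fail("summaries", exc) from exc
    _stage("summaries", t0, f"{len(report.summary)} clusters summarised")

    manifest = {
        "status": "ok",
        "config": {
            "k": cfg.k,
            "seed": cfg.seed,
            "min_item_protein_g": cfg.min_item_protein_g,
            "filter_after_tid": cfg.filter_after_tid,
        },
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in artifacts.items()
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def scan_k(cfg: PipelineConfig, k_range: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Silhouette table over a k range without writing the full report."""
    cfg.validate_paths()
    if k_range is not None:
        cfg = replace(cfg, k_scan_range=tuple(k_range))
    diary = pd.read_csv(
        cfg.diary_csv, dtype={"participant_id": str, "food_id": str},
        keep_default_na=False, na_values=[],
    )
    composition = read_composition(cfg.composition_csv)
    clean, _ = intake.validate_days(diary)
    eos, _ = intake.build_eos(
        clean, composition, min_item_protein_g=cfg.min_item_protein_g,
        filter_after_tid=cfg.filter_after_tid,
    )
    series = intake.to_series(eos)
    dm = distance_matrix(series)
    tree = ck.ward_linkage(dm)
    k_values = [k for k in cfg.k_scan_range if 2 <= k <= dm.n - 1]
    return ck.silhouette_scan(dm, tree, k_values)
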