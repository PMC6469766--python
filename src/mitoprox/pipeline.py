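"""Batch driver: manifest in, per-image metrics and group summaries out.

A run is described by a :class:`RunConfig` (manifest CSV + parameters).  For
every manifest row the pipeline reads the image, segments the two channels
(median -> top-hat -> threshold), computes percent overlap and the proximity
index, and appends one row to a tidy results table.  Group summaries report
mean +/- SEM per treatment group.  Hypothesis testing is deliberately left to
downstream statistics packages; the per-image table carries everything they
need.

Every run writes a JSON-lines log recording parameters, realized thresholds
and warnings, so each result row can be reconstructed from its raw image.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import ProximityConfig, SweepResult, percent_overlap, proximity_index, window_size_sweep
from .errors import ConfigurationError
from .io import read_image, read_roi
from .scenes import LabeledScene, SceneConfig, scene_batch, write_scene
from .segmentation import PreprocessParams, ThresholdSpec, segment_pair

__all__ = ["RunConfig", "GroupSummary", "run_batch", "run_synthetic_benchmark", "summarize_groups"]

RESULT_COLUMNS = [
    "image_id",
    "group",
    "k",
    "window_size",
    "common",
    "union",
    "overlap",
    "overlap_percent",
    "n_nonzero_windows",
    "proximity_index",
    "threshold_a",
    "threshold_b",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a batch run.

    The manifest is a CSV with header columns ``image``, ``group``,
    ``channel_a``, ``channel_b`` and optional ``roi`` (blank = whole image).
    """

    manifest: str | Path
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    threshold_a: ThresholdSpec = field(default_factory=ThresholdSpec)
    threshold_b: ThresholdSpec = field(default_factory=ThresholdSpec)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    output_dir: str | Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        manifest = raw["manifest"]
        if not Path(manifest).is_absolute():
            manifest = base / manifest
        return cls(
            manifest=manifest,
            preprocess=PreprocessParams(**raw.get("preprocess", {})),
            threshold_a=ThresholdSpec(**raw.get("threshold_a", {})),
            threshold_b=ThresholdSpec(**raw.get("threshold_b", {})),
            proximity=ProximityConfig(**raw.get("proximity", {})),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean +/- SEM of the two statistics (SEM = sample SD / sqrt(n))."""

    group: str
    n: int
    mean_proximity_index: float
    sem_proximity_index: float
    mean_overlap_percent: float
    sem_overlap_percent: float


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def summarize_groups(results: pd.DataFrame) -> list[GroupSummary]:
    """Mean +/- SEM of proximity index and percent overlap per group."""
    summaries = []
    for group, sub in results.groupby("group", sort=True):
        pi = sub["proximity_index"].to_numpy(dtype=float)
        ov = sub["overlap_percent"].to_numpy(dtype=float)
        summaries.append(
            GroupSummary(
                group=str(group),
                n=len(sub),
                mean_proximity_index=float(pi.mean()),
                sem_proximity_index=_sem(pi),
                mean_overlap_percent=float(ov.mean()),
                sem_overlap_percent=_sem(ov),
            )
        )
    return summaries


class _RunLog:
    def __init__(self, path: Path | None):
        self.path = path
        self.records: list[dict] = []

    def write(self, **record) -> None:
        self.records.append(record)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(record, default=str) + "\n")


def _measure_pair(mask_a, mask_b, proximity_cfg: ProximityConfig) -> dict:
    ov = percent_overlap(mask_a, mask_b)
    prox = proximity_index(mask_a, mask_b, proximity_cfg)
    return {
        "k": proximity_cfg.k,
        "window_size": proximity_cfg.window_size,
        "common": ov.common,
        "union": ov.union,
        "overlap": ov.overlap,
        "overlap_percent": ov.overlap_percent,
        "n_nonzero_windows": prox.n_nonzero_windows,
        "proximity_index": prox.proximity_index,
    }


def run_batch(config: RunConfig) -> tuple[pd.DataFrame, list[GroupSummary]]:
    """Run the full pipeline over a manifest; returns (results, summaries).

    Per-image failures are logged and skipped; the run fails outright only on
    an unusable manifest.  If ``output_dir`` is set, writes ``results.csv``,
    ``summaries.csv`` and ``run.log.jsonl`` there.
    """
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise ConfigurationError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, dtype=str)
    required = {"image", "group", "channel_a", "channel_b"}
    if manifest.empty:
        raise ConfigurationError("manifest has no rows")
    if not required.issubset(manifest.columns):
        raise ConfigurationError(f"manifest must have columns {sorted(required)}")

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run.log.jsonl" if out_dir else None)
    log.write(
        event="run_start",
        version=__version__,
        seed=config.seed,
        preprocess=asdict(config.preprocess),
        threshold_a=asdict(config.threshold_a),
        threshold_b=asdict(config.threshold_b),
        proximity=asdict(config.proximity),
        n_images=len(manifest),
    )

    rows, n_failed = [], 0
    for i, row in manifest.iterrows():
        image_id = Path(row["image"]).stem
        try:
            img_path = Path(row["image"])
            if not img_path.is_absolute():
                img_path = manifest_path.parent / img_path
            img = read_image(img_path)
            roi = None
            if "roi" in manifest.columns and isinstance(row.get("roi"), str) and row["roi"].strip():
                roi_path = Path(row["roi"])
                if not roi_path.is_absolute():
                    roi_path = manifest_path.parent / roi_path
                roi = read_roi(roi_path)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                mask_a, mask_b = segment_pair(
                    img,
                    row["channel_a"],
                    row["channel_b"],
                    config.preprocess,
                    config.threshold_a,
                    config.threshold_b,
                    roi=roi,
                )
                record = _measure_pair(mask_a, mask_b, config.proximity)
            for wmsg in caught:
                log.write(event="warning", image_id=image_id, message=str(wmsg.message))
            record.update(
                image_id=image_id,
                group=row["group"],
                threshold_a=mask_a.threshold,
                threshold_b=mask_b.threshold,
            )
            rows.append(record)
            log.write(event="image_done", **record)
        except Exception as exc:
            n_failed += 1
            log.write(event="image_failed", image_id=image_id, error=str(exc))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    summaries = summarize_groups(results) if not results.empty else []
    log.write(event="run_end", n_done=len(rows), n_failed=n_failed)
    if out_dir:
        results.to_csv(out_dir / "results.csv", index=False)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(out_dir / "summaries.csv", index=False)
    return results, summaries


def _benchmark_scenes(base_seed: int, n_per_group: int) -> list[LabeledScene]:
    coloc = SceneConfig(protein_mode="mito_colocalized", coloc_fraction=1.0, displacement=0)
    membrane = SceneConfig(protein_mode="membrane")
    configs = [coloc] * n_per_group + [membrane] * n_per_group
    labels = ["colocalized"] * n_per_group + ["membrane"] * n_per_group
    return scene_batch(configs, labels, base_seed=base_seed)


def run_synthetic_benchmark(
    base_seed: int = 0,
    n_per_group: int = 10,
    out_dir: str | Path | None = None,
    k_range: range | None = None,
    preprocess: PreprocessParams | None = None,
) -> tuple[pd.DataFrame, list[GroupSummary], SweepResult]:
    """Full pipeline on matched synthetic groups plus the window-size sweep.

    Generates ``n_per_group`` fully colocalized scenes and ``n_per_group``
    membrane-localized control scenes, segments each rendered image
    (median -> top-hat -> Otsu), measures both statistics at the default
    64-px window, and sweeps window exponents k (default 2..8, the full
    range a 256-px scene can hold) to select the most discriminating window
    size.
    """
    if n_per_group < 2:
        raise ConfigurationError("need at least 2 scenes per group")
    scenes = _benchmark_scenes(base_seed, n_per_group)
    preprocess = preprocess or PreprocessParams()
    prox_cfg = ProximityConfig()

    rows = []
    grouped_masks: dict[str, list[tuple]] = {}
    for ls in scenes:
        mask_a, mask_b = segment_pair(ls.scene.image, "mito", "protein", preprocess)
        record = _measure_pair(mask_a, mask_b, prox_cfg)
        record.update(
            image_id=ls.scene_id,
            group=ls.label,
            threshold_a=mask_a.threshold,
            threshold_b=mask_b.threshold,
        )
        rows.append(record)
        grouped_masks.setdefault(ls.label, []).append((mask_a, mask_b))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    summaries = summarize_groups(results)
    if k_range is None:
        side = min(scenes[0].scene.image.height, scenes[0].scene.image.width)
        k_range = range(2, min(10, int(math.log2(side))) + 1)
    sweep = window_size_sweep(grouped_masks, k_range=k_range)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(out_dir / "summaries.csv", index=False)
        sweep_table = sweep.per_k_group_means.copy()
        sweep_table["separation"] = sweep.separation
        sweep_table["selected"] = sweep_table.index == sweep.selected_k
        sweep_table.to_csv(out_dir / "sweep.csv")
        for ls in scenes:
            write_scene(ls.scene, out_dir / "scenes", stem=ls.scene_id)
    return results, summaries, sweep
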