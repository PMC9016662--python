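"""Heatmaps, time-series exports and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .io import (ConfigurationError, GazeDataset, GroupAssignment,
                 apply_validity_rules, downsample_to_frames, read_gaze_long)
from .framewise import (DEFAULT_ALPHA, DEFAULT_MIN_N, FrameStat, detect_runs,
                        group_stats_by_video, stats_table, summarize_all,
                        video_framewise_stats)
from .selection import DEFAULT_THRESHOLD_PCT, SelectionRegime
from .validate import MODEL_KINDS, repeat_experiment

logger = logging.getLogger(__name__)


@dataclass
class HeatmapGrid:
    """Normalised gaze density of one group over one video."""

    values: np.ndarray  # (h_bins, w_bins), sums to 1 when any point contributed
    video_id: str
    group_tag: str
    sigma: float
    screen: tuple[float, float]
    empty: bool = False


def gaze_heatmap(dataset: GazeDataset, video_id: str,
                 participants: Sequence[str] | None = None,
                 sigma: float = 40.0, grid: tuple[int, int] = (160, 112),
                 group_tag: str = "", frame_range: tuple[int, int] | None = None
                 ) -> HeatmapGrid:
    """Gaussian kernel density of valid gaze points on a regular grid.

    Every valid gaze point of the listed participants over the video's frames
    (optionally restricted to ``frame_range``, inclusive) contributes an
    isotropic Gaussian kernel of sd ``sigma`` px; the grid is normalised to
    total mass 1.  Zero valid points yield an all-zero grid flagged ``empty``.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    w_bins, h_bins = grid
    w, h = dataset.screen
    vi = dataset.video_index(video_id)
    idx = (dataset.participant_index(participants)
           if participants is not None else slice(None))
    pos = dataset.positions[idx, vi]
    val = dataset.validity[idx, vi]
    if frame_range is not None:
        lo, hi = frame_range
        sel = np.zeros(pos.shape[1], dtype=bool)
        sel[lo:hi + 1] = True
        val = val & sel[None, :]
    pts = pos[val]
    if pts.shape[0] == 0:
        logger.warning("heatmap %s/%s: zero valid gaze points", video_id,
                       group_tag or "all")
        return HeatmapGrid(np.zeros((h_bins, w_bins)), video_id, group_tag,
                           sigma, (w, h), empty=True)
    hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(h_bins, w_bins),
                                range=[[0, h], [0, w]])
    sigma_bins = (sigma / (h / h_bins), sigma / (w / w_bins))
    dens = ndimage.gaussian_filter(hist, sigma=sigma_bins, mode="constant")
    total = dens.sum()
    if total > 0:
        dens = dens / total
    return HeatmapGrid(dens, video_id, group_tag, sigma, (w, h))


def distance_timeseries(stats: Sequence[FrameStat]) -> pd.DataFrame:
    """Per-frame distance-method trace: one row per frame, untestable frames
    carry empty stat fields."""
    rows = []
    for s in stats:
        if s.method != "distance":
            raise ConfigurationError("distance_timeseries needs distance-method "
                                     "stats")
        rows.append({
            "video": s.video_id, "frame": s.frame,
            "mean_dist_a": np.nan if s.mean_dist_a is None else s.mean_dist_a,
            "mean_dist_b": np.nan if s.mean_dist_b is None else s.mean_dist_b,
            "p": s.p if s.testable else np.nan,
            "sign": s.sign if s.testable else "",
        })
    return pd.DataFrame(
        rows, columns=["video", "frame", "mean_dist_a", "mean_dist_b", "p",
                       "sign"])


@dataclass
class RunConfig:
    """Full configuration of an end-to-end analysis run."""

    gaze_path: str
    groups_path: str
    output_dir: str
    analysis_fps: float = 30.0
    source_rate: float = 60.0
    screen: tuple[float, float] = (1280.0, 900.0)
    method: str = "distance"
    alpha: float = DEFAULT_ALPHA
    near_alpha: float = 0.10
    min_n: int = DEFAULT_MIN_N
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    regimes: tuple[str, ...] = tuple(r.value for r in SelectionRegime)
    models: tuple[str, ...] = MODEL_KINDS
    n_repetitions: int = 18
    base_seed: int = 0
    test_fraction: float = 0.2
    feature_mode: str = "leak_free_two_centres"
    heatmap_sigma: float = 40.0
    heatmap_top_k: int = 4
    write_heatmap_png: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or self.near_alpha < self.alpha:
            raise ConfigurationError("need 0 < alpha <= near_alpha < 1")
        for p in (self.gaze_path, self.groups_path):
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        for key in ("screen", "regimes", "models"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the output dir.

    Stages: ingest → downsample → validity rules → framewise stats →
    summaries and runs → repeated validation → heatmaps of the top-k videos
    by percent significant frames.  A manifest (config, versions, outputs)
    is written last; on failure a FAILED marker names the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stage = "ingest"
    try:
        dataset = read_gaze_long(config.gaze_path, source_rate=config.source_rate,
                                 screen=config.screen)
        groups = GroupAssignment.from_table(config.groups_path)
        stage = "downsample"
        if dataset.fps != config.analysis_fps:
            dataset = downsample_to_frames(dataset, config.analysis_fps)
        stage = "validity"
        dataset = apply_validity_rules(dataset)
        logger.info("run: %d participants, %d videos, %d frames max, "
                    "%.1f%% valid", dataset.n_participants, dataset.n_videos,
                    dataset.positions.shape[2],
                    100 * dataset.validity.mean() if dataset.validity.size else 0)

        stage = "framewise_stats"
        stats = video_framewise_stats(dataset, groups, method=config.method,
                                      min_n=config.min_n, alpha=config.alpha)
        table = stats_table(stats)
        table.to_csv(out / "frame_stats.csv", index=False)
        written.append("frame_stats.csv")

        stage = "summaries"
        summaries = summarize_all(stats, config.alpha)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(
            out / "video_summaries.csv", index=False)
        written.append("video_summaries.csv")

        run_rows = []
        for vid, vstats in group_stats_by_video(stats).items():
            for seg in detect_runs(vstats, config.alpha, config.near_alpha):
                run_rows.append({"video": seg.video_id,
                                 "start_frame": seg.start_frame,
                                 "end_frame": seg.end_frame,
                                 "sign": seg.sign, "n_frames": seg.n_frames})
        pd.DataFrame(run_rows, columns=["video", "start_frame", "end_frame",
                                        "sign", "n_frames"]).to_csv(
            out / "runs.csv", index=False)
        written.append("runs.csv")

        if config.method == "distance":
            distance_timeseries(stats).to_csv(out / "distance_timeseries.csv",
                                              index=False)
            written.append("distance_timeseries.csv")

        stage = "validation"
        report = repeat_experiment(
            dataset, groups, regimes=list(config.regimes),
            models=list(config.models), n_repetitions=config.n_repetitions,
            base_seed=config.base_seed, method=config.method,
            alpha=config.alpha, min_n=config.min_n,
            threshold_pct=config.threshold_pct,
            test_fraction=config.test_fraction,
            feature_mode=config.feature_mode)
        report.rows.to_csv(out / "evaluation_rows.csv", index=False)
        written.append("evaluation_rows.csv")
        (out / "evaluation_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=float))
        written.append("evaluation_report.json")

        stage = "heatmaps"
        top = sorted(summaries, key=lambda s: s.pct_significant,
                     reverse=True)[:config.heatmap_top_k]
        for summ in top:
            for tag, label in (("group_a", GroupAssignment.GROUP_A),
                               ("group_b", GroupAssignment.GROUP_B)):
                hm = gaze_heatmap(dataset, summ.video_id,
                                  participants=groups.members(label),
                                  sigma=config.heatmap_sigma, group_tag=tag)
                name = f"heatmap_{summ.video_id}_{tag}"
                np.savetxt(out / f"{name}.csv", hm.values, delimiter=",")
                written.append(f"{name}.csv")
                if config.write_heatmap_png:
                    _save_heatmap_png(hm, out / f"{name}.png")
                    written.append(f"{name}.png")

        stage = "manifest"
        manifest = {
            "package": "gazediff", "version": __version__,
            "library_versions": _library_versions(),
            "config": asdict(config),
            "chance_level": report.chance_level,
            "n_participants": dataset.n_participants,
            "n_videos": dataset.n_videos,
            "outputs": written,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _save_heatmap_png(hm: HeatmapGrid, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * hm.screen[1] / hm.screen[0]))
    ax.imshow(hm.values, extent=(0, hm.screen[0], hm.screen[1], 0),
              cmap="inferno", aspect="equal")
    ax.set_title(f"{hm.video_id} {hm.group_tag}".strip())
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__}
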