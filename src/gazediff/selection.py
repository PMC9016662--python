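"""Training-derived frame/video selection and the classification feature table.

Selection of informative material happens strictly on the training
participants: videos whose percent of 'significant' frames exceeds a
threshold (10% by default), and frames whose per-frame test is significant.
Four regimes combine the two choices.  The feature table then holds, per
participant and per included video, the mean distance of that participant's
gaze to the *training* group centres over the included, valid frames.

Two feature modes exist.  The default ``leak_free_two_centres`` mode emits two
features per video — distance to the training group-A centre and to the
training group-B centre — computed identically for training and test rows, so
no group label of a test participant is needed (or leaked) at prediction
time.  The ``paper_faithful_own_centre`` mode reproduces the single
distance-to-own-group-centre feature of the original analysis; it requires
labels for every row and is meant for reproduction only.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import ConfigurationError, GazeDataset, GroupAssignment
from .framewise import (DEFAULT_ALPHA, DEFAULT_MIN_N, FrameStat, VideoSummary,
                        group_stats_by_video)

logger = logging.getLogger(__name__)


class SelectionRegime(str, enum.Enum):
    """Which material enters the per-participant features."""

    ALL_FRAMES_ALL_VIDEOS = "all_frames_all_videos"
    ALL_FRAMES_SELECTED_VIDEOS = "all_frames_selected_videos"
    SELECTED_FRAMES_ALL_VIDEOS = "selected_frames_all_videos"
    SELECTED_FRAMES_SELECTED_VIDEOS = "selected_frames_selected_videos"

    @property
    def selects_videos(self) -> bool:
        return self in (SelectionRegime.ALL_FRAMES_SELECTED_VIDEOS,
                        SelectionRegime.SELECTED_FRAMES_SELECTED_VIDEOS)

    @property
    def selects_frames(self) -> bool:
        return self in (SelectionRegime.SELECTED_FRAMES_ALL_VIDEOS,
                        SelectionRegime.SELECTED_FRAMES_SELECTED_VIDEOS)


DEFAULT_THRESHOLD_PCT = 10.0

FeatureMode = Literal["leak_free_two_centres", "paper_faithful_own_centre"]


@dataclass
class SelectionMask:
    """Training-derived inclusion flags for videos and frames."""

    video_included: dict[str, bool]
    frame_included: dict[str, np.ndarray]  # video_id -> bool array over frames
    derived_from: frozenset[str]
    threshold_pct: float
    alpha: float
    regime: SelectionRegime

    def included_videos(self) -> list[str]:
        return [v for v, ok in self.video_included.items() if ok]

    def to_dict(self) -> dict:
        return {
            "regime": self.regime.value,
            "threshold_pct": self.threshold_pct,
            "alpha": self.alpha,
            "derived_from": sorted(self.derived_from),
            "video_included": self.video_included,
            "frame_included": {v: np.nonzero(m)[0].tolist()
                               for v, m in self.frame_included.items()},
        }


@dataclass
class FeatureTable:
    """Per-participant per-video mean distance-to-centre features.

    ``values`` is a participants × columns DataFrame; column names are
    ``"<video>|centre_a"`` / ``"<video>|centre_b"`` (default mode) or
    ``"<video>|own_centre"`` (paper-faithful mode).  ``imputed`` flags cells
    that had zero usable frames and were filled with the training-column mean.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    mode: str
    mask: SelectionMask

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self, participants: Sequence[str]) -> np.ndarray:
        return self.values.loc[list(participants)].to_numpy(float)


def select_videos(summaries: Sequence[VideoSummary],
                  threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> set[str]:
    """Videos whose percent of 'significant' frames strictly exceeds the
    threshold (training-set summaries only)."""
    if not summaries:
        raise ConfigurationError("select_videos: empty summary list")
    return {s.video_id for s in summaries if s.pct_significant > threshold_pct}


def select_frames(stats: Iterable[FrameStat],
                  alpha: float = DEFAULT_ALPHA) -> dict[str, np.ndarray]:
    """Per-video boolean masks: True where testable and p < alpha."""
    masks: dict[str, np.ndarray] = {}
    for vid, vstats in group_stats_by_video(stats).items():
        n = max(s.frame for s in vstats) + 1
        m = np.zeros(n, dtype=bool)
        for s in vstats:
            if s.testable and s.p < alpha:
                m[s.frame] = True
        masks[vid] = m
    return masks


def build_selection_mask(stats: Sequence[FrameStat],
                         summaries: Sequence[VideoSummary],
                         regime: SelectionRegime,
                         train_ids: Iterable[str],
                         threshold_pct: float = DEFAULT_THRESHOLD_PCT,
                         alpha: float = DEFAULT_ALPHA) -> SelectionMask:
    """Compose video and frame inclusion for a regime from training-set stats.

    Falls back to all videos (with a warning) when no video clears the
    threshold, so downstream models never see an empty feature set.
    """
    regime = SelectionRegime(regime)
    by_video = group_stats_by_video(stats)
    all_videos = list(by_video)

    if regime.selects_videos:
        chosen = select_videos(summaries, threshold_pct)
        if not chosen:
            logger.warning("no video exceeds the %.1f%% threshold; "
                           "falling back to all videos", threshold_pct)
            chosen = set(all_videos)
    else:
        chosen = set(all_videos)
    video_included = {v: v in chosen for v in all_videos}

    if regime.selects_frames:
        frame_included = select_frames(stats, alpha)
    else:
        frame_included = {v: np.ones(max(s.frame for s in by_video[v]) + 1, bool)
                          for v in all_videos}
    for v, ok in video_included.items():
        if not ok:
            frame_included[v] = np.zeros_like(frame_included[v])

    return SelectionMask(video_included=video_included,
                         frame_included=frame_included,
                         derived_from=frozenset(train_ids),
                         threshold_pct=threshold_pct, alpha=alpha, regime=regime)


def _training_centres(dataset: GazeDataset, groups_train: GroupAssignment,
                      min_n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame group centres from training participants only.

    Returns (centre_a, centre_b, defined) with centres of shape
    (V, Fmax, 2) and ``defined`` a (V, Fmax) bool mask true where both groups
    have >= min_n valid training samples.
    """
    pos = dataset.masked_positions()
    ia = dataset.participant_index(groups_train.members(GroupAssignment.GROUP_A))
    ib = dataset.participant_index(groups_train.members(GroupAssignment.GROUP_B))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centre_a = np.nanmean(pos[ia], axis=0)
        centre_b = np.nanmean(pos[ib], axis=0)
    n_a = dataset.validity[ia].sum(axis=0)
    n_b = dataset.validity[ib].sum(axis=0)
    defined = (n_a >= min_n) & (n_b >= min_n)
    return centre_a, centre_b, defined


def build_feature_table(dataset: GazeDataset, groups_train: GroupAssignment,
                        all_participants: Sequence[str], mask: SelectionMask,
                        mode: FeatureMode = "leak_free_two_centres",
                        min_n: int = DEFAULT_MIN_N,
                        groups_all: GroupAssignment | None = None) -> FeatureTable:
    """Mean distance-to-training-centre features for every participant.

    For each participant (training or test) and each included video, features
    average the per-frame Euclidean distance from the participant's gaze to
    the training group centres over the frames that are (a) included by the
    mask, (b) valid for the participant, and (c) have defined training centres
    (both groups >= ``min_n`` valid training samples).  Cells with zero usable
    frames are imputed with the training-column mean and flagged.

    ``paper_faithful_own_centre`` mode needs ``groups_all`` labels for every
    row and emits a single distance-to-own-group-centre feature per video.
    """
    if mode not in ("leak_free_two_centres", "paper_faithful_own_centre"):
        raise ConfigurationError(f"unknown feature mode {mode!r}")
    faithful = mode == "paper_faithful_own_centre"
    if faithful:
        if groups_all is None:
            raise ConfigurationError(
                "paper_faithful_own_centre mode requires groups_all labels "
                "for every participant")
        missing = set(all_participants) - set(groups_all.labels)
        if missing:
            raise ConfigurationError(
                f"paper_faithful mode: participants without labels: "
                f"{sorted(missing)}")

    centre_a, centre_b, defined = _training_centres(dataset, groups_train, min_n)
    pos = dataset.masked_positions()
    rows = list(all_participants)
    ridx = dataset.participant_index(rows)
    train_rows = [p for p in rows if p in mask.derived_from]

    dist_a = np.linalg.norm(pos[ridx] - centre_a[None], axis=3)  # (R, V, Fmax)
    dist_b = np.linalg.norm(pos[ridx] - centre_b[None], axis=3)

    values: dict[str, np.ndarray] = {}
    imputed: dict[str, np.ndarray] = {}
    n_rows = len(rows)

    for vi, vid in enumerate(dataset.video_ids):
        if not mask.video_included.get(vid, False):
            continue
        fmask = np.zeros(dataset.positions.shape[2], dtype=bool)
        incl = mask.frame_included.get(vid)
        if incl is not None:
            fmask[:len(incl)] = incl
        fmask &= defined[vi]
        usable = fmask[None, :] & dataset.validity[ridx, vi]  # (R, Fmax)
        if not fmask.any():
            logger.warning("video %s: zero included frames under regime %s; "
                           "column dropped", vid, mask.regime.value)
            continue

        def _mean_dist(dist_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            cnt = usable.sum(axis=1)
            s = np.where(usable, dist_v, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                m = s / cnt
            return m, cnt == 0

        if faithful:
            own_b = np.array([groups_all.labels[p] == GroupAssignment.GROUP_B
                              for p in rows])
            d_own = np.where(own_b[:, None], dist_b[:, vi], dist_a[:, vi])
            m, empty = _mean_dist(d_own)
            values[f"{vid}|own_centre"] = m
            imputed[f"{vid}|own_centre"] = empty
        else:
            for tag, dist_v in (("centre_a", dist_a[:, vi]),
                                ("centre_b", dist_b[:, vi])):
                m, empty = _mean_dist(dist_v)
                values[f"{vid}|{tag}"] = m
                imputed[f"{vid}|{tag}"] = empty

    if not values:
        raise ConfigurationError("no feature columns survive the selection mask")

    vals = pd.DataFrame(values, index=rows)
    flags = pd.DataFrame(imputed, index=rows)

    # impute empty cells with the training-column mean
    train_vals = vals.loc[train_rows]
    col_means = train_vals.mean(axis=0, skipna=True)
    col_means = col_means.fillna(vals.mean(axis=0, skipna=True)).fillna(0.0)
    for col in vals.columns:
        bad = flags[col].to_numpy()
        if bad.any():
            vals.loc[bad, col] = col_means[col]
    n_imputed = int(flags.to_numpy().sum())
    if n_imputed:
        logger.info("feature table: imputed %d cells with training means",
                    n_imputed)

    return FeatureTable(values=vals, imputed=flags, mode=mode, mask=mask)
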