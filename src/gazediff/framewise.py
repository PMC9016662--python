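"""Per-frame group-divergence statistics.

For every video frame the gaze positions of two participant groups are
compared with an (uncorrected, exploratory) two-sided Student t-test.  Two
variants exist:

* **distance method** — each participant's Euclidean distance to their own
  group's centre (per-frame arithmetic mean of the group's valid positions)
  is computed, and the two distance samples are compared; this indexes
  differential within-group dispersion.
* **position method** — the raw horizontal or vertical gaze coordinates are
  compared, indexing central-tendency differences.

Per-video summaries (percent "significant" frames, direction shares) and
run-length detection of consecutive divergent frames complete the module.
The per-frame p values are exploratory markers: with thousands of frames and
no multiplicity correction they say nothing about confirmatory significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .io import ConfigurationError, GazeDataset, GroupAssignment

Method = Literal["distance", "horizontal", "vertical"]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_N = 3

SIGN_A = "a_larger"
SIGN_B = "b_larger"
SIGN_TIE = "tie"


@dataclass
class FrameStat:
    """Result of one per-frame two-group test."""

    video_id: str
    frame: int
    method: str
    n_a: int
    n_b: int
    centre_a: tuple[float, float] | None
    centre_b: tuple[float, float] | None
    mean_dist_a: float | None
    mean_dist_b: float | None
    t: float
    p: float
    sign: str
    testable: bool

    def significant(self, alpha: float = DEFAULT_ALPHA) -> bool:
        return bool(self.testable and self.p < alpha)


@dataclass
class VideoSummary:
    """Per-video roll-up of frame statistics."""

    video_id: str
    method: str
    pct_significant: float
    direction_share_a: float
    n_testable: int


@dataclass
class RunSegment:
    """Maximal run of consecutive divergent frames sharing one sign."""

    video_id: str
    start_frame: int
    end_frame: int
    sign: str

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


class EmptyGroupError(ValueError):
    """No valid points available where at least one was required."""


def group_centre(points: Sequence[tuple[float, float]] | np.ndarray
                 ) -> tuple[float, float]:
    """Arithmetic mean of valid gaze points, per coordinate."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise EmptyGroupError("group centre of zero valid points")
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


def pooled_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Classic two-sample pooled-variance Student t, two-sided p.

    ``t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b))`` with
    ``df = n_a + n_b - 2``.  Undefined (NaN, NaN) when the pooled variance is
    zero or either sample has fewer than two values.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        return float("nan"), float("nan")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        return float("nan"), float("nan")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * _sstats.t.sf(abs(t), df)
    return float(t), float(p)


def _sign_of(mean_a: float, mean_b: float) -> str:
    if np.isnan(mean_a) or np.isnan(mean_b) or mean_a == mean_b:
        return SIGN_TIE
    return SIGN_A if mean_a > mean_b else SIGN_B


def _untestable(video_id: str, frame: int, method: str, n_a: int, n_b: int,
                centre_a=None, centre_b=None, mda=None, mdb=None) -> FrameStat:
    return FrameStat(video_id, frame, method, n_a, n_b, centre_a, centre_b,
                     mda, mdb, float("nan"), float("nan"), SIGN_TIE, False)


def distance_test_frame(points_a, points_b, min_n: int = DEFAULT_MIN_N,
                        alpha: float = DEFAULT_ALPHA, video_id: str = "",
                        frame: int = 0) -> FrameStat:
    """Distance-to-own-group-centre test for a single frame.

    Each group's centre is the mean of its own valid points (each member
    included); each member's Euclidean distance to that centre forms the two
    samples compared by the pooled t-test.  Degenerate inputs (too few valid
    points, zero variance in both groups) yield ``testable=False`` instead of
    raising.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < min_n or n_b < min_n:
        return _untestable(video_id, frame, "distance", n_a, n_b)
    c_a, c_b = group_centre(a), group_centre(b)
    d_a = np.linalg.norm(a - c_a, axis=1)
    d_b = np.linalg.norm(b - c_b, axis=1)
    mda, mdb = float(d_a.mean()), float(d_b.mean())
    t, p = pooled_t(d_a, d_b)
    if np.isnan(t):
        return _untestable(video_id, frame, "distance", n_a, n_b, c_a, c_b, mda, mdb)
    return FrameStat(video_id, frame, "distance", n_a, n_b, c_a, c_b,
                     mda, mdb, t, p, _sign_of(mda, mdb), True)


def position_test_frame(points_a, points_b, axis: Literal["horizontal", "vertical"],
                        min_n: int = DEFAULT_MIN_N, alpha: float = DEFAULT_ALPHA,
                        video_id: str = "", frame: int = 0) -> FrameStat:
    """Central-tendency test on one gaze coordinate for a single frame."""
    if axis not in ("horizontal", "vertical"):
        raise ConfigurationError(f"unknown axis {axis!r}")
    dim = 0 if axis == "horizontal" else 1
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < min_n or n_b < min_n:
        return _untestable(video_id, frame, axis, n_a, n_b)
    c_a, c_b = group_centre(a), group_centre(b)
    t, p = pooled_t(a[:, dim], b[:, dim])
    if np.isnan(t):
        return _untestable(video_id, frame, axis, n_a, n_b, c_a, c_b)
    return FrameStat(video_id, frame, axis, n_a, n_b, c_a, c_b, None, None,
                     t, p, _sign_of(float(a[:, dim].mean()), float(b[:, dim].mean())),
                     True)


# ---------------------------------------------------------------------------
# vectorised whole-dataset computation


def _nan_mean_var_n(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware per-column mean, ddof-1 variance and count (participants on
    axis 0)."""
    n = np.sum(np.isfinite(x), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=0)
        var = np.nanvar(x, axis=0, ddof=1)
    return mean, var, n


def _framewise_arrays(dataset: GazeDataset, groups: GroupAssignment,
                      method: Method, min_n: int) -> dict[str, np.ndarray]:
    """Vectorised per-frame statistics over the whole dataset.

    Returns arrays of shape (n_videos, n_frames_max); frames beyond a video's
    length come out untestable.
    """
    ids_a = [p for p in dataset.participant_ids
             if groups.labels.get(p) == GroupAssignment.GROUP_A]
    ids_b = [p for p in dataset.participant_ids
             if groups.labels.get(p) == GroupAssignment.GROUP_B]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ConfigurationError("each group needs >= 2 participants in the dataset")
    ia = dataset.participant_index(ids_a)
    ib = dataset.participant_index(ids_b)

    pos = dataset.masked_positions()  # NaN where invalid
    pa, pb = pos[ia], pos[ib]  # (n_a, V, F, 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centre_a = np.nanmean(pa, axis=0)  # (V, F, 2)
        centre_b = np.nanmean(pb, axis=0)

    out: dict[str, np.ndarray] = {"centre_a": centre_a, "centre_b": centre_b}

    if method == "distance":
        d_a = np.linalg.norm(pa - centre_a[None], axis=3)  # (n_a, V, F)
        d_b = np.linalg.norm(pb - centre_b[None], axis=3)
        mean_a, var_a, n_a = _nan_mean_var_n(d_a)
        mean_b, var_b, n_b = _nan_mean_var_n(d_b)
        out["mean_dist_a"], out["mean_dist_b"] = mean_a, mean_b
    elif method in ("horizontal", "vertical"):
        dim = 0 if method == "horizontal" else 1
        mean_a, var_a, n_a = _nan_mean_var_n(pa[..., dim])
        mean_b, var_b, n_b = _nan_mean_var_n(pb[..., dim])
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    df = n_a + n_b - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
    testable = (n_a >= max(min_n, 2)) & (n_b >= max(min_n, 2)) & (sp2 > 0) \
        & np.isfinite(t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * _sstats.t.sf(np.abs(t), np.maximum(df, 1.0))
    t = np.where(testable, t, np.nan)
    p = np.where(testable, p, np.nan)
    sign = np.where(mean_a > mean_b, 1, np.where(mean_a < mean_b, -1, 0))
    sign = np.where(np.isfinite(mean_a) & np.isfinite(mean_b), sign, 0)

    out.update(t=t, p=p, n_a=n_a.astype(int), n_b=n_b.astype(int),
               sign=sign, testable=testable)
    return out


_SIGN_NAME = {1: SIGN_A, -1: SIGN_B, 0: SIGN_TIE}


def video_framewise_stats(dataset: GazeDataset, groups: GroupAssignment,
                          method: Method = "distance",
                          min_n: int = DEFAULT_MIN_N,
                          alpha: float = DEFAULT_ALPHA) -> list[FrameStat]:
    """One :class:`FrameStat` per frame per video, ordered by (video, frame).

    Only participants with a valid sample at a frame enter that frame's test;
    frames where either group has fewer than ``min_n`` valid participants (or
    where pooled variance vanishes) are marked untestable.
    """
    arr = _framewise_arrays(dataset, groups, method, min_n)
    stats: list[FrameStat] = []
    is_distance = method == "distance"
    for vi, vid in enumerate(dataset.video_ids):
        nf = int(dataset.n_frames[vi])
        for f in range(nf):
            testable = bool(arr["testable"][vi, f])
            ca = arr["centre_a"][vi, f]
            cb = arr["centre_b"][vi, f]
            stats.append(FrameStat(
                video_id=vid, frame=f, method=method,
                n_a=int(arr["n_a"][vi, f]), n_b=int(arr["n_b"][vi, f]),
                centre_a=(float(ca[0]), float(ca[1])) if np.isfinite(ca).all() else None,
                centre_b=(float(cb[0]), float(cb[1])) if np.isfinite(cb).all() else None,
                mean_dist_a=float(arr["mean_dist_a"][vi, f]) if is_distance else None,
                mean_dist_b=float(arr["mean_dist_b"][vi, f]) if is_distance else None,
                t=float(arr["t"][vi, f]), p=float(arr["p"][vi, f]),
                sign=_SIGN_NAME[int(arr["sign"][vi, f])] if testable else SIGN_TIE,
                testable=testable))
    return stats


def stats_table(stats: Iterable[FrameStat]) -> pd.DataFrame:
    """Flat table of frame statistics (one row per frame)."""
    rows = []
    for s in stats:
        rows.append({
            "video": s.video_id, "frame": s.frame, "method": s.method,
            "n_a": s.n_a, "n_b": s.n_b,
            "centre_a_x": s.centre_a[0] if s.centre_a else np.nan,
            "centre_a_y": s.centre_a[1] if s.centre_a else np.nan,
            "centre_b_x": s.centre_b[0] if s.centre_b else np.nan,
            "centre_b_y": s.centre_b[1] if s.centre_b else np.nan,
            "mean_dist_a": np.nan if s.mean_dist_a is None else s.mean_dist_a,
            "mean_dist_b": np.nan if s.mean_dist_b is None else s.mean_dist_b,
            "t": s.t, "p": s.p, "sign": s.sign, "testable": s.testable,
        })
    return pd.DataFrame(rows)


def group_stats_by_video(stats: Iterable[FrameStat]) -> dict[str, list[FrameStat]]:
    """Split a flat stat list into per-video lists (insertion order kept)."""
    by_video: dict[str, list[FrameStat]] = {}
    for s in stats:
        by_video.setdefault(s.video_id, []).append(s)
    return by_video


class UnsummarizableVideoError(ValueError):
    """A video with zero testable frames cannot be summarised."""


def summarize_video(stats: Sequence[FrameStat],
                    alpha: float = DEFAULT_ALPHA) -> VideoSummary:
    """Percent 'significant' frames and direction share for one video."""
    stats = list(stats)
    if not stats:
        raise UnsummarizableVideoError("no frame statistics supplied")
    vid = stats[0].video_id
    method = stats[0].method
    testable = [s for s in stats if s.testable]
    if not testable:
        raise UnsummarizableVideoError(f"video {vid}: zero testable frames")
    n_sig = sum(1 for s in testable if s.p < alpha)
    n_a_larger = sum(1 for s in testable if s.sign == SIGN_A)
    return VideoSummary(
        video_id=vid, method=method,
        pct_significant=100.0 * n_sig / len(testable),
        direction_share_a=n_a_larger / len(testable),
        n_testable=len(testable))


def summarize_all(stats: Iterable[FrameStat],
                  alpha: float = DEFAULT_ALPHA) -> list[VideoSummary]:
    """Per-video summaries for a whole-dataset stat list (skips videos with
    zero testable frames)."""
    out = []
    for vid, vstats in group_stats_by_video(stats).items():
        try:
            out.append(summarize_video(vstats, alpha))
        except UnsummarizableVideoError:
            continue
    return out


def detect_runs(stats: Sequence[FrameStat], alpha: float = DEFAULT_ALPHA,
                near_alpha: float = 0.10) -> list[RunSegment]:
    """Maximal runs of consecutive divergent frames for one video.

    A run is anchored by frames significant at ``alpha``; near-significant
    frames (``alpha <= p < near_alpha``) are merged into the current run only
    when their divergence has the same sign.  Any other frame — opposite
    sign, p >= near_alpha, or untestable — closes the run.
    """
    if near_alpha < alpha:
        raise ConfigurationError("near_alpha must be >= alpha")
    runs: list[RunSegment] = []
    start: int | None = None
    end = -1
    sign = SIGN_TIE
    has_sig = False

    def close() -> None:
        nonlocal start, has_sig
        if start is not None and has_sig:
            runs.append(RunSegment(stats[start].video_id, stats[start].frame,
                                   stats[end].frame, sign))
        start, has_sig = None, False

    for i, s in enumerate(stats):
        if not s.testable or s.p >= near_alpha or s.sign == SIGN_TIE:
            close()
            continue
        significant = s.p < alpha
        if start is None:
            if significant:
                start, end, sign, has_sig = i, i, s.sign, True
            # a near-significant frame cannot open a run
            continue
        if s.sign != sign:
            close()
            if significant:
                start, end, sign, has_sig = i, i, s.sign, True
            continue
        end = i
        has_sig = has_sig or significant
    close()
    return runs
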