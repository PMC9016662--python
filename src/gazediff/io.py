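"""Reading, writing and conditioning of raw gaze recordings.

Raw eye-tracker exports arrive as long-format delimited text, one row per
gaze sample (participant, video, sample index, x, y, validity).  This module
turns them into a dense :class:`GazeDataset` — a participant × video × frame
array of screen coordinates with a validity mask — aligns the source sampling
rate to the video frame rate, and applies validity rules (blinks coded as
missing, off-screen samples, sentinel codes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column names of the canonical long format
CANONICAL_COLUMNS = {
    "participant": "participant",
    "video": "video",
    "sample": "sample",
    "x": "x",
    "y": "y",
    "valid": "valid",
}


class ConfigurationError(ValueError):
    """A configuration problem (missing column, bad rate ratio, bad value)."""


class DataError(ValueError):
    """Malformed input data (e.g. duplicate samples)."""


@dataclass
class GroupAssignment:
    """Two-group labelling of participants.

    Parameters
    ----------
    labels
        Mapping ``participant_id -> label`` where label is ``"group_a"`` or
        ``"group_b"``.
    """

    labels: dict[str, str]

    GROUP_A = "group_a"
    GROUP_B = "group_b"

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {self.GROUP_A, self.GROUP_B}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        for g in (self.GROUP_A, self.GROUP_B):
            if len(self.members(g)) < 2:
                raise ConfigurationError(f"{g} has fewer than 2 participants")

    def members(self, label: str) -> list[str]:
        return [p for p, g in self.labels.items() if g == label]

    def label_of(self, participant: str) -> str:
        return self.labels[participant]

    def restrict(self, participants: Sequence[str]) -> "GroupAssignment":
        """Assignment restricted to a participant subset (e.g. training ids)."""
        keep = set(participants)
        return GroupAssignment({p: g for p, g in self.labels.items() if p in keep})

    def majority_share(self) -> float:
        """Share of the larger group — the chance level for classification."""
        n_a = len(self.members(self.GROUP_A))
        n_b = len(self.members(self.GROUP_B))
        return max(n_a, n_b) / (n_a + n_b)

    @classmethod
    def from_table(cls, path, participant_col: str = "participant",
                   group_col: str = "group") -> "GroupAssignment":
        df = pd.read_csv(path, sep=None, engine="python")
        for col in (participant_col, group_col):
            if col not in df.columns:
                raise ConfigurationError(f"group table lacks column {col!r}")
        raw = dict(zip(df[participant_col].astype(str), df[group_col].astype(str)))
        names = sorted(set(raw.values()))
        if set(names) <= {cls.GROUP_A, cls.GROUP_B}:
            return cls(raw)
        if len(names) != 2:
            raise ConfigurationError(
                f"group table must contain exactly two labels, got {names}")
        remap = {names[0]: cls.GROUP_A, names[1]: cls.GROUP_B}
        return cls({p: remap[g] for p, g in raw.items()})

    def to_table(self, path) -> None:
        pd.DataFrame(
            {"participant": list(self.labels), "group": list(self.labels.values())}
        ).to_csv(path, index=False)


@dataclass
class GazeDataset:
    """Dense participant × video × frame gaze positions with validity mask.

    ``positions`` has shape ``(n_participants, n_videos, n_frames_max, 2)``
    (x, y in screen pixels, origin top-left, y down); ``validity`` has shape
    ``(n_participants, n_videos, n_frames_max)``.  Videos may be shorter than
    the padded frame axis; ``n_frames[v]`` gives each video's true length and
    padding frames are always invalid.  Invalid positions are ignored by all
    downstream computation.
    """

    positions: np.ndarray
    validity: np.ndarray
    participant_ids: list[str]
    video_ids: list[str]
    n_frames: np.ndarray
    fps: float = 30.0
    source_rate: float = 60.0
    screen: tuple[float, float] = (1280.0, 900.0)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        self.n_frames = np.asarray(self.n_frames, dtype=int)
        if self.positions.shape[:3] != self.validity.shape or (
                self.positions.ndim != 4 or self.positions.shape[3] != 2):
            raise ValueError("positions and validity shapes are inconsistent")
        if self.positions.shape[0] != len(self.participant_ids):
            raise ValueError("participant axis does not match participant_ids")
        if self.positions.shape[1] != len(self.video_ids):
            raise ValueError("video axis does not match video_ids")
        # padding beyond each video's frame count can never be valid
        fmax = self.positions.shape[2]
        frame_idx = np.arange(fmax)
        pad = frame_idx[None, :] >= self.n_frames[:, None]  # (V, Fmax)
        self.validity = self.validity & ~pad[None, :, :]

    # -- basic introspection -------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.positions.shape[0]

    @property
    def n_videos(self) -> int:
        return self.positions.shape[1]

    def participant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.participant_ids)}
        return np.array([lookup[p] for p in ids], dtype=int)

    def video_index(self, video_id: str) -> int:
        return self.video_ids.index(video_id)

    def subset_participants(self, ids: Sequence[str]) -> "GazeDataset":
        idx = self.participant_index(ids)
        return replace(
            self,
            positions=self.positions[idx].copy(),
            validity=self.validity[idx].copy(),
            participant_ids=list(ids),
        )

    def masked_positions(self) -> np.ndarray:
        """Positions with invalid cells replaced by NaN (copy)."""
        pos = self.positions.copy()
        pos[~self.validity] = np.nan
        return pos


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _resolve_columns(columns, column_map: Mapping[str, str] | None) -> dict[str, str]:
    cmap = dict(CANONICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    missing = [k for k in ("participant", "video", "sample", "x", "y")
               if cmap[k] not in columns]
    if missing:
        raise ConfigurationError(
            f"input lacks mandatory columns for fields {missing} "
            f"(expected names {[cmap[m] for m in missing]})")
    return cmap


def read_gaze_long(path, column_map: Mapping[str, str] | None = None,
                   fps: float | None = None, source_rate: float = 60.0,
                   screen: tuple[float, float] = (1280.0, 900.0)) -> GazeDataset:
    """Read a long-format gaze export into a dense :class:`GazeDataset`.

    The frame axis of the result is the sample axis (``fps`` defaults to
    ``source_rate``); use :func:`downsample_to_frames` to move to the video
    frame rate.  Rows with blank/non-numeric x or y become invalid entries, as
    do rows whose validity column (if present) is falsy.

    Parameters
    ----------
    path
        Delimited text file (separator auto-detected).
    column_map
        Optional remapping of canonical field names (``participant``,
        ``video``, ``sample``, ``x``, ``y``, ``valid``) to file column names.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path), skipinitialspace=True,
                     float_precision="round_trip")
    cmap = _resolve_columns(df.columns, column_map)

    participants = sorted(df[cmap["participant"]].astype(str).unique())
    videos = sorted(df[cmap["video"]].astype(str).unique())
    if not participants or not videos:
        return GazeDataset(
            positions=np.zeros((0, 0, 0, 2)), validity=np.zeros((0, 0, 0), bool),
            participant_ids=[], video_ids=[], n_frames=np.zeros(0, int),
            fps=fps if fps is not None else source_rate,
            source_rate=source_rate, screen=screen)

    p_idx = df[cmap["participant"]].astype(str).map(
        {p: i for i, p in enumerate(participants)}).to_numpy()
    v_idx = df[cmap["video"]].astype(str).map(
        {v: i for i, v in enumerate(videos)}).to_numpy()
    s_idx = pd.to_numeric(df[cmap["sample"]], errors="raise").to_numpy().astype(int)
    if (s_idx < 0).any():
        raise DataError("negative sample indices")

    key = (p_idx.astype(np.int64) * len(videos) + v_idx) * (s_idx.max() + 1) + s_idx
    uniq, first = np.unique(key, return_index=True)
    if uniq.size != key.size:
        dup_mask = np.ones(key.size, bool)
        dup_mask[first] = False
        row = int(np.nonzero(dup_mask)[0][0])
        raise DataError(
            f"duplicate (participant, video, sample) at input row {row}: "
            f"({df[cmap['participant']].iloc[row]!r}, "
            f"{df[cmap['video']].iloc[row]!r}, {s_idx[row]})")

    n_frames = np.zeros(len(videos), dtype=int)
    np.maximum.at(n_frames, v_idx, s_idx + 1)
    fmax = int(n_frames.max())

    positions = np.full((len(participants), len(videos), fmax, 2), np.nan)
    validity = np.zeros((len(participants), len(videos), fmax), dtype=bool)

    x = pd.to_numeric(df[cmap["x"]], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[cmap["y"]], errors="coerce").to_numpy(float)
    valid = np.isfinite(x) & np.isfinite(y)
    if cmap["valid"] in df.columns:
        flag = df[cmap["valid"]]
        if flag.dtype == object:
            flag = flag.astype(str).str.strip().str.lower().isin(
                ("1", "true", "t", "yes", "y"))
        valid &= flag.to_numpy(bool)

    positions[p_idx, v_idx, s_idx, 0] = x
    positions[p_idx, v_idx, s_idx, 1] = y
    validity[p_idx, v_idx, s_idx] = valid
    positions[~validity] = np.nan

    return GazeDataset(
        positions=positions, validity=validity,
        participant_ids=participants, video_ids=videos, n_frames=n_frames,
        fps=fps if fps is not None else source_rate,
        source_rate=source_rate, screen=screen)


def write_gaze_long(dataset: GazeDataset, path) -> None:
    """Write the canonical long format (round-trips with :func:`read_gaze_long`)."""
    frames = []
    for vi, vid in enumerate(dataset.video_ids):
        nf = int(dataset.n_frames[vi])
        for pi, pid in enumerate(dataset.participant_ids):
            pos = dataset.positions[pi, vi, :nf]
            val = dataset.validity[pi, vi, :nf]
            frames.append(pd.DataFrame({
                "participant": pid,
                "video": vid,
                "sample": np.arange(nf),
                "x": np.where(val, pos[:, 0], np.nan),
                "y": np.where(val, pos[:, 1], np.nan),
                "valid": val.astype(int),
            }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["participant", "video", "sample", "x", "y", "valid"])
    # default float formatting = shortest round-trip repr, so positions
    # survive write -> read bit-exactly
    out.to_csv(path, index=False)


def downsample_to_frames(dataset: GazeDataset, target_fps: float) -> GazeDataset:
    """Align samples to video frames, keeping the first sample of each period.

    With a 60 Hz source and 30 fps video, output frame ``k`` is input sample
    ``2k``.  The source rate must be an integer multiple of ``target_fps``.
    """
    ratio = dataset.fps / target_fps
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ConfigurationError(
            f"source rate {dataset.fps} is not an integer multiple "
            f"of target fps {target_fps}")
    r = int(round(ratio))
    if r == 1:
        return replace(dataset, fps=float(target_fps))
    return replace(
        dataset,
        positions=dataset.positions[:, :, ::r].copy(),
        validity=dataset.validity[:, :, ::r].copy(),
        n_frames=-(-dataset.n_frames // r),  # ceil division
        fps=float(target_fps),
    )


def apply_validity_rules(dataset: GazeDataset,
                         sentinel: tuple[float, float] | None = None) -> GazeDataset:
    """Invalidate blink gaps, off-screen samples and sentinel-coded samples.

    Blink gaps are assumed to arrive as missing (NaN) coordinates or as
    already-false validity flags.  Off-screen samples (outside
    ``[0, width] × [0, height]``) are invalidated rather than clamped, which
    avoids biasing group centres toward the screen edges.  ``sentinel`` is an
    optional exact (x, y) code, e.g. ``(-1, -1)``.  Idempotent.
    """
    w, h = dataset.screen
    pos = dataset.positions
    finite = np.isfinite(pos).all(axis=3)
    on_screen = finite & (pos[..., 0] >= 0) & (pos[..., 0] <= w) \
        & (pos[..., 1] >= 0) & (pos[..., 1] <= h)
    valid = dataset.validity & on_screen
    if sentinel is not None:
        sx, sy = sentinel
        valid &= ~((pos[..., 0] == sx) & (pos[..., 1] == sy))
    n_dropped = int(dataset.validity.sum() - valid.sum())
    if n_dropped:
        logger.info("apply_validity_rules: invalidated %d entries", n_dropped)
    new_pos = pos.copy()
    new_pos[~valid] = np.nan
    return replace(dataset, positions=new_pos, validity=valid)
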