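"""Synthetic two-group gaze datasets with controllable group differences.

The generator emulates the structure of a video-viewing eye-tracking study:
per video a shared *attractor* trajectory (the locus of attentional synchrony)
evolves as a reflected Gaussian random walk inside the screen; each
participant's gaze follows the attractor with a smooth idiosyncratic *wander*
term (stationary AR(1), i.e. discretised Ornstein–Uhlenbeck) plus fast
isotropic sample noise.  Group differences are injected on a subset of
"effect" videos, inside a contiguous effect window of each such video, as a
dispersion ratio (group B's wander and noise scaled up) and/or a mean offset
added to group B.  Blink gaps are geometric-length runs of invalid samples.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .io import ConfigurationError, GazeDataset, GroupAssignment


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by mirror reflection at the boundaries."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic gaze study.

    Defaults mirror the scale of a two-group video-viewing experiment:
    21 + 23 participants, 16 s clips at 30 fps on a 1280 × 900 px display.

    Within-group gaze dispersion is split into a slow idiosyncratic wander
    (``wander_sd`` px, AR(1) correlation time ``wander_tau`` frames) and fast
    per-sample noise (``base_sd`` px); the group effect (``dispersion_ratio``
    scaling group B's wander and noise, and/or a mean ``offset`` on group B)
    applies on ``effect_videos`` during a contiguous window covering
    ``effect_window_frac`` of each such video's frames.
    """

    n_group_a: int = 21
    n_group_b: int = 23
    n_videos: int = 20
    frames_per_video: int = 480
    fps: float = 30.0
    screen: tuple[float, float] = (1280.0, 900.0)
    attractor_step_sd: float = 20.0
    base_sd: float = 40.0
    wander_sd: float = 80.0
    wander_tau: float = 30.0
    effect_videos: frozenset[int] = frozenset()
    dispersion_ratio: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)
    effect_window_frac: float = 0.4
    attractor_margin_frac: float = 0.15
    blink_prob: float = 0.01
    blink_mean_len: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b, self.n_videos,
               self.frames_per_video) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.screen[0] <= 0 or self.screen[1] <= 0:
            raise ConfigurationError("degenerate screen (zero area)")
        if self.dispersion_ratio <= 0:
            raise ConfigurationError("dispersion_ratio must be > 0")
        if not 0.0 <= self.blink_prob < 1.0:
            raise ConfigurationError("blink_prob must be in [0, 1)")
        if not 0.0 < self.effect_window_frac <= 1.0:
            raise ConfigurationError("effect_window_frac must be in (0, 1]")
        if not 0.0 <= self.attractor_margin_frac < 0.5:
            raise ConfigurationError("attractor_margin_frac must be in [0, 0.5)")
        bad = set(self.effect_videos) - set(range(self.n_videos))
        if bad:
            raise ConfigurationError(f"effect_videos out of range: {sorted(bad)}")
        object.__setattr__(self, "effect_videos", frozenset(self.effect_videos))


def null_config(n_a: int = 21, n_b: int = 23, n_videos: int = 20,
                frames: int = 480, seed: int = 0, **overrides) -> SyntheticConfig:
    """Config where both groups are drawn from the identical generative process."""
    return SyntheticConfig(
        n_group_a=n_a, n_group_b=n_b, n_videos=n_videos,
        frames_per_video=frames, effect_videos=frozenset(),
        dispersion_ratio=1.0, offset=(0.0, 0.0), seed=seed, **overrides)


def _blink_mask(rng: np.random.Generator, n_frames: int, blink_prob: float,
                mean_len: float) -> np.ndarray:
    """Boolean mask (True = inside a blink) with geometric blink lengths."""
    if blink_prob <= 0:
        return np.zeros(n_frames, dtype=bool)
    starts = rng.random(n_frames) < blink_prob
    mask = np.zeros(n_frames, dtype=bool)
    for t in np.nonzero(starts)[0]:
        length = rng.geometric(1.0 / max(mean_len, 1.0))
        mask[t:t + length] = True
    return mask


def generate(config: SyntheticConfig) -> tuple[GazeDataset, GroupAssignment, dict]:
    """Generate a two-group gaze dataset plus ground-truth record.

    Returns
    -------
    dataset : GazeDataset
        Dense positions/validity at the analysis frame rate.
    groups : GroupAssignment
        Participants ``a01..`` are group_a, ``b01..`` group_b.
    truth : dict
        Effect videos (ids and indices), effect windows per effect video,
        dispersion ratio, offset, and the full config.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.screen
    n_a, n_b = cfg.n_group_a, cfg.n_group_b
    n_p = n_a + n_b
    n_v, n_f = cfg.n_videos, cfg.frames_per_video

    participant_ids = [f"a{i + 1:02d}" for i in range(n_a)] + \
                      [f"b{i + 1:02d}" for i in range(n_b)]
    video_ids = [f"v{i + 1:02d}" for i in range(n_v)]
    groups = GroupAssignment(
        {p: GroupAssignment.GROUP_A for p in participant_ids[:n_a]}
        | {p: GroupAssignment.GROUP_B for p in participant_ids[n_a:]})

    rho = float(np.exp(-1.0 / max(cfg.wander_tau, 1e-9))) if cfg.wander_sd > 0 else 0.0
    innov_sd = cfg.wander_sd * np.sqrt(1.0 - rho ** 2)

    positions = np.empty((n_p, n_v, n_f, 2))
    validity = np.ones((n_p, n_v, n_f), dtype=bool)
    is_b = np.zeros(n_p, dtype=bool)
    is_b[n_a:] = True

    windows: dict[str, tuple[int, int]] = {}
    win_len = max(1, int(round(cfg.effect_window_frac * n_f)))

    # filmed content (and viewers' gaze) is strongly centre-biased, so the
    # attractor walk stays inside a central content region of the screen
    mx, my = cfg.attractor_margin_frac * w, cfg.attractor_margin_frac * h

    for vi in range(n_v):
        # shared attractor: reflected Gaussian random walk from screen centre
        steps = rng.normal(0.0, cfg.attractor_step_sd, size=(n_f, 2))
        steps[0] = 0.0
        walk = np.array([w / 2.0, h / 2.0]) + np.cumsum(steps, axis=0)
        attractor = np.empty_like(walk)
        attractor[:, 0] = _reflect(walk[:, 0], mx, w - mx)
        attractor[:, 1] = _reflect(walk[:, 1], my, h - my)

        # per-participant smooth wander: stationary AR(1) around the attractor
        wander = np.empty((n_p, n_f, 2))
        wander[:, 0] = rng.normal(0.0, cfg.wander_sd, size=(n_p, 2)) \
            if cfg.wander_sd > 0 else 0.0
        innov = rng.normal(0.0, 1.0, size=(n_p, n_f, 2)) * innov_sd
        for t in range(1, n_f):
            wander[:, t] = rho * wander[:, t - 1] + innov[:, t]

        noise = rng.normal(0.0, cfg.base_sd, size=(n_p, n_f, 2))

        effect = vi in cfg.effect_videos
        in_window = np.zeros(n_f, dtype=bool)
        if effect:
            start = int(rng.integers(0, n_f - win_len + 1))
            in_window[start:start + win_len] = True
            windows[video_ids[vi]] = (start, start + win_len - 1)
            scale = np.where(in_window[None, :, None] & is_b[:, None, None],
                             cfg.dispersion_ratio, 1.0)
            wander = wander * scale
            noise = noise * scale

        gaze = attractor[None, :, :] + wander + noise
        if effect and (cfg.offset[0] or cfg.offset[1]):
            gaze[np.ix_(is_b.nonzero()[0], in_window.nonzero()[0])] += \
                np.asarray(cfg.offset)

        positions[:, vi, :, 0] = _reflect(gaze[..., 0], 0.0, w)
        positions[:, vi, :, 1] = _reflect(gaze[..., 1], 0.0, h)

        for pi in range(n_p):
            blink = _blink_mask(rng, n_f, cfg.blink_prob, cfg.blink_mean_len)
            validity[pi, vi, blink] = False

    positions[~validity] = np.nan

    dataset = GazeDataset(
        positions=positions, validity=validity,
        participant_ids=participant_ids, video_ids=video_ids,
        n_frames=np.full(n_v, n_f, dtype=int),
        fps=cfg.fps, source_rate=cfg.fps, screen=cfg.screen)

    truth = {
        "effect_videos": sorted(video_ids[i] for i in cfg.effect_videos),
        "effect_video_indices": sorted(cfg.effect_videos),
        "effect_windows": windows,
        "dispersion_ratio": cfg.dispersion_ratio,
        "offset": list(cfg.offset),
        "config": {k: (sorted(v) if isinstance(v, frozenset) else
                       list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    return dataset, groups, truth
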