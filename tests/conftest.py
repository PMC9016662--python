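import numpy as np
import pytest

from gazediff import GazeDataset, GroupAssignment, SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_effect_setup():
    """Small two-group dataset with a known dispersion effect on one video."""
    cfg = SyntheticConfig(
        n_group_a=8, n_group_b=8, n_videos=4, frames_per_video=120,
        effect_videos=frozenset({1}), dispersion_ratio=2.0,
        blink_prob=0.005, seed=42)
    dataset, groups, truth = generate(cfg)
    return dataset, groups, truth


@pytest.fixture(scope="session")
def tiny_null_setup():
    """Small dataset where both groups share the generative process."""
    cfg = SyntheticConfig(
        n_group_a=8, n_group_b=8, n_videos=3, frames_per_video=90,
        blink_prob=0.0, seed=7)
    dataset, groups, truth = generate(cfg)
    return dataset, groups, truth


@pytest.fixture()
def handmade_dataset():
    """Fully hand-constructed 4-participant, 1-video, 3-frame dataset."""
    # participants p1, p2 (group_a), p3, p4 (group_b)
    positions = np.array([
        [[[100.0, 100.0], [110.0, 100.0], [120.0, 100.0]]],
        [[[200.0, 100.0], [210.0, 100.0], [220.0, 100.0]]],
        [[[100.0, 300.0], [110.0, 300.0], [120.0, 300.0]]],
        [[[200.0, 300.0], [250.0, 300.0], [220.0, 300.0]]],
    ])
    validity = np.ones((4, 1, 3), dtype=bool)
    dataset = GazeDataset(
        positions=positions, validity=validity,
        participant_ids=["p1", "p2", "p3", "p4"], video_ids=["v1"],
        n_frames=np.array([3]), fps=30.0, source_rate=30.0,
        screen=(1280.0, 900.0))
    groups = GroupAssignment({"p1": "group_a", "p2": "group_a",
                              "p3": "group_b", "p4": "group_b"})
    return dataset, groups
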