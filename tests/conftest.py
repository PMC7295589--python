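import numpy as np
import pytest

from cellwalk import (
    AlphaStableParams,
    Trajectory,
    WalkSimConfig,
    simulate_levy_walk_cohort,
)


@pytest.fixture
def straight_track():
    """(0,0) -> (1,0) -> (2,0) at 10-min frames."""
    return Trajectory(
        track_id="straight",
        t=np.array([0.0, 10.0, 20.0]),
        x=np.array([0.0, 1.0, 2.0]),
        y=np.zeros(3),
        frame_interval=10.0,
    )


@pytest.fixture
def out_and_back_track():
    return Trajectory(
        track_id="oab",
        t=np.array([0.0, 10.0, 20.0]),
        x=np.array([0.0, 1.0, 0.0]),
        y=np.zeros(3),
        frame_interval=10.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two-condition Lévy-walk cohort, 20 cells x 12 frames, fixed seed."""
    cfg = WalkSimConfig(
        params={
            "vehicle": AlphaStableParams(1.5, 0.5, 0.8, 2.6),
            "dex": AlphaStableParams(1.6, 0.5, 0.6, 2.4),
        },
        n_cells=20,
        n_frames=12,
        seed=123,
    )
    return simulate_levy_walk_cohort(cfg)


def random_walk_tracks(n_tracks: int, n_frames: int, seed: int) -> list[Trajectory]:
    """Plain Gaussian random walks for kinematics identities."""
    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, 2.0, size=(n_frames - 1, 2))
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(
            Trajectory(
                track_id=f"rw{i}",
                t=np.arange(n_frames) * 10.0,
                x=xy[:, 0],
                y=xy[:, 1],
                frame_interval=10.0,
            )
        )
    return tracks
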