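import numpy as np
import pandas as pd
import pytest

from skinoverlap.dataset import ANALYSIS_SITES, SkinDataset


def make_dataset(group_points: dict[str, np.ndarray], site: str = "cheek") -> SkinDataset:
    """Build a SkinDataset from {group: (n, 3) lab array} with minimal metadata."""
    frames = []
    for g, lab in group_points.items():
        lab = np.atleast_2d(np.asarray(lab, dtype=float))
        n = len(lab)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{g}{i:04d}" for i in range(n)],
                    "group": g,
                    "gender": np.where(np.arange(n) % 2 == 0, "female", "male"),
                    "age": 30.0,
                    "body_site": site,
                    "L": lab[:, 0],
                    "a": lab[:, 1],
                    "b": lab[:, 2],
                }
            )
        )
    return SkinDataset(pd.concat(frames, ignore_index=True))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_cloud_dataset(rng):
    """Two partially overlapping Gaussian clouds (CA, CN)."""
    a = rng.normal((55.0, 10.0, 16.0), (4.0, 2.0, 2.0), size=(300, 3))
    b = rng.normal((59.0, 10.0, 16.0), (4.0, 2.0, 2.0), size=(300, 3))
    return make_dataset({"CA": a, "CN": b})


@pytest.fixture
def lab_csv(tmp_path):
    """A tiny valid lab-format CSV file with three records."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2"],
            "group": ["CA", "CA", "CN"],
            "gender": ["female", "female", "male"],
            "age": [30, 30, 41],
            "body_site": [ANALYSIS_SITES[0], ANALYSIS_SITES[1], ANALYSIS_SITES[0]],
            "L": [61.0, 60.5, 58.2],
            "a": [11.0, 10.8, 10.1],
            "b": [14.5, 14.9, 16.2],
        }
    ).to_csv(path, index=False)
    return path
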