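import numpy as np
import pytest

from irbedpose import fixtures


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """Small on-disk synthetic dataset shared by manifest-driven tests."""
    root = tmp_path_factory.mktemp("dataset")
    manifest = fixtures.build_manifest(12, 6, 6, 4, 4, rng_seed=202, out_dir=root)
    return root, manifest


@pytest.fixture()
def sample_pose():
    return fixtures.generate_subject_pose(7, "supine")


@pytest.fixture()
def sample_frame(sample_pose):
    return fixtures.render_frame(sample_pose, 3)


def refine_oracle(heatmap, seed, d=5, n_iter=3):
    """Literal transcription of the iterative center-of-mass refinement.

    Kept deliberately naive (python loops, out-of-bounds reads are zero) and
    independent of the library implementation it checks.
    """
    h = np.asarray(heatmap, dtype=np.float64)
    rows, cols = h.shape

    def at(y, x):
        if 0 <= y < rows and 0 <= x < cols:
            return h[y, x]
        return 0.0

    x, y = float(seed[0]), float(seed[1])
    half = (d - 1) // 2
    for _ in range(n_iter):
        xn = int(np.floor(x + 0.5))
        yn = int(np.floor(y + 0.5))
        s = 0.0
        sx = 0.0
        sy = 0.0
        for i in range(-half, half + 1):
            for j in range(-half, half + 1):
                v = at(yn + j, xn + i)
                s += v
                sx += v * (xn + i)
                sy += v * (yn + j)
        if s == 0.0:
            return float(seed[0]), float(seed[1])
        x = sx / s
        y = sy / s
    return x, y
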