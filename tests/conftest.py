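import numpy as np
import pytest

from arenatrack.synth import make_ymaze
from arenatrack.tracking import Track, TrackRecord


@pytest.fixture
def maze():
    return make_ymaze()


def track_from_path(centers, dpix=None, fps=30.0, roi_id="maze"):
    """Build a Track directly from scripted positions (bypassing vision)."""
    tr = Track(roi_id)
    n = len(centers)
    dp = np.zeros(n, dtype=int) if dpix is None else np.asarray(dpix)
    for i, (x, y) in enumerate(np.asarray(centers, dtype=float)):
        tr.records.append(TrackRecord(i, (x, y), (float(x), float(y)), int(dp[i]), True))
    return tr


@pytest.fixture
def plate96_small():
    """A short 96-well scene shared across vision tests."""
    from arenatrack.synth import plate96_scene

    return plate96_scene(n_frames=80, seed=3)
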