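import numpy as np
import pandas as pd
import pytest

from ighloci.ensemble_analysis import BeadAnnotation
from ighloci.polymer import Ensemble, ModelParams


def make_ensemble(frames, **params) -> Ensemble:
    """Ensemble from an explicit list of (n_beads, 3) coordinate arrays."""
    coords = np.asarray(frames, dtype=float)
    return Ensemble(coords, ModelParams(n_beads=coords.shape[1], **params))


def straight_chain(n: int, spacing: float = 1.0) -> np.ndarray:
    conf = np.zeros((n, 3))
    conf[:, 0] = spacing * np.arange(n)
    return conf


@pytest.fixture(scope="session")
def toy_annotation() -> BeadAnnotation:
    """6-bead annotation: one DH bead (1), three VH beads (3, 4, 5)."""
    return BeadAnnotation(pd.DataFrame({
        "bead_index": [1, 2, 3, 4, 5, 6],
        "element_class": ["DH", "none", "VH", "VH", "VH", "none"],
        "ctcf_level": [1.0, 0.0, 0.5, 0.5, 0.5, 0.0],
        "recombination_score": [np.nan, np.nan, 0.3, 0.5, 0.1, np.nan],
    }))


@pytest.fixture(scope="session")
def compiled_kernel():
    """Warm the numba kernel once so per-test timings stay small."""
    from ighloci.polymer import SamplingSchedule, mc_sample

    mc_sample(np.zeros((4, 4)), ModelParams(n_beads=4), 2, seed=0,
              schedule=SamplingSchedule(1, 1))
    return True
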