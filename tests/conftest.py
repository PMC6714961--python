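import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ripscan import RipThresholds, SequenceRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rec(residues: str, seq_id: str = "seq") -> SequenceRecord:
    return SequenceRecord(id=seq_id, description="", residues=residues)


def revcomp(residues: str) -> str:
    return residues.translate(COMPLEMENT)[::-1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_th():
    return RipThresholds()


def windows_from_mask(mask, th: RipThresholds, seq_id: str = "seq", length: int = None) -> pd.DataFrame:
    """Build a synthetic window table with prescribed positivity.

    Positive windows get indices that satisfy the thresholds, negative ones
    indices that do not, so the table is internally consistent.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if length is None:
        length = n * th.step + (th.window - th.step)
    starts = np.arange(n) * th.step
    ends = np.minimum(starts + th.window, length)
    product = np.where(mask, th.product_min + 0.5, th.product_min - 0.5)
    substrate = np.where(mask, max(th.substrate_max - 0.3, 0.0), th.substrate_max + 0.3)
    return pd.DataFrame(
        {
            "seq_id": seq_id,
            "index": np.arange(n),
            "start": starts,
            "end": ends,
            "product": product,
            "substrate": substrate,
            "composite": product - substrate,
            "gc": np.full(n, 0.3),
            "positive": mask,
        }
    )
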