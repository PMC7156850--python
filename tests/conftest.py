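import numpy as np
import pytest

from segqc.datamodel import SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_subject(
    conf: np.ndarray,
    gt: np.ndarray,
    subject_id: str = "s0",
    split: str = "test",
    region: str = "WT",
    brain: np.ndarray | None = None,
) -> SubjectRecord:
    """Minimal single-region subject from a confidence field and labels."""
    conf = np.asarray(conf, dtype=float)
    gt = np.asarray(gt).astype(bool)
    if brain is None:
        brain = np.ones(conf.shape, dtype=bool)
    return SubjectRecord(
        subject_id=subject_id,
        spacing=(1.0, 1.0, 1.0),
        brain_mask=brain,
        gt_labels={region: gt & brain},
        pred_labels={region: (conf >= 0.5) & brain},
        prob_maps={region: conf},
        split=split,
    )
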