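import numpy as np
import pytest

from octstitch.training import OCTDataset


def _intervals(mask):
    out, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def oracle_detect(img: np.ndarray) -> int:
    """Hand-coded phenotype detector, independent of any trained model.

    CNV: a wide contiguous excess in per-column bright-pixel thickness
    (the sub-retinal lesion).  Drusen: medium-reflectivity deposit area
    between the bright-band and background intensity levels.  Otherwise
    normal.
    """
    side = img.shape[0]
    bright = img > 0.45
    thickness = bright.sum(axis=0).astype(float)
    excess = np.clip(thickness - np.median(thickness), 0, None)
    iv = _intervals(excess > 0.035 * side)
    maxw = max((e - s for s, e in iv), default=0) / side
    if maxw > 0.13 and excess.sum() / side ** 2 > 0.015:
        return 2
    if ((img > 0.28) & (img < 0.46)).mean() > 0.014:
        return 1
    return 0


@pytest.fixture(scope="session")
def toy_dataset_32() -> OCTDataset:
    """Small balanced synthetic dataset at 32 px for training tests."""
    return OCTDataset.from_synthetic(150, side=32, seed=5,
                                     proportions=(1 / 3, 1 / 3, 1 / 3))


@pytest.fixture(scope="session")
def imbalanced_dataset_32() -> OCTDataset:
    """Normal-majority synthetic dataset at 32 px."""
    return OCTDataset.from_synthetic(300, side=32, seed=9)
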