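import numpy as np
import pandas as pd
import pytest

from dipmap.simulate import default_geometry
from dipmap.tmap import ImageDataset


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


def make_image_dataset(n_per_class, size=8, seed=0, n_subjects=1):
    """Tiny labelled dataset with random images, for split/count tests."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    images = rng.random((n, size, size, 3)).astype(np.float32)
    labels = np.array(["RHTF"] * n_per_class + ["RHLF"] * n_per_class)
    meta = pd.DataFrame({
        "subject": np.arange(n) % n_subjects,
        "label": labels,
    })
    return ImageDataset(images=images, labels=labels, meta=meta)


def make_quadrant_dataset(n_per_class, size=56, seed=0):
    """Linearly separable toy images: class-distinct bright quadrants."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls, (qr, qc) in (("RHTF", (0, 0)), ("RHLF", (1, 1))):
        for _ in range(n_per_class):
            img = rng.uniform(0.0, 0.2, (size, size, 3)).astype(np.float32)
            h = size // 2
            img[qr * h : (qr + 1) * h, qc * h : (qc + 1) * h] += 0.6
            images.append(np.clip(img, 0, 1))
            labels.append(cls)
    labels = np.array(labels)
    meta = pd.DataFrame({"subject": np.zeros(len(labels), dtype=int), "label": labels})
    return ImageDataset(images=np.stack(images), labels=labels, meta=meta)
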