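import numpy as np
import pytest

from corrseg.masks import AnnotationMask, BinaryMask


def random_mask(rng: np.random.Generator, height: int = 16, width: int = 16,
                p: float = 0.3) -> BinaryMask:
    return BinaryMask(rng.random((height, width)) < p)


def random_annotation(rng: np.random.Generator, height: int = 16,
                      width: int = 16, p: float = 0.15) -> AnnotationMask:
    u = rng.random((height, width))
    return AnnotationMask(u < p, (u >= p) & (u < 2 * p))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
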