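import numpy as np
import pytest

from compartmarks.features import FeatureDescriptor, FeatureMatrix
from compartmarks.genomic_io import GenomicInterval, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(20211027)


def random_peaks(rng, chrom="chr1", n=20, span=10_000, max_width=800):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span - 1))
        width = int(rng.integers(1, max_width))
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, min(start + width, span)),
                float(rng.uniform(0, 10)),
            )
        )
    return peaks


def random_matrix(rng, n=60, d=5, informative=0):
    """Labeled random feature matrix; first `informative` columns shifted by class."""
    labels = np.array(["A" if i < n // 2 else "B" for i in range(n)], dtype=object)
    values = rng.normal(size=(n, d))
    for j in range(informative):
        values[labels == "A", j] += 3.0
    descriptors = [FeatureDescriptor(f"m{j}", "fraction") for j in range(d)]
    return FeatureMatrix(
        region_ids=[f"r{i}" for i in range(n)],
        labels=labels,
        descriptors=descriptors,
        values=values,
    )
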