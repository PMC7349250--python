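import numpy as np
import pytest

from gbspopgen import GenotypeMatrix, VariantRecord, make_study_like_fixture


def build_matrix(dosage, chroms=None, positions=None, sample_ids=None):
    """Small GenotypeMatrix from a dosage array (samples x variants)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if chroms is None:
        chroms = ["chr1"] * m
    if positions is None:
        positions = {}
        pos = []
        for c in chroms:
            positions[c] = positions.get(c, 0) + 100
            pos.append(positions[c])
        positions = pos
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    variants = [VariantRecord(c, p) for c, p in zip(chroms, positions)]
    return GenotypeMatrix(sample_ids, variants, dosage)


@pytest.fixture(scope="session")
def study_fixture():
    """Study-shaped synthetic data set: 50 samples, 5 weak populations."""
    return make_study_like_fixture(seed=7)
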