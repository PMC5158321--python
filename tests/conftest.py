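import numpy as np
import pytest

from psmmkit.motif_io import MotifHit
from psmmkit.psmm import BandScheme, FeatureMatrix, FeatureSpace


@pytest.fixture
def small_scheme():
    return BandScheme(promoter_length=250, band_width=50)


@pytest.fixture
def rng():
    return np.random.default_rng(20161128)


def make_matrix(values, labels, band_width=50):
    """Wrap a plain array into a FeatureMatrix with generic motif names.

    Columns are grouped into one synthetic motif per band-block so that any
    column count is representable.
    """
    values = np.asarray(values)
    n, p = values.shape
    scheme = BandScheme(promoter_length=band_width, band_width=band_width)
    # one band per motif: p motifs x 1 band
    space = FeatureSpace(tuple(f"MA{i:04d}.1" for i in range(1, p + 1)), scheme)
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        labels=list(labels),
        space=space,
        values=values,
    )


def random_hits(rng, n, promoter_ids, motif_ids, promoter_length=250):
    hits = []
    for _ in range(n):
        hits.append(
            MotifHit(
                promoter_id=str(rng.choice(promoter_ids)),
                motif_id=str(rng.choice(motif_ids)),
                start=int(rng.integers(0, promoter_length)),
                strand=str(rng.choice(["+", "-", "."])),
                score=float(np.round(rng.normal(), 4)) if rng.random() < 0.5 else None,
            )
        )
    return hits
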