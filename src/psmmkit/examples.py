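"""The small worked examples of the method, as reusable fixtures.

The method's behaviour is easiest to check on a hypothetical 4-motif x
5-band feature space (20 features over bands 0-50 .. 201-250): ten of the
features carry known two-sample t-test P values, the other ten are
non-discriminative (P > 0.19), so P-value selection at T = 50% must retain
exactly the ten known features.
"""

from __future__ import annotations

import numpy as np

from .psmm import BandScheme, FeatureSpace
from .selection import PValueProfile

__all__ = [
    "EXAMPLE_MOTIFS",
    "EXAMPLE_PVALUES",
    "example_feature_space",
    "example_pvalue_profile",
]

EXAMPLE_MOTIFS = ("MA0041.1", "MA0072.1", "MA0084.1", "MA0141.1")

# The ten discriminative features of the worked example, by (motif, band):
# MA0041.1 in bands 51-100, 151-200 and 201-250; MA0084.1 in bands 0-50,
# 101-150 and 151-200; MA0141.1 in every band except 151-200.
EXAMPLE_PVALUES: dict[tuple[str, int], float] = {
    ("MA0041.1", 1): 0.17,
    ("MA0041.1", 3): 0.15,
    ("MA0041.1", 4): 0.04,
    ("MA0084.1", 0): 0.10,
    ("MA0084.1", 2): 0.10,
    ("MA0084.1", 3): 0.15,
    ("MA0141.1", 0): 0.15,
    ("MA0141.1", 1): 0.17,
    ("MA0141.1", 2): 0.15,
    ("MA0141.1", 4): 0.19,
}


def example_feature_space() -> FeatureSpace:
    """4 motifs x 5 bands of 50 bp over a 250-bp window."""
    return FeatureSpace(EXAMPLE_MOTIFS, BandScheme(250, 50))


def example_pvalue_profile(seed: int = 0) -> tuple[PValueProfile, FeatureSpace]:
    """The example's 20-feature P-value profile.

    The ten named features get their known P values; the remaining ten get
    values drawn uniformly from (0.19, 1], i.e. above every known value, so
    they can never displace a known feature in the ranking.
    """
    space = example_feature_space()
    rng = np.random.default_rng(seed)
    p = np.empty(len(space))
    for i, (motif, band) in enumerate(space.pairs):
        known = EXAMPLE_PVALUES.get((motif, band))
        if known is not None:
            p[i] = known
        else:
            p[i] = rng.uniform(0.19, 1.0) + 1e-9
    return PValueProfile(np.clip(p, 0, 1)), space
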