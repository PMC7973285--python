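"""Shared cohort fixtures.

The default synthetic cohort (233 fractions, 147 IC / 86 IS) and its
extracted feature table are expensive (~3 min together), so they are built
once per session and shared by the recovery, selection, and weighting tests.
"""

import numpy as np
import pytest

from brachysel import CohortConfig, GeometricFeatureExtractor, generate_cohort
from brachysel.quality_weighting import DosimetricWeighter


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """(feature DataFrame, labels, plan-quality weights) for the default cohort."""
    X = GeometricFeatureExtractor().transform(default_cohort)
    y = np.array([f.label for f in default_cohort])
    w = np.array(DosimetricWeighter().weights([f.record for f in default_cohort]))
    return X, y, w


@pytest.fixture(scope="session")
def reduced_features(default_features):
    """The six HR-CTV geometry features as a plain array, with labels/weights."""
    from brachysel import HRCTVFeatureSelector

    X, y, w = default_features
    sel = HRCTVFeatureSelector(rule="group").fit(X, y)
    return np.asarray(sel.transform(X)), y, w, sel
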