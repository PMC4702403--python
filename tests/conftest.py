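import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ssealign import ScoringParams
from ssealign import synthetic as syn


@pytest.fixture
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def helix_bundle() -> syn.SyntheticChain:
    return syn.helix_bundle()


@pytest.fixture
def strand_sheet() -> syn.SyntheticChain:
    return syn.strand_sheet()


@pytest.fixture
def mixed_fold() -> syn.SyntheticChain:
    return syn.mixed_fold()


def fixture_collection() -> dict[str, syn.SyntheticChain]:
    """The catalog of standard synthetic constructs.

    Every entry is a connected, compact fold (consecutive SSEs within the
    contact cutoff).  The *moved* partner chains of the hinge and
    multi-segment constructs are derived variants, not catalog fixtures:
    their segments are pushed out of mutual contact by design, so even a
    self-comparison correctly reports one rigid block per segment.
    """
    hinge_q, _t, _ = syn.make_hinge_protein(60.0)
    seg_q, _t2, _ = syn.make_multi_segment_protein()
    return {
        "helix_bundle": syn.helix_bundle(),
        "strand_sheet": syn.strand_sheet(),
        "mixed_fold": syn.mixed_fold(),
        "hinge_query": hinge_q,
        "three_segment_query": seg_q,
    }
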