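import numpy as np
import pytest

from replichore.io import AnnotationSet, CircularSequence, FeatureAnnotation
from replichore.simulate import SyntheticGenomeSpec, simulate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic genome (100 kb, 60 genes, 2 rRNA operons)."""
    return simulate_genome(SyntheticGenomeSpec(seed=7))


@pytest.fixture(scope="session")
def offset_ori_genome():
    """Synthetic genome whose origin is planted away from base 1, so some
    features wrap the junction."""
    return simulate_genome(SyntheticGenomeSpec(seed=19, ori=73_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_annotation(features, seq_id="chr"):
    return AnnotationSet(seq_id, features)


def cds(start, end, strand="+", tag="", **kw):
    return FeatureAnnotation("CDS", start, end, strand, locus_tag=tag, **kw)
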