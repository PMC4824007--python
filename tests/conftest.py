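import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from protevo.pairalign import SubstitutionMatrix
from protevo.pipeline import run_survey_data
from protevo.synthdata import generate_survey_fixture


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def survey_fixture():
    """The default planted-truth fixture: 6 nested + 2 outgroup clades,
    2 organisms each, 8 query families, 200 decoys per proteome."""
    return generate_survey_fixture(seed=42)


@pytest.fixture(scope="session")
def survey_result(survey_fixture):
    """One full survey run over the default fixture (shared session-wide:
    the end-to-end computation is the expensive part of the suite)."""
    fx = survey_fixture
    return run_survey_data(
        proteomes=fx.proteomes,
        seed_alignments=fx.seed_alignments,
        domain_alignments=fx.domain_alignments,
        taxonomy=fx.taxonomy,
        families=fx.families,
        reference_organism=fx.reference_organism,
        tail_policies=fx.tail_policies,
        interactions=fx.interactions,
        apa_seed=fx.apa_seed,
        apa_family=fx.apa_family,
        seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
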