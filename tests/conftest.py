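import os
from pathlib import Path

import numpy as np
import pytest

from msat.coverage import SpeciesProfile
from msat.phylo import load_tree

REPO_ROOT = Path(__file__).resolve().parent.parent
DATASET_ENV = "MSAT_DATASET_S1"
DATASET_DEFAULT = REPO_ROOT / "data" / "pone.0040861.s006.csv"


def dataset_path() -> Path | None:
    """Published survey table, if supplied locally (never required)."""
    candidate = Path(os.environ.get(DATASET_ENV, DATASET_DEFAULT))
    return candidate if candidate.exists() else None


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120716)


@pytest.fixture
def balanced_tree():
    """Four leaves, two cherries at age 10, root at age 100."""
    return load_tree("((a:10,b:10):90,(c:10,d:10):90);")


@pytest.fixture
def make_profile():
    def _make(bases_by_motif, total_bases=1_000_000, gc=0.4,
              species_id="sp1", taxonomy=("PhylumX",)):
        return SpeciesProfile(
            species_id=species_id,
            taxonomy=taxonomy,
            total_bases=total_bases,
            gc_fraction=gc,
            bases_by_motif=dict(bases_by_motif),
        )

    return _make


@pytest.fixture
def survey_profiles():
    profiles = dataset_path()
    if profiles is None:
        pytest.skip("published survey table not supplied "
                    f"(set ${DATASET_ENV} or place it at {DATASET_DEFAULT})")
    from msat.survey import load_survey_table

    return load_survey_table(profiles)
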