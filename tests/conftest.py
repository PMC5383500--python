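import warnings

import numpy as np
import pandas as pd
import pytest

import darkneighbors as dn
from darkneighbors.tables import (
    LEVEL_DARK,
    LEVEL_ENV_EXCLUDED,
    LEVEL_OBSERVED,
    PoolAssignment,
)

# the simulator intentionally warns about truncated plot richness etc.;
# tests assert on behaviour, not on noise
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def assembly():
    """One default synthetic assembly shared by read-only tests."""
    return dn.simulate_assembly(dn.SimulationConfig(), seed=11)


def make_pool(trait_index, pool_species, observed_species=()):
    """PoolAssignment directly from known membership (test helper)."""
    level = pd.Series(LEVEL_ENV_EXCLUDED, index=trait_index, name="level")
    pool_species = pd.Index(pool_species)
    level.loc[pool_species.difference(pd.Index(observed_species))] = LEVEL_DARK
    if len(observed_species):
        level.loc[pd.Index(observed_species)] = LEVEL_OBSERVED
    return PoolAssignment(
        table=pd.DataFrame(
            {
                "level": level,
                "in_regional": True,
                "in_habitat_pool": level != LEVEL_ENV_EXCLUDED,
            }
        )
    )


@pytest.fixture
def tiny_csvs(tmp_path):
    """A well-formed 3-species CSV fixture set."""
    (tmp_path / "traits.csv").write_text(
        "species_id,height,sla\nsp1,10.0,20.0\nsp2,20.0,25.0\nsp3,30.0,30.0\n"
    )
    (tmp_path / "regional.csv").write_text("species_id\nsp1\nsp2\nsp3\n")
    (tmp_path / "occurrences.csv").write_text(
        "site_id,species_id\nfocal,sp1\nhabA,sp1\nhabA,sp2\nhabB,sp2\n"
    )
    (tmp_path / "community.csv").write_text(
        "plot_id,site_id,species_id,count\np1,focal,sp1,3\np1,focal,sp2,1\n"
        "p2,focal,sp1,2\n"
    )
    (tmp_path / "colonists.csv").write_text(
        "species_id,site_id,plot_id,seeds_added,plants_year3\n"
        "sp3,focal,p1,15,3\nsp3,focal,p2,15,6\n"
    )
    return tmp_path
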