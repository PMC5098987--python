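import numpy as np
import pandas as pd
import pytest

from reefcross.simulate import (
    CommunityParams,
    EffectParams,
    generate_cross_design,
    simulate_life_history,
    simulate_symbiont_table,
)


@pytest.fixture(scope="session")
def design():
    return generate_cross_design(4, 4, seed=7)


@pytest.fixture(scope="session")
def life(design):
    return simulate_life_history(design, EffectParams(), seed=3)


def class_metadata(n_high_fam=4, n_low_fam=4, per_fam=3):
    """Juvenile metadata with mortality classes fixed by construction."""
    rows = []
    for f in range(n_high_fam + n_low_fam):
        cls = "high" if f < n_high_fam else "low"
        for j in range(per_fam):
            rows.append(
                {
                    "sample_id": f"F{f + 1}_J{j + 1}",
                    "family_id": f"F{f + 1}",
                    "dam_id": "O1" if f % 2 else "W1",
                    "sire_id": "W5",
                    "dam_population": "O" if f % 2 else "W",
                    "sire_population": "W",
                    "mortality_class": cls,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def metadata_12v12():
    return class_metadata(4, 4, 3)


@pytest.fixture(scope="session")
def symbiont(metadata_12v12):
    table, seqs, truth = simulate_symbiont_table(
        metadata_12v12, CommunityParams(), seed=11
    )
    return table, seqs, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
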