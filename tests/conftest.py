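import numpy as np
import pandas as pd
import pytest

from dielomics import DiurnalExpressionModel, GeneratorConfig, generate_triplet


@pytest.fixture(scope="session")
def default_triplet():
    """One default-condition synthetic triplet (1000 genes, seed 0)."""
    return generate_triplet(GeneratorConfig(), seed=0)


@pytest.fixture(scope="session")
def fitted_default(default_triplet):
    trip = default_triplet
    model = DiurnalExpressionModel(
        trip.tables["mrna"],
        trip.tables["ribo"],
        trip.tables["protein"],
        trip.samples,
        trip.counts["mrna_counts"],
        trip.counts["ribo_counts"],
        timepoint_hours=trip.timepoint_hours,
    )
    return trip, model.fit()


def make_sample_sheet(levels=("mrna", "ribo", "protein"), n_timepoints=5, n_reps=2):
    rows = []
    for level in levels:
        for tp in range(1, n_timepoints + 1):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{level}_t{tp}_r{rep}",
                        "level": level,
                        "time_point": tp,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def sample_sheet():
    return make_sample_sheet()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
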