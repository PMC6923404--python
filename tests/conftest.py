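import numpy as np
import pandas as pd
import pytest

from cytoda import preprocess as pp
from cytoda import synthetic_data as sim
from cytoda.fcs_io import ChannelInfo, EventTable, SampleMetadata


@pytest.fixture(scope="session")
def small_truth():
    """8 samples x 2000 events, 5 populations, 8 markers — fast but rich
    enough to exercise every preprocessing stage."""
    return sim.default_truth(
        n_per_group=(4, 4),
        n_events=2000,
        n_populations=5,
        n_markers=8,
        n_lineage=6,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_result(small_truth):
    return sim.simulate_experiment(small_truth)


@pytest.fixture(scope="session")
def small_gating():
    return pp.GatingConfig(
        dna_channels=("191Ir", "193Ir"),
        bead_interval_seconds=60.0,
        min_beads_per_interval=5,
    )


@pytest.fixture()
def tiny_table():
    """Hand-made 4-event table with one channel of every role."""
    channels = [
        ChannelInfo(metal="M01", marker="CD4", role="marker"),
        ChannelInfo(metal="89Y", marker="CD45", role="barcode"),
        ChannelInfo(metal="140Ce", role="bead"),
        ChannelInfo(metal="191Ir", marker="DNA1", role="dna"),
        ChannelInfo(metal="EventLength", role="event_length"),
        ChannelInfo(metal="Time", role="time"),
    ]
    values = np.array(
        [
            [10.0, 200.0, 0.5, 300.0, 20.0, 0.1],
            [0.0, 1.0, 0.2, 280.0, 25.0, 0.2],
            [55.0, 180.0, 0.1, 310.0, 30.0, 0.3],
            [7.0, 2.0, 0.4, 290.0, 22.0, 0.4],
        ]
    )
    return EventTable(values=values, channels=channels)


@pytest.fixture(scope="session")
def two_group_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"S{i:02d}" for i in range(1, 23)],
                "group": ["CON"] * 11 + ["MS"] * 11,
            }
        )
    )
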