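import logging

import pytest

from opsinconv.alignment_io import Alignment, SequenceRecord, default_opsin_region_map
from opsinconv.simulate import SimulationConfig, simulate_dataset

logging.getLogger("opsinconv").setLevel(logging.ERROR)


def make_alignment(seqs: dict[str, str]) -> Alignment:
    records = []
    for raw_id, bases in seqs.items():
        records.append(SequenceRecord(raw_id=raw_id, bases=bases))
    return Alignment(tuple(records))


@pytest.fixture(scope="session")
def region_map():
    return default_opsin_region_map()


@pytest.fixture(scope="session")
def tiny_region_map():
    """12-site map: exon [0,6), intron [6,12); residue 1 anchored at 0."""
    from opsinconv.alignment_io import Region, RegionMap

    return RegionMap(
        (Region("exon1", 0, 6, "exon", 0), Region("intron1", 6, 12, "intron", 0)),
        {1: ("exon1", 0), 2: ("exon1", 3)},
    )


@pytest.fixture(scope="session")
def simulated_default():
    """One data set under the default (conversion + purging) scenario."""
    cfg = SimulationConfig(seed=42)
    aln, truth = simulate_dataset(cfg)
    return cfg, aln, truth


@pytest.fixture(scope="session")
def simulated_null():
    """One data set with conversion switched off."""
    cfg = SimulationConfig(seed=43, conv_rate=0.0)
    aln, truth = simulate_dataset(cfg)
    return cfg, aln, truth
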