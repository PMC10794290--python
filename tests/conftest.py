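import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lfdr_snv.caller import CallerConfig, run_algorithm1
from lfdr_snv.counts_io import RawBaseRecord
from lfdr_snv.simulator import SimulationSpec, simulate_dataset


def make_record(chrom="chr1", pos=100, ref="A", counts=None, bq=30.0, mq=40.0,
                bq_by_base=None, mq_by_base=None):
    """Convenience raw record with uniform (or per-base) qualities."""
    counts = counts or {"A": 9, "C": 1, "G": 0, "T": 0}
    bases = ("A", "C", "G", "T")
    return RawBaseRecord(
        chrom=chrom, pos=pos, ref_base=ref, depth=sum(counts.values()),
        counts={b: counts.get(b, 0) for b in bases},
        mean_bq={b: (bq_by_base or {}).get(b, bq) for b in bases},
        mean_mq={b: (mq_by_base or {}).get(b, mq) for b in bases},
    )


@pytest.fixture(scope="session")
def sim_small():
    """2,000-site synthetic dataset at the default study conditions."""
    return simulate_dataset(SimulationSpec(p=2000, seed=11))


@pytest.fixture(scope="session")
def sim_flagship():
    """The flagship 20,000-site simulation: pi0=0.95, depth 100, e=0.01,
    bimodal allele frequencies at 0.5/1.0."""
    return simulate_dataset(SimulationSpec(p=20000, pi0_true=0.95, depth=100,
                                           e_true=0.01, seed=17))


@pytest.fixture(scope="session")
def sim_config():
    """Caller configuration for synthetic tables: quality pre-filters are
    disabled because simulated reads carry uniform calibrated qualities
    (there are no low-quality artifacts to exclude)."""
    return CallerConfig(min_bq=0.0, min_mq=0.0, tau=1e-20, seed=17, g_mode="empirical")


@pytest.fixture(scope="session")
def flagship_callset(sim_flagship, sim_config):
    return run_algorithm1(sim_flagship.records, sim_config)
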