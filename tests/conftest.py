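import numpy as np
import pytest

from somacohort import CohortSimConfig, simulate_cohort, toy_genome
from somacohort.cnv import CopyNumberSegment, SamplePloidyProfile


@pytest.fixture(scope="session")
def toy():
    """(build, arms, genes) of a small scaled genome."""
    return toy_genome(0.5)


@pytest.fixture(scope="session")
def small_cohort():
    """A default-frequency cohort on a fast 0.3 Mb-scale genome."""
    return simulate_cohort(CohortSimConfig(seed=11, genome_scale_mb=0.3))


def make_segments(sample, spec, chromosome="chr1"):
    """Build segments from (start, end, total[, major]) tuples."""
    out = []
    for item in spec:
        if len(item) == 3:
            start, end, total = item
            major = total / 2
        else:
            start, end, total, major = item
        out.append(CopyNumberSegment(sample, chromosome, start, end, total, major))
    return out


def diploid_profile(sample="s", ploidy=2.0, wgd=False):
    return SamplePloidyProfile(sample, purity=0.8, ploidy=ploidy, wgd=wgd)
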