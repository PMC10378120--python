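import random

import pytest

from earmeta.core import GenomicInterval, QtlRecord, QtnRecord
from earmeta.io import load_fixtures
from earmeta.simulate import SimulationConfig


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=1)


def make_interval(chrom, start, end):
    return GenomicInterval(str(chrom), start, end)


def make_qtl(rid, study, trait, chrom, start, end):
    return QtlRecord(
        record_id=rid,
        study_id=study,
        trait=trait,
        chrom=str(chrom),
        interval=GenomicInterval(str(chrom), start, end),
    )


def make_qtn(rid, study, trait, chrom, pos):
    return QtnRecord(
        record_id=rid, study_id=study, trait=trait, chrom=str(chrom), pos_bp=pos
    )


def random_interval(rng, chrom="1", lo=0, hi=200):
    start = rng.randrange(lo, hi - 1)
    end = rng.randrange(start + 1, hi)
    return GenomicInterval(chrom, start, end)
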