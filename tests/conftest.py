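import numpy as np
import pytest

from cnvpop.core_io import DepthTrack
from cnvpop.simulate import SimConfig, simulate_all

# Published breed-private CNVR rows (chrom, start, end, printed length, breed,
# n members, printed %, state) used as coordinate-convention fixtures.
TABLE3_ROWS = [
    ("chrA1", 117_723_730, 117_738_524, 14_794, "ABY", 2, 67, "loss"),
    ("chrB2", 74_110_332, 74_120_349, 10_017, "BIR", 2, None, "loss"),
    ("chrD1", 103_586_099, 103_601_179, 15_080, "BIR", 3, None, "loss"),
    ("chrD4", 83_882_234, 83_893_715, 11_481, "BIR", 5, 83, "loss"),
    ("chrE1", 56_306_407, 56_332_265, 25_858, "BIR", 3, None, "loss"),
    ("chrB2", 96_292_366, 96_391_191, 98_825, "BSH", 2, None, "loss"),
    ("chrB3", 70_859_943, 71_389_394, 529_451, "BUR", 2, None, "gain"),
    ("chrB4", 109_221_798, 109_251_945, 30_147, "BUR", 3, 60, "loss"),
    ("chrE2", 28_876_777, 28_888_767, 11_990, "BUR", 3, 60, "loss"),
    ("chrA1", 82_527_688, 82_544_767, 17_079, "MCO", 2, 100, "loss"),
    ("chrC2", 116_748_111, 116_766_145, 18_034, "NAP", 2, None, "loss"),
    ("chrA2", 121_965_379, 121_983_429, 18_050, "OSH", 2, 25, "gain"),
    ("chrB1", 139_721_970, 139_739_225, 17_255, "OSH", 2, 25, "loss"),
    ("chrB2", 110_152_121, 110_360_880, 208_759, "OSH", 2, 25, "loss"),
    ("chrB4", 89_793_534, 89_841_761, 48_227, "OSH", 2, 25, "loss"),
    ("chrC2", 17_974_294, 17_988_686, 14_392, "OSH", 2, 25, "loss"),
]

#: post-exclusion cohort sizes per breed used by the percentage column
BREED_SIZES = {"ABY": 3, "BEN": 2, "BIR": 6, "BSH": 2, "BUR": 5, "EGY": 1,
               "MCO": 2, "NAP": 3, "OSH": 8, "PER": 1, "RAG": 2, "REX": 2,
               "SIA": 3, "SPH": 1}


def make_track(values, window=100, chrom="chrT", sample="S1", chrom_length=None):
    arr = np.asarray(values, dtype=float)
    lengths = {chrom: chrom_length or len(arr) * window}
    return DepthTrack(sample=sample, window_size=window,
                      depths={chrom: arr}, chrom_lengths=lengths)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_true_cnvrs=15, n_chroms=2, chrom_length=4_000_000,
                     samples_per_breed=2, breeds_per_group=2, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_all(small_cfg)
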