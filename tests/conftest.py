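import numpy as np
import pytest

from msiamp import Panel, ReadPair, default_panel
from msiamp.binning import bin_reads, build_lookup
from msiamp.preprocess import MergeFailure, PreprocessConfig, merge_pair


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def bat26_panel(panel):
    """Single-locus panel for fast mononucleotide experiments."""
    return Panel(loci=[panel["BAT26"]], name="bat26-only")


def pairs_from_sample(sample):
    """Convert simulated records into ReadPair objects."""
    return [ReadPair(rid, s1, tuple(q1), s2, tuple(q2))
            for rid, s1, q1, s2, q2 in sample.records]


def merge_all(sample, pre_cfg=None):
    """Merge every simulated pair; returns (merged reads, n_failures)."""
    pre_cfg = pre_cfg or PreprocessConfig()
    merged, failed = [], 0
    for pair in pairs_from_sample(sample):
        m = merge_pair(pair, pre_cfg)
        if isinstance(m, MergeFailure):
            failed += 1
        else:
            merged.append(m)
    return merged, failed


def distributions_for(sample, panel, pre_cfg=None, max_flank_mismatches=0):
    """In-memory merge + bin of a simulated sample."""
    merged, _ = merge_all(sample, pre_cfg)
    dists, _, _ = bin_reads(merged, build_lookup(panel),
                            max_flank_mismatches)
    return dists


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
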