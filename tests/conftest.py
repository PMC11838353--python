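import numpy as np
import pytest

from ibdscan.maps import GeneticMap, build_grid, uniform_map


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def linear_map():
    """One chromosome, 0..100 cM at 1 Mb/cM."""
    return uniform_map({"1": 100.0})


@pytest.fixture
def ten_chrom_map():
    """Ten 100 cM chromosomes at 1 Mb/cM (the calibration geometry)."""
    return uniform_map([100.0] * 10)


@pytest.fixture
def small_grid(linear_map):
    return build_grid(linear_map, delta_cm=0.5, trim_cm=0.0)


def brute_force_coverage(segments_cm, grid_cm):
    """Per-point overlap counts by checking every (segment, point) pair.

    ``segments_cm`` is a list of (start_cm, end_cm); closed intervals.
    """
    counts = np.zeros(len(grid_cm), dtype=int)
    for lo, hi in segments_cm:
        for i, p in enumerate(grid_cm):
            if lo <= p <= hi:
                counts[i] += 1
    return counts


def write_seg_file(path, rows):
    """rows: (s1, h1, s2, h2, chrom, start_bp, end_bp, cm)."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path
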