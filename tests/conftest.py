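import numpy as np
import pytest

import sspgds as s
from sspgds.simulator import SimSpec, simulate_counts


@pytest.fixture(scope="session")
def toy_sizes():
    # three small "chromosomes" (karyotype names so they are retained)
    return {"chr1": 400_000, "chr2": 200_000, "chr3": 300_000}


@pytest.fixture(scope="session")
def toy_grid(toy_sizes):
    return s.make_bins(toy_sizes, 20_000)


@pytest.fixture(scope="session")
def sim_grid():
    """Full hg19-sized 20 kb grid with synthetic GC (SurePlex preset)."""
    return s.make_synthetic_grid("sureplex")


@pytest.fixture(scope="session")
def control_profiles(sim_grid):
    """16 euploid SurePlex-preset control samples (fixed seeds)."""
    return [simulate_counts(SimSpec(sample_id=f"ctrl_{i:02d}", seed=40_000 + i),
                            sim_grid) for i in range(16)]


@pytest.fixture(scope="session")
def fitted_screen(sim_grid, control_profiles):
    """EmbryoScreen fitted on the shared control panel.

    Permutations are reduced to 2,000 (alpha unchanged at 0.01) to keep the
    suite fast; the acceptance script uses the full 10,000.
    """
    screen = s.EmbryoScreen(sim_grid, n_perm=2_000, seed=17)
    screen.fit(control_profiles)
    return screen


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:60000\n"


def sam_line(qname, flag, pos, mapq=60, rname="chr1"):
    rname = "*" if flag & 4 else rname
    pos = 0 if flag & 4 else pos
    return f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"


@pytest.fixture()
def fixture_sam(tmp_path):
    """Hand-constructed 10-read SAM: 6 retained (distinct positions),
    2 unmapped, 1 duplicate-flagged, 1 secondary.

    Retained 0-based starts: 100, 2000, 19998 (bin 0), 20500 (bin 1),
    40000, 45000 (bin 2) -> counts [3, 1, 2].
    """
    lines = [
        sam_line("r_keep1", 0, 101),
        sam_line("r_dupfl", 1024, 101),          # duplicate-flagged
        sam_line("r_keep2", 0, 2001),
        sam_line("r_secon", 256, 2001),          # secondary record
        sam_line("r_keep3", 16, 19999),
        sam_line("r_keep4", 0, 20501),
        sam_line("r_keep5", 0, 40001),
        sam_line("r_keep6", 16, 45001),
        sam_line("r_unmp1", 4, 0),
        sam_line("r_unmp2", 4, 0),
    ]
    path = tmp_path / "fixture.sam"
    path.write_text(SAM_HEADER + "".join(lines))
    return path
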