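import numpy as np
import pytest

from ascotwalk.junctions import Junction, JunctionTable
from ascotwalk.simulate import uniform_count_table


@pytest.fixture
def toy_table():
    """Three junctions forming one cassette (exon [150, 159]) over two samples."""
    return uniform_count_table(
        {"chr1": {(100, 199), (100, 149), (160, 199)}}, count=30, samples=["s1", "s2"]
    )


@pytest.fixture
def make_table():
    """Factory: junction coordinate dict -> table with chosen counts."""

    def build(coords_by_chrom, counts_by_coord=None, samples=("s1", "s2"), default=30):
        junctions = []
        n = len(samples)
        for chrom, coords in coords_by_chrom.items():
            for coord in sorted(coords):
                vec = (counts_by_coord or {}).get(coord, [default] * n)
                junctions.append(
                    Junction(
                        chrom=chrom,
                        start=coord[0],
                        end=coord[1],
                        strand="+",
                        counts=np.asarray(vec, dtype=np.int64),
                    )
                )
        return JunctionTable(junctions=junctions, samples=list(samples))

    return build
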