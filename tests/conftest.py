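import numpy as np
import pandas as pd
import pytest

from adipomem.regions import RegionSet
from adipomem.simulate import SimConfig


@pytest.fixture(scope="session")
def tiny_config():
    """Complete condition ladder at reduced scale for fast end-to-end runs."""
    return SimConfig(
        n_genes=120, n_chroms=2, chrom_length=4_000_000,
        n_cells_per_condition=50,
        gene_counts={"memory_up": 10, "memory_down": 10,
                     "restored_up": 10, "restored_down": 10},
        region_counts={"gain_maintained": 5, "gain_lost": 5,
                       "loss_maintained": 5, "loss_regained": 5, "wl_only": 5},
        n_distal_regions=60, n_enhancer_runs=80,
        qc_min_features=20, qc_max_features=120, qc_max_umi=100_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def study_config():
    """The default study-scale configuration with a fixed seed."""
    return SimConfig(seed=1)


def random_region_set(rng, n_intervals, genome_size, chroms=("chrA", "chrB")):
    chrom = rng.choice(chroms, size=n_intervals)
    start = rng.integers(0, genome_size - 1, size=n_intervals)
    length = rng.integers(1, max(2, genome_size // 20), size=n_intervals)
    end = np.minimum(start + length, genome_size)
    return RegionSet(
        pd.DataFrame({"chrom": chrom, "start": start, "end": end}),
        genome_size=genome_size * len(chroms))


class BitmapGenome:
    """Per-base-pair boolean-mask oracle for interval arithmetic."""

    def __init__(self, regions: RegionSet, genome_size: int,
                 chroms=("chrA", "chrB")):
        self.size = genome_size
        self.chroms = chroms
        self.masks = {c: np.zeros(genome_size, dtype=bool) for c in chroms}
        for row in regions.df.itertuples(index=False):
            self.masks[row.chrom][row.start:row.end] = True

    def total_bp(self):
        return sum(int(m.sum()) for m in self.masks.values())

    def overlap_bp(self, other):
        return sum(int((self.masks[c] & other.masks[c]).sum())
                   for c in self.chroms)

    def union_intervals(self):
        rows = []
        for c in self.chroms:
            m = self.masks[c]
            padded = np.concatenate([[False], m, [False]])
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for s, e in zip(edges[::2], edges[1::2]):
                rows.append((c, int(s), int(e)))
        return rows
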