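import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phindex import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticCommunityConfig(
        n_prokaryote_genomes=10,
        n_free_viruses=10,
        prophage_fraction=0.5,
        genome_length_range=(200_000, 500_000),
        viral_length_range=(10_000, 60_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return syn.make_community(small_config)


@pytest.fixture(scope="session")
def genome_lengths(small_community):
    genomes, _ = small_community
    return pd.Series({g.genome_id: g.length for g in genomes})


def brute_force_average_linkage(points: np.ndarray):
    """Independent UPGMA oracle: naive agglomeration over explicit clusters.

    Returns the ordered list of merge heights.
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [
                        np.linalg.norm(points[i] - points[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights
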