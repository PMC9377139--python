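"""Relative-abundance profiles and their condition responses.

Read counts are turned into genome counts per million (CPM): counts are
divided by genome length, and each sample column is rescaled to sum to one
million, so 10,000 CPM corresponds to 1% of the community.  Condition
responses are log2 ratios of CPM against a reference (the mean across
conditions, a control sample, or the inoculum); profiles are compared by
Spearman correlation and grouped by average-linkage (UPGMA) hierarchical
clustering on Euclidean distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, NormalizationError, UndefinedStatisticError
from .errors import PhindexError

#: log2 ratios are finite even at zero counts thanks to this CPM pseudocount
DEFAULT_PSEUDOCOUNT_CPM = 0.5

#: at or below this many observations the Spearman p-value is computed by
#: exhaustive permutation; above it, by the t approximation
SPEARMAN_EXACT_MAX_N = 10


def cpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Genome-count-per-million normalization.

    CPM(g, s) = [count(g,s)/length(g)] / sum_g'[count(g',s)/length(g')] x 1e6.
    Accounts for both genome length and sequencing depth; every column of
    the result sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise ConfigurationError(f"missing genome lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ConfigurationError("genome lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ConfigurationError("counts must be nonnegative")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(f"all-zero count column(s): {list(zero.index)}")
    return rate.div(totals, axis=1) * 1e6


def cpm_to_percent(cpm: float | np.ndarray | pd.DataFrame):
    """CPM expressed as a percentage of the community (CPM / 10,000)."""
    return cpm / 10_000.0


def log_ratio(
    abundance: pd.DataFrame,
    reference: str = "mean",
    reference_samples: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> pd.DataFrame:
    """Per-genome log2 ratio of CPM against a reference.

    ``reference`` is either ``"mean"`` (mean CPM across
    ``reference_samples``, defaulting to all samples) or the label of a
    reference sample (control or inoculum).  Positive values mean above
    reference.
    """
    if reference == "mean":
        cols = list(reference_samples) if reference_samples is not None else list(
            abundance.columns
        )
        missing = [c for c in cols if c not in abundance.columns]
        if missing:
            raise ConfigurationError(f"reference samples absent: {missing}")
        ref = abundance[cols].mean(axis=1)
    else:
        if reference not in abundance.columns:
            raise ConfigurationError(f"reference sample absent: {reference!r}")
        ref = abundance[reference]
    return np.log2(abundance.add(pseudocount)).sub(
        np.log2(ref + pseudocount), axis=0
    )


def coefficient_of_variation(values: Sequence[float], ddof: int = 0) -> float:
    """Standard deviation divided by the mean (population sd by default)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UndefinedStatisticError("CV needs at least 2 observations")
    mean = arr.mean()
    if mean <= 0:
        raise UndefinedStatisticError("CV undefined for non-positive mean")
    return float(arr.std(ddof=ddof) / mean)


def top_n_genomes(
    abundance: pd.DataFrame, n: int, ranking_samples: Sequence[str] | None = None
) -> list[str]:
    """The n most abundant genomes by mean CPM over the ranking samples.

    Viral genomes are conventionally ranked on supernatant samples,
    prokaryotes on pellet samples.  Ties break lexicographically by genome
    id for reproducibility.
    """
    cols = list(ranking_samples) if ranking_samples is not None else list(abundance.columns)
    if not cols:
        raise ConfigurationError("ranking sample set is empty")
    missing = [c for c in cols if c not in abundance.columns]
    if missing:
        raise ConfigurationError(f"ranking samples absent: {missing}")
    if n > len(abundance.index):
        raise ConfigurationError("n exceeds the number of genomes")
    means = abundance[cols].mean(axis=1)
    order = sorted(abundance.index, key=lambda g: (-means[g], g))
    return order[:n]


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for the Spearman statistic.

    Enumerates all n! pairings of the rank vectors; feasible for n <= 10.
    """
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk):
        nonlocal count, total
        if not chunk:
            return
        perm = np.array(chunk)
        rhos = (yc[perm] * xc).sum(axis=1) / denom
        count += int((np.abs(rhos) >= target).sum())
        total += len(chunk)

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) >= 50_000:
            flush(chunk)
            chunk = []
    flush(chunk)
    return count / total


def condition_spearman(
    response: pd.DataFrame | None,
    condition_a: str | Sequence[float],
    condition_b: str | Sequence[float] = None,
) -> tuple[float, float]:
    """Spearman rank correlation between two condition-response vectors.

    Accepts either a response matrix plus two column labels, or two raw
    vectors (``response=None``).  Ties receive average ranks.  The two-sided
    p-value is exact (full permutation enumeration) for n <= 10 and uses
    the t approximation otherwise.
    """
    if response is not None:
        x = response[condition_a].to_numpy(dtype=float)
        y = response[condition_b].to_numpy(dtype=float)
    else:
        x = np.asarray(condition_a, dtype=float)
        y = np.asarray(condition_b, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("Spearman needs at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(xr, yr, rho)
    else:
        rho_s, p_s = stats.spearmanr(x, y)
        rho, p = float(rho_s), float(p_s)
    return rho, min(1.0, float(p))


@dataclass
class ClusteringResult:
    leaves: list[str]
    linkage: np.ndarray
    labels: pd.Series | None
    newick: str


def _linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z, rd=False)

    def walk(node, parent_height):
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{bl:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def cluster_responses(
    response: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
) -> ClusteringResult:
    """Average-linkage (UPGMA) clustering of response profiles.

    Rows are genomes, columns conditions; the metric is Euclidean distance
    between log-ratio row vectors.  Cluster labels come from cutting the
    tree at ``k`` clusters or at ``height``; the full tree is serialized as
    Newick.
    """
    X = response.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise PhindexError("clustering needs at least 2 genomes")
    if not np.isfinite(X).all():
        raise PhindexError("response matrix contains non-finite entries")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    labels = None
    if k is not None:
        labels = pd.Series(
            hierarchy.fcluster(Z, t=k, criterion="maxclust"), index=response.index
        )
    elif height is not None:
        labels = pd.Series(
            hierarchy.fcluster(Z, t=height, criterion="distance"), index=response.index
        )
    newick = _linkage_to_newick(Z, list(response.index))
    return ClusteringResult(list(response.index), Z, labels, newick)
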