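"""Consensus taxonomy voting and gene-family statistics.

Viral genomes are assigned taxonomy by majority vote over their per-ORF
hits against a pVOG-style profile database: ranks are walked from order
down to species, at each rank keeping the taxon supported by a strict
majority of the ORFs that carry an assignment at that rank (and whose path
is consistent with the levels already assigned), stopping at the first
rank without one.  Gene-family enrichment between viral and prokaryotic
genomes (e.g. the GH33 sialidase family) is tested with Fisher's exact
test on the 2x2 table of family-annotated vs other annotated ORFs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .errors import ConsistencyError


@dataclass(frozen=True)
class TaxonomyAssignment:
    path: tuple[str, ...]
    rank_depth: int  # number of ranks assigned; 0 = unclassified

    @property
    def label(self) -> str:
        return ";".join(self.path) if self.path else "unclassified"


def consensus_taxonomy(
    orf_paths: Iterable[str | Sequence[str]],
    min_fraction: float = 0.5,
) -> TaxonomyAssignment:
    """Majority-vote consensus taxonomy over per-ORF taxon paths.

    Each path is a ";"-separated string (or sequence) from highest rank to
    lowest.  At each rank the vote is taken among ORFs with an assignment
    at that rank whose higher ranks match the consensus so far; a taxon
    needs a strict > ``min_fraction`` share to win.  An empty hit set
    yields an unclassified assignment (not an error).
    """
    paths = [
        tuple(p.split(";")) if isinstance(p, str) else tuple(p) for p in orf_paths
    ]
    paths = [tuple(part.strip() for part in p if str(part).strip()) for p in paths]
    paths = [p for p in paths if p]
    assigned: list[str] = []
    depth = 0
    while True:
        candidates = [
            p[depth]
            for p in paths
            if len(p) > depth and tuple(p[:depth]) == tuple(assigned)
        ]
        if not candidates:
            break
        counts = Counter(candidates)
        taxon, n = counts.most_common(1)[0]
        if n <= min_fraction * len(candidates):
            break
        assigned.append(taxon)
        depth += 1
    return TaxonomyAssignment(tuple(assigned), depth)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows (family hits, other hits), columns (viral, prokaryotic)."""

    viral_hits: int
    viral_other: int
    prok_hits: int
    prok_other: int

    def as_array(self):
        return [[self.viral_hits, self.prok_hits], [self.viral_other, self.prok_other]]


def family_enrichment(
    hits: pd.DataFrame,
    family: str,
    viral_genomes: Set[str],
    prokaryotic_genomes: Set[str],
) -> tuple[ContingencyTable, float, float]:
    """Fisher's exact test for over-representation of one gene family.

    ``hits`` needs columns genome, orf, label; the unit of counting is the
    annotated ORF.  Returns (table, conditional odds ratio, two-sided p);
    the two-sided p sums hypergeometric point probabilities no larger than
    the observed table's.
    """
    overlap = viral_genomes & prokaryotic_genomes
    if overlap:
        raise ConsistencyError(f"genome sets overlap: {sorted(overlap)[:5]}")
    viral = hits[hits.genome.isin(viral_genomes)]
    prok = hits[hits.genome.isin(prokaryotic_genomes)]
    table = ContingencyTable(
        viral_hits=int((viral.label == family).sum()),
        viral_other=int((viral.label != family).sum()),
        prok_hits=int((prok.label == family).sum()),
        prok_other=int((prok.label != family).sum()),
    )
    arr = table.as_array()
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    try:
        or_ = float(_odds_ratio(arr, kind="conditional").statistic)
    except ValueError:
        or_ = float("nan")
    return table, or_, float(p)


def cluster_specific_profiles(
    cluster_labels: Mapping[str, object],
    profile_hits: Mapping[str, Set[str]],
) -> tuple[pd.Series, int, int]:
    """Which HMM profiles are specific to a single response cluster.

    A profile is cluster-specific when every genome hitting it carries the
    same cluster label.  Returns (per-profile flag, number specific,
    percentage rounded to the nearest integer).
    """
    flags = {}
    for profile, genomes in profile_hits.items():
        labels = set()
        for g in genomes:
            if g not in cluster_labels:
                raise ConsistencyError(f"genome {g!r} has no cluster label")
            labels.add(cluster_labels[g])
        flags[profile] = len(labels) == 1
    series = pd.Series(flags, dtype=bool)
    n_specific = int(series.sum())
    pct = round(100.0 * n_specific / len(series)) if len(series) else 0
    return series, n_specific, pct
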