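"""Prophage induction detection from virus/host coverage ratios.

Genomes carrying an integrated prophage are split into a viral part (the
annotated prophage intervals) and a host part (everything else).  In each
sample, the mean per-contig read coverage of each part is computed; a part
is considered present when its coverage reaches 0.01x.  When both parts
are present, the virus/host coverage ratio is the induction statistic: a
lysogenic prophage replicates with its host and keeps the ratio near 1,
while an induced (lytic) prophage replicates independently and drives the
ratio far above it.  A prophage is called putatively induced in a sample
when the ratio strictly exceeds 10 (a cutoff chosen where the empirical
ratio distribution plateaus, beyond coverage noise).

Samples where reads map only onto the viral part are excluded from
induction calling and flagged separately: the most likely explanation is
the virus infecting a different host, not induction.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import abundance
from .errors import FormatError, IntervalError, UndefinedStatisticError
from .synthetic import GenomeRecord

PRESENCE_THRESHOLD = 0.01
RATIO_CUTOFF = 10.0
DEFAULT_SUBSAMPLE_READS = 10_000_000

PRESENCE_CLASSES = ("both", "host_only", "virus_only", "neither")


@dataclass(frozen=True)
class SplitGenome:
    """A prophage-carrying genome split into host and viral parts.

    A contig belongs to the viral part when the majority of its length lies
    inside prophage intervals (in the usual case the prophage occupies its
    own contig entirely).  Lengths are exact interval arithmetic:
    host_length + virus_length equals the original genome length.
    """

    mag_id: str
    host_contigs: tuple[str, ...]
    virus_contigs: tuple[str, ...]
    virus_intervals: tuple[tuple[str, int, int], ...]
    host_length: int
    virus_length: int


def split_prophage(
    genome: GenomeRecord,
    regions: Sequence[tuple[str, int, int]] | None = None,
) -> SplitGenome:
    """Split a genome at its prophage intervals (0-based, half-open).

    Raises IntervalError for an empty interval list (the genome does not
    belong in the split set) or for overlapping / out-of-bounds intervals.
    """
    regions = list(regions if regions is not None else genome.prophage_regions)
    if not regions:
        raise IntervalError(f"{genome.genome_id}: no prophage intervals to split on")
    contig_len = {c.contig_id: c.length for c in genome.contigs}
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in regions:
        if contig not in contig_len:
            raise IntervalError(f"{genome.genome_id}: unknown contig {contig!r}")
        if not 0 <= start < end <= contig_len[contig]:
            raise IntervalError(
                f"{genome.genome_id}: interval [{start}, {end}) outside contig "
                f"{contig!r} of length {contig_len[contig]}"
            )
        per_contig.setdefault(contig, []).append((start, end))
    virus_length = 0
    virus_contigs = []
    host_contigs = []
    for contig, ln in contig_len.items():
        ivs = sorted(per_contig.get(contig, []))
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise IntervalError(
                    f"{genome.genome_id}: overlapping intervals on {contig!r}"
                )
        covered = sum(e - s for s, e in ivs)
        virus_length += covered
        if ivs and covered * 2 > ln:
            virus_contigs.append(contig)
        else:
            host_contigs.append(contig)
    total = sum(contig_len.values())
    return SplitGenome(
        mag_id=genome.genome_id,
        host_contigs=tuple(host_contigs),
        virus_contigs=tuple(virus_contigs),
        virus_intervals=tuple((c, s, e) for c in sorted(per_contig) for s, e in sorted(per_contig[c])),
        host_length=total - virus_length,
        virus_length=virus_length,
    )


def genome_coverage(contig_coverages: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-contig coverage values.

    The mean is deliberately not length-weighted: each contig contributes
    one value regardless of its size.
    """
    vals = np.asarray(list(contig_coverages), dtype=float)
    if vals.size == 0:
        raise UndefinedStatisticError("no contig coverage values to average")
    return float(vals.mean())


def classify_presence(
    host_coverage: float,
    virus_coverage: float,
    threshold: float = PRESENCE_THRESHOLD,
) -> str:
    """Presence class from mean coverages, inclusive at the threshold."""
    if host_coverage < 0 or virus_coverage < 0:
        raise UndefinedStatisticError("coverage values must be nonnegative")
    host = host_coverage >= threshold
    virus = virus_coverage >= threshold
    if host and virus:
        return "both"
    if host:
        return "host_only"
    if virus:
        return "virus_only"
    return "neither"


def call_induction(
    host_coverage: float,
    virus_coverage: float,
    ratio_cutoff: float = RATIO_CUTOFF,
) -> tuple[bool, float]:
    """Induction call from the raw virus/host coverage ratio.

    Returns (induced, ratio); induced iff ratio strictly exceeds the
    cutoff.  The ratio is infinite when the host has zero coverage.
    """
    ratio = virus_coverage / host_coverage if host_coverage > 0 else float("inf")
    return ratio > ratio_cutoff, ratio


def induction_table(
    coverage: pd.DataFrame,
    splits: Sequence[SplitGenome],
    threshold: float = PRESENCE_THRESHOLD,
    ratio_cutoff: float = RATIO_CUTOFF,
) -> pd.DataFrame:
    """Per (sample, MAG) induction records from a per-contig coverage table.

    ``coverage`` needs columns sample, contig, coverage.  For each sample
    and split genome the host and viral parts are averaged separately,
    presence classified, and induction called only when the virus is
    detected together with its host (virus_only cases are flagged, not
    called).  Columns: sample, mag, host_coverage, virus_coverage, ratio,
    presence, induced.
    """
    by_sample = {s: dict(zip(g.contig, g.coverage)) for s, g in coverage.groupby("sample")}
    rows = []
    for sample, cov in sorted(by_sample.items()):
        for sg in splits:
            host_vals = [cov[c] for c in sg.host_contigs if c in cov]
            virus_vals = [cov[c] for c in sg.virus_contigs if c in cov]
            host_cov = genome_coverage(host_vals) if host_vals else 0.0
            virus_cov = genome_coverage(virus_vals) if virus_vals else 0.0
            presence = classify_presence(host_cov, virus_cov, threshold)
            if presence == "both":
                induced, ratio = call_induction(host_cov, virus_cov, ratio_cutoff)
            else:
                induced = False
                ratio = np.nan
            rows.append((sample, sg.mag_id, host_cov, virus_cov, ratio, presence, induced))
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "mag",
            "host_coverage",
            "virus_coverage",
            "ratio",
            "presence",
            "induced",
        ],
    )


def cooccurrence_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages (1 d.p.) per presence class over all
    evaluations of the rectangular sample x genome design."""
    total = len(records)
    rows = []
    for cls in PRESENCE_CLASSES:
        n = int((records["presence"] == cls).sum())
        pct = round(100.0 * n / total, 1) if total else 0.0
        rows.append((cls, n, pct))
    return pd.DataFrame(rows, columns=["presence", "count", "percent"])


def group_abundance_test(
    coverages: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-provirus two-group comparison of coverage (Mann-Whitney U).

    ``coverages`` is provirus x sample; ``groups`` maps sample labels to
    group labels (e.g. mesophilic vs thermophilic).  The test is two-sided
    with tie correction (exact when sample sizes are small and untied).
    A provirus is flagged "higher in" the group with the greater mean rank
    when p < alpha.  Columns: provirus, U, p, direction, significant.
    """
    from scipy import stats

    a_cols = [s for s in coverages.columns if groups.get(s) == group_a]
    b_cols = [s for s in coverages.columns if groups.get(s) == group_b]
    if not a_cols or not b_cols:
        raise UndefinedStatisticError("both groups must be non-empty")
    rows = []
    for provirus, row in coverages.iterrows():
        a = row[a_cols].to_numpy(dtype=float)
        b = row[b_cols].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            u = len(a) * len(b) / 2.0
            p = 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            u, p = float(res.statistic), float(res.pvalue)
        ranks = stats.rankdata(np.concatenate([a, b]))
        direction = group_a if ranks[: len(a)].mean() > ranks[len(a):].mean() else group_b
        significant = p < alpha
        rows.append((provirus, u, p, direction if significant else "", significant))
    return pd.DataFrame(rows, columns=["provirus", "U", "p", "direction", "significant"])


def group_test_summary(results: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """Counts and whole-percent shares of proviruses higher in each group."""
    n = len(results)
    higher_a = int((results.direction == group_a).sum())
    higher_b = int((results.direction == group_b).sum())
    return {
        "n": n,
        f"higher_in_{group_a}": higher_a,
        f"higher_in_{group_a}_percent": round(100.0 * higher_a / n) if n else 0,
        f"higher_in_{group_b}": higher_b,
        f"higher_in_{group_b}_percent": round(100.0 * higher_b / n) if n else 0,
        "not_significant": n - higher_a - higher_b,
    }


def ratio_log_profiles(
    records: pd.DataFrame, pseudocount: float = PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """MAG x sample matrix of log2 virus/host coverage ratios.

    Both coverages get the presence threshold as pseudocount, which bounds
    the dynamic range and keeps entries finite when one part is absent.
    """
    v = records.pivot(index="mag", columns="sample", values="virus_coverage")
    h = records.pivot(index="mag", columns="sample", values="host_coverage")
    return np.log2((v + pseudocount) / (h + pseudocount))


def cluster_ratio_profiles(
    log_ratios: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
) -> abundance.ClusteringResult:
    """Average-linkage Euclidean clustering of log2 ratio profiles.

    Delegates to the shared response-profile clustering with identical
    contracts.
    """
    return abundance.cluster_responses(log_ratios, k=k, height=height)


# ---------------------------------------------------------------------------
# FASTQ subsampling


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path) -> Iterable[tuple[str, str, str]]:
    """Yield FASTQ records as (title, sequence, quality) tuples."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(
                    f"malformed FASTQ record at index {idx} in {path}: {exc}"
                ) from exc
            yield rec
            idx += 1


def subsample_reads(
    fastq: str | Path,
    n: int = DEFAULT_SUBSAMPLE_READS,
    seed: int = 0,
    mate: str | Path | None = None,
) -> list[tuple[str, str, str]] | tuple[list, list]:
    """Uniform random subsample of exactly min(n, total) reads.

    Reservoir sampling (single pass, no replacement), deterministic per
    seed.  When ``mate`` is given the two files are sampled in lockstep:
    the same record indices are kept in both.  Records are returned as
    (title, sequence, quality) tuples in reservoir order.
    """
    if n <= 0:
        raise FormatError("n must be > 0")
    rng = np.random.default_rng(seed)
    if mate is None:
        reservoir: list = []
        for i, rec in enumerate(_iter_fastq(fastq)):
            if i < n:
                reservoir.append(rec)
            else:
                j = int(rng.integers(0, i + 1))
                if j < n:
                    reservoir[j] = rec
        return reservoir
    r1: list = []
    r2: list = []
    it1, it2 = _iter_fastq(fastq), _iter_fastq(mate)
    i = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            break
        if rec1 is None or rec2 is None:
            raise FormatError("paired FASTQ files have different record counts")
        if i < n:
            r1.append(rec1)
            r2.append(rec2)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                r1[j] = rec1
                r2[j] = rec2
        i += 1
    return r1, r2


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
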