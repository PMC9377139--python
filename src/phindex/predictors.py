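"""Viral-predictor consensus calling and bin triage.

Four predictors vote on each contig.  Per-tool filters are applied first:
PPR-Meta needs a viral score >= 0.75; CheckV calls are suppressed when the
quality tier is "not determined" AND no viral genes were detected; VIBRANT
and PHASTER votes pass unfiltered.  A contig is called viral when PHASTER
alone says so, or when at least two of the other three tools agree.  Bins
are then triaged into prokaryotic MAGs, viral MAGs and unclassified
contigs, with small bins discarded and oversized viral bins dissolved into
single-contig viral genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ConsistencyError, FormatError

TOOLS = ("PHASTER", "CheckV", "PPR-Meta", "VIBRANT")
PPR_SCORE_MIN = 0.75
MIN_BIN_SIZE = 10_000
VIRAL_SPLIT_LENGTH = 200_000


def _is_not_determined(quality: str | None) -> bool:
    if quality is None:
        return True
    return quality.strip().lower().replace("-", " ").replace("_", " ") in (
        "",
        "not determined",
        "nd",
        "na",
    )


@dataclass(frozen=True)
class PredictorEvidence:
    """One tool's filtered verdict on one contig."""

    contig_id: str
    tool: str
    is_viral_vote: bool
    ppr_score: float | None = None
    checkv_quality: str | None = None
    checkv_viral_genes: int | None = None


def filter_tool_vote(
    contig_id: str,
    tool: str,
    predicted_viral: bool,
    score: float | None = None,
    quality: str | None = None,
    viral_genes: int | None = None,
) -> PredictorEvidence:
    """Apply the per-tool filter to one raw predictor record.

    The vote is true iff the tool predicted viral AND passes its filter.
    """
    if tool not in TOOLS:
        raise FormatError(f"unknown predictor tool: {tool!r}")
    vote = bool(predicted_viral)
    if tool == "PPR-Meta":
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise FormatError("PPR-Meta record lacks a viral score")
        vote = vote and score >= PPR_SCORE_MIN
        return PredictorEvidence(contig_id, tool, vote, ppr_score=float(score))
    if tool == "CheckV":
        genes = 0 if viral_genes is None else int(viral_genes)
        if vote and _is_not_determined(quality) and genes == 0:
            vote = False
        return PredictorEvidence(
            contig_id, tool, vote, checkv_quality=quality, checkv_viral_genes=genes
        )
    return PredictorEvidence(contig_id, tool, vote)


def consensus_viral_call(votes: Iterable[PredictorEvidence]) -> bool:
    """True iff PHASTER votes viral, or >= 2 of {CheckV, PPR-Meta, VIBRANT} do."""
    seen: dict[str, bool] = {}
    for v in votes:
        if v.tool in seen:
            raise ConsistencyError(f"duplicate vote for tool {v.tool!r}")
        if v.tool not in TOOLS:
            raise FormatError(f"unknown predictor tool: {v.tool!r}")
        seen[v.tool] = v.is_viral_vote
    if seen.get("PHASTER", False):
        return True
    others = sum(seen.get(t, False) for t in ("CheckV", "PPR-Meta", "VIBRANT"))
    return others >= 2


def consensus_calls(evidence: pd.DataFrame) -> dict[str, bool]:
    """Filtered consensus call per contig from a normalized evidence table.

    Expects columns: contig, tool, predicted_viral, score, quality,
    viral_genes (as written by the synthetic generator or the normalized
    predictor TSV reader).
    """
    calls: dict[str, bool] = {}
    for contig, grp in evidence.groupby("contig", sort=False):
        votes = [
            filter_tool_vote(
                contig,
                row.tool,
                bool(row.predicted_viral),
                score=getattr(row, "score", None),
                quality=getattr(row, "quality", None),
                viral_genes=getattr(row, "viral_genes", None),
            )
            for row in grp.itertuples()
        ]
        calls[str(contig)] = consensus_viral_call(votes)
    return calls


@dataclass(frozen=True)
class BinAssignment:
    bin_id: str
    contig_ids: tuple[str, ...]
    total_length: int
    klass: str  # "MAG" | "virMAG" | "unclassified"
    tier: str | None = None
    completeness: float | None = None
    contamination: float | None = None


@dataclass
class TriageResult:
    """Outcome of bin triage.

    Every input contig lands in exactly one of: a retained bin
    (``assignments``), a dissolved-viral-bin singleton
    (``viral_singletons``), or ``discarded_contigs`` (member of a bin below
    the minimum size).
    """

    assignments: list[BinAssignment]
    viral_singletons: list[BinAssignment]
    discarded_bins: list[str]
    discarded_contigs: list[str]


def mimag_miuvig_tier(
    completeness: float, contamination: float | None, klass: str
) -> str:
    """Quality tier per the MIMAG (prokaryote) / MIUViG (virus) standards.

    MAGs: high (completeness > 90, contamination < 5), medium
    (completeness >= 50, contamination < 10), else low.  virMAGs: complete
    (completeness == 100), high (>= 90), else genome-fragment.
    """
    if not 0.0 <= completeness <= 100.0:
        raise ConfigurationError("completeness must lie in [0, 100]")
    if contamination is not None and not 0.0 <= contamination <= 100.0:
        raise ConfigurationError("contamination must lie in [0, 100]")
    if klass == "MAG":
        if contamination is None:
            raise ConfigurationError("MAG tier requires a contamination value")
        if completeness > 90 and contamination < 5:
            return "high"
        if completeness >= 50 and contamination < 10:
            return "medium"
        return "low"
    if klass == "virMAG":
        if completeness == 100:
            return "complete"
        if completeness >= 90:
            return "high"
        return "genome-fragment"
    raise ConfigurationError(f"unknown class for quality tier: {klass!r}")


def triage_bins(
    bin_membership: Mapping[str, Sequence[str]],
    contig_lengths: Mapping[str, int],
    consensus: Mapping[str, bool],
    quality: Mapping[str, tuple[float, float]] | None = None,
    min_bin_size: int = MIN_BIN_SIZE,
    viral_majority: float = 0.5,
    viral_split_length: int = VIRAL_SPLIT_LENGTH,
) -> TriageResult:
    """Triage bins into MAG / virMAG / unclassified.

    Bins below ``min_bin_size`` bp are discarded.  A bin is viral when more
    than ``viral_majority`` of its length lies in consensus-viral contigs;
    otherwise it is a MAG when CheckM-style quality metrics are available,
    unclassified when not.  Viral bins longer than ``viral_split_length``
    are dissolved into single-contig viral genomes.
    """
    quality = quality or {}
    seen: dict[str, str] = {}
    for bin_id, contigs in bin_membership.items():
        for c in contigs:
            if c in seen:
                raise ConsistencyError(
                    f"contig {c!r} appears in bins {seen[c]!r} and {bin_id!r}"
                )
            seen[c] = bin_id

    assignments: list[BinAssignment] = []
    singletons: list[BinAssignment] = []
    discarded_bins: list[str] = []
    discarded_contigs: list[str] = []

    for bin_id, contigs in bin_membership.items():
        contigs = tuple(contigs)
        lengths = {c: int(contig_lengths[c]) for c in contigs}
        total = sum(lengths.values())
        if total < min_bin_size:
            discarded_bins.append(bin_id)
            discarded_contigs.extend(contigs)
            continue
        viral_len = sum(ln for c, ln in lengths.items() if consensus.get(c, False))
        if viral_len / total > viral_majority:
            if total > viral_split_length:
                for c in contigs:
                    singletons.append(
                        BinAssignment(
                            bin_id=c, contig_ids=(c,), total_length=lengths[c], klass="virMAG"
                        )
                    )
            else:
                assignments.append(
                    BinAssignment(bin_id, contigs, total, "virMAG")
                )
        elif bin_id in quality:
            comp, cont = quality[bin_id]
            assignments.append(
                BinAssignment(
                    bin_id,
                    contigs,
                    total,
                    "MAG",
                    tier=mimag_miuvig_tier(comp, cont, "MAG"),
                    completeness=comp,
                    contamination=cont,
                )
            )
        else:
            assignments.append(BinAssignment(bin_id, contigs, total, "unclassified"))

    return TriageResult(assignments, singletons, discarded_bins, discarded_contigs)
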