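"""Synthetic metagenome communities with planted ground truth.

The generator builds what a stress-perturbation experiment on an anaerobic
digester yields after assembly, binning and read mapping: a community of
prokaryotic genomes (a fraction of which carry one integrated prophage),
free viral genomes, per-condition abundance shifts, read counts sampled
multinomially in proportion to abundance x genome length, per-contig
coverage with multiplicative noise, and a planted set of (sample, prophage)
induction events that elevate prophage coverage relative to the host.
Every downstream stage of the pipeline is testable against this truth
without any sequencing data.

Conventions
-----------
* One sample per condition; sample labels equal condition labels.
* Each prophage occupies a dedicated contig whose full span is the prophage
  region, so splitting genomes into viral and non-viral parts is exact.
* Coverage noise is lognormal with unit mean, parameterized by its
  coefficient of variation (CV): ``sigma^2 = ln(1 + CV^2)``,
  ``mu = -sigma^2 / 2``.
* Condition effects (log2 multipliers) are drawn i.i.d. normal and then
  recentred per condition so that the community abundance total is
  identical across conditions.  Compositional data only identify effects up
  to a per-sample offset; storing the identifiable effects makes noise-free
  log-ratio recovery exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PREDICTOR_TOOLS = ("PHASTER", "CheckV", "PPR-Meta", "VIBRANT")

_CHECKV_POSITIVE_TIERS = ("Complete", "High-quality", "Medium-quality", "Low-quality")


@dataclass(frozen=True)
class Contig:
    contig_id: str
    length: int


@dataclass(frozen=True)
class GenomeRecord:
    """A prokaryotic MAG or a free viral genome.

    ``prophage_regions`` holds 0-based half-open ``(contig_id, start, end)``
    intervals; at most one region per genome is generated here.
    """

    genome_id: str
    klass: str  # "prokaryote" | "virus"
    contigs: tuple[Contig, ...]
    prophage_regions: tuple[tuple[str, int, int], ...] = ()

    @property
    def length(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def has_prophage(self) -> bool:
        return len(self.prophage_regions) > 0


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic community."""

    basis_abundance: pd.DataFrame       # genome x condition, columns sum to 1
    condition_multiplier: pd.DataFrame  # genome x condition, log2 effects
    induced_set: set[tuple[str, str]]   # (sample, prophage-carrier genome)
    true_fold: dict[tuple[str, str], float]
    conditions: tuple[str, ...]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.basis_abundance.equals(other.basis_abundance)
            and self.condition_multiplier.equals(other.condition_multiplier)
            and self.induced_set == other.induced_set
            and self.true_fold == other.true_fold
            and self.conditions == other.conditions
        )


@dataclass(frozen=True)
class SyntheticCommunityConfig:
    """Study conditions for the synthetic community.

    Defaults mirror the structure of a stress-perturbation digester
    experiment: a control plus four DNA-damaging stresses, roughly half of
    the prokaryotes carrying one integrated prophage, viral genome lengths
    inside the 1.5-200 kbp span typical of tailed phages, and induction
    folds large relative to coverage noise.
    """

    n_prokaryote_genomes: int = 30
    n_free_viruses: int = 60
    prophage_fraction: float = 0.5
    genome_length_range: tuple[int, int] = (1_500_000, 4_000_000)
    viral_length_range: tuple[int, int] = (5_000, 150_000)
    conditions: tuple[str, ...] = (
        "control",
        "overload",
        "microaeration",
        "basic_pH",
        "peroxide",
    )
    effect_sd: float = 0.5
    read_depth: int = 1_000_000
    coverage_noise_cv: float = 0.2
    induction_rate: float = 0.1
    induction_fold_range: tuple[float, float] = (20.0, 200.0)
    coverage_depth_scale: float = 1_000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_prokaryote_genomes < 1:
            raise ConfigurationError("n_prokaryote_genomes must be >= 1")
        if self.n_free_viruses < 0:
            raise ConfigurationError("n_free_viruses must be >= 0")
        for name in ("prophage_fraction", "induction_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("genome_length_range", "viral_length_range", "induction_fold_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must have min <= max")
        if min(self.genome_length_range) <= 0 or min(self.viral_length_range) <= 0:
            raise ConfigurationError("genome_length_range and viral_length_range must be positive")
        if self.induction_fold_range[0] <= 1.0:
            raise ConfigurationError(
                "induction_fold_range minimum must exceed 1 (induction elevates coverage)"
            )
        if len(self.conditions) < 1:
            raise ConfigurationError("conditions must be non-empty")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("conditions must be unique")
        if self.read_depth <= 0:
            raise ConfigurationError("read_depth must be > 0")
        if self.effect_sd < 0:
            raise ConfigurationError("effect_sd must be >= 0")
        if self.coverage_noise_cv < 0:
            raise ConfigurationError("coverage_noise_cv must be >= 0")
        if self.coverage_depth_scale <= 0:
            raise ConfigurationError("coverage_depth_scale must be > 0")


def _split_lengths(total: int, n_parts: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` bp into ``n_parts`` contigs, each >= 1 kb (or an
    even split when total is small)."""
    if n_parts == 1:
        return [total]
    min_len = min(1_000, total // n_parts)
    free = total - min_len * n_parts
    w = rng.dirichlet(np.ones(n_parts))
    extra = np.floor(w * free).astype(int)
    extra[0] += free - extra.sum()
    return [min_len + int(e) for e in extra]


def make_community(
    config: SyntheticCommunityConfig,
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate genome records and planted truth, reproducibly from the seed.

    Exactly ``round(prophage_fraction * n_prokaryote_genomes)`` prokaryotes
    carry one prophage, each on a dedicated contig fully covered by its
    region.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_pro = config.n_prokaryote_genomes
    n_vir = config.n_free_viruses
    n_carriers = round(config.prophage_fraction * n_pro)
    carrier_idx = set(rng.choice(n_pro, size=n_carriers, replace=False).tolist())

    genomes: list[GenomeRecord] = []
    for i in range(n_pro):
        gid = f"MAG{i:04d}"
        total = int(rng.integers(config.genome_length_range[0], config.genome_length_range[1] + 1))
        n_contigs = int(rng.integers(2, 7))
        contigs = [
            Contig(f"{gid}_c{j}", ln)
            for j, ln in enumerate(_split_lengths(total, n_contigs, rng))
        ]
        regions: tuple[tuple[str, int, int], ...] = ()
        if i in carrier_idx:
            pro_len = int(
                rng.integers(config.viral_length_range[0], config.viral_length_range[1] + 1)
            )
            pro_contig = Contig(f"{gid}_pro", pro_len)
            contigs.append(pro_contig)
            regions = ((pro_contig.contig_id, 0, pro_len),)
        genomes.append(GenomeRecord(gid, "prokaryote", tuple(contigs), regions))

    for i in range(n_vir):
        gid = f"VIR{i:04d}"
        ln = int(rng.integers(config.viral_length_range[0], config.viral_length_range[1] + 1))
        genomes.append(GenomeRecord(gid, "virus", (Contig(f"{gid}_c0", ln),)))

    ids = [g.genome_id for g in genomes]
    conditions = tuple(config.conditions)

    # Skewed basis abundances, shared across conditions before effects apply.
    base = rng.lognormal(mean=0.0, sigma=1.5, size=len(genomes))
    base /= base.sum()
    basis = pd.DataFrame(
        np.tile(base[:, None], (1, len(conditions))), index=ids, columns=list(conditions)
    )

    mult = rng.normal(0.0, config.effect_sd, size=(len(genomes), len(conditions)))
    if "control" in conditions:
        mult[:, conditions.index("control")] = 0.0
    # Recentre: equalize the community abundance total across conditions so
    # the per-sample compositional offset in CPM vanishes and the stored
    # effects are exactly what noise-free log ratios recover.  (CPM divides
    # counts by genome length, so the relevant total is length-free.)
    totals = (base[:, None] * np.exp2(mult)).sum(axis=0)
    ref_total = totals[conditions.index("control")] if "control" in conditions else totals.mean()
    mult = mult - np.log2(totals / ref_total)[None, :]
    multiplier = pd.DataFrame(mult, index=ids, columns=list(conditions))

    induced: set[tuple[str, str]] = set()
    folds: dict[tuple[str, str], float] = {}
    carriers = [genomes[i].genome_id for i in sorted(carrier_idx)]
    for cond in conditions:
        for gid in carriers:
            if rng.random() < config.induction_rate:
                induced.add((cond, gid))
                folds[(cond, gid)] = float(
                    rng.uniform(config.induction_fold_range[0], config.induction_fold_range[1])
                )

    truth = SyntheticTruth(basis, multiplier, induced, folds, conditions)
    return genomes, truth


def _sampling_probabilities(
    truth: SyntheticTruth, genomes: Sequence[GenomeRecord], condition: str
) -> pd.Series:
    if condition not in truth.conditions:
        raise KeyError(f"unknown condition: {condition!r}")
    ids = [g.genome_id for g in genomes]
    lengths = pd.Series({g.genome_id: g.length for g in genomes}, dtype=float)
    w = (
        truth.basis_abundance.loc[ids, condition]
        * np.exp2(truth.condition_multiplier.loc[ids, condition])
        * lengths
    )
    return w / w.sum()


def simulate_counts(
    truth: SyntheticTruth,
    genomes: Sequence[GenomeRecord],
    condition: str,
    depth: int,
    seed: int,
) -> pd.Series:
    """One multinomial read-count column; counts sum exactly to ``depth``.

    Per-genome probability is proportional to basis abundance x 2^effect x
    genome length (longer genomes attract proportionally more reads).
    """
    p = _sampling_probabilities(truth, genomes, condition)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p.to_numpy())
    return pd.Series(counts, index=p.index, name=condition)


def expected_counts(
    truth: SyntheticTruth,
    genomes: Sequence[GenomeRecord],
    condition: str,
    depth: int,
) -> pd.Series:
    """Noise-free expected counts (real-valued), for exact-recovery checks."""
    p = _sampling_probabilities(truth, genomes, condition)
    return (p * depth).rename(condition)


def simulate_count_matrix(
    truth: SyntheticTruth,
    genomes: Sequence[GenomeRecord],
    depth: int,
    seed: int,
) -> pd.DataFrame:
    """Genome x sample count matrix over all conditions."""
    ss = np.random.SeedSequence(seed)
    cols = [
        simulate_counts(truth, genomes, cond, depth, int(child.generate_state(1)[0] % 2**31))
        for cond, child in zip(truth.conditions, ss.spawn(len(truth.conditions)))
    ]
    return pd.concat(cols, axis=1)


def simulate_coverage(
    truth: SyntheticTruth,
    genomes: Sequence[GenomeRecord],
    sample: str,
    seed: int,
    depth_scale: float = 1_000.0,
    coverage_noise_cv: float = 0.2,
) -> pd.DataFrame:
    """Per-contig coverage table for one sample.

    Coverage = genome relative abundance x ``depth_scale``, with lognormal
    noise of the given CV; contigs inside an induced prophage region in this
    sample are additionally multiplied by the planted fold.
    Columns: sample, contig, genome, coverage.
    """
    if sample not in truth.conditions:
        raise KeyError(f"unknown sample: {sample!r}")
    ids = [g.genome_id for g in genomes]
    w = truth.basis_abundance.loc[ids, sample] * np.exp2(
        truth.condition_multiplier.loc[ids, sample]
    )
    rel = w / w.sum()
    rng = np.random.default_rng(seed)
    if coverage_noise_cv > 0:
        sigma = np.sqrt(np.log1p(coverage_noise_cv**2))
        mu = -(sigma**2) / 2.0
    rows = []
    for g in genomes:
        base = rel[g.genome_id] * depth_scale
        pro_contigs = {r[0] for r in g.prophage_regions}
        fold = truth.true_fold.get((sample, g.genome_id), 1.0)
        is_induced = (sample, g.genome_id) in truth.induced_set
        for c in g.contigs:
            cov = base
            if coverage_noise_cv > 0:
                cov *= rng.lognormal(mu, sigma)
            if is_induced and c.contig_id in pro_contigs:
                cov *= fold
            rows.append((sample, c.contig_id, g.genome_id, cov))
    return pd.DataFrame(rows, columns=["sample", "contig", "genome", "coverage"])


def emit_predictor_evidence(
    genomes: Sequence[GenomeRecord],
    error_rates: Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Per-contig verdicts from the four viral predictors.

    Each tool reports the contig's true class (viral vs non-viral) with
    probability ``1 - error_rate``.  PPR-Meta verdicts carry a viral score
    (>= 0.75 when positive, < 0.75 otherwise); CheckV verdicts carry a
    quality tier and viral-gene count ("Not-determined"/0 when negative).
    Columns: contig, tool, predicted_viral, score, quality, viral_genes.
    """
    for tool, rate in error_rates.items():
        if tool not in PREDICTOR_TOOLS:
            raise ConfigurationError(f"unknown tool in error_rates: {tool!r}")
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"error_rates[{tool!r}] must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genomes:
        pro_contigs = {r[0] for r in g.prophage_regions}
        for c in g.contigs:
            truly_viral = g.klass == "virus" or c.contig_id in pro_contigs
            for tool in PREDICTOR_TOOLS:
                err = error_rates.get(tool, 0.0)
                verdict = truly_viral if rng.random() >= err else not truly_viral
                score = np.nan
                quality = ""
                viral_genes = 0
                if tool == "PPR-Meta":
                    score = rng.uniform(0.75, 1.0) if verdict else rng.uniform(0.0, 0.75)
                elif tool == "CheckV":
                    if verdict:
                        quality = _CHECKV_POSITIVE_TIERS[
                            int(rng.integers(0, len(_CHECKV_POSITIVE_TIERS)))
                        ]
                        viral_genes = int(rng.integers(1, 20))
                    else:
                        quality = "Not-determined"
                        viral_genes = 0
                rows.append((c.contig_id, tool, bool(verdict), score, quality, viral_genes))
    return pd.DataFrame(
        rows, columns=["contig", "tool", "predicted_viral", "score", "quality", "viral_genes"]
    )


_VIRAL_FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae")


def emit_orf_annotations(
    genomes: Sequence[GenomeRecord],
    seed: int,
    orfs_per_genome: int = 20,
    family_labels: Sequence[str] = ("GH33", "GT2", "GT4", "GH13", "CBM56"),
    family_rate_viral: Sequence[float] = (0.16, 0.15, 0.15, 0.02, 0.02),
    family_rate_prokaryote: Sequence[float] = (0.02, 0.07, 0.08, 0.05, 0.03),
) -> pd.DataFrame:
    """ORF annotation table emulating CAZy family hits and pVOG taxonomy hits.

    Viral genomes receive gene-family labels at the viral rates (sialidases,
    GH33, enriched), prokaryotes at the prokaryotic rates; unlabelled ORFs
    are omitted.  Each viral genome is assigned a true family under
    Caudovirales, and its ORFs report taxonomy paths truncated at a random
    depth.  Columns: genome, orf, label, source.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genomes:
        viral = g.klass == "virus"
        rates = family_rate_viral if viral else family_rate_prokaryote
        true_family = _VIRAL_FAMILIES[int(rng.integers(0, len(_VIRAL_FAMILIES)))]
        for j in range(orfs_per_genome):
            orf = f"{g.genome_id}_orf{j:03d}"
            u = rng.random()
            acc = 0.0
            for lab, rate in zip(family_labels, rates):
                acc += rate
                if u < acc:
                    rows.append((g.genome_id, orf, lab, "cazy"))
                    break
            if viral:
                depth = int(rng.integers(1, 4))  # order / family / species
                path = ["Caudovirales", true_family, f"{true_family} sp. {g.genome_id[-4:]}"]
                rows.append((g.genome_id, orf, ";".join(path[:depth]), "pvog_taxonomy"))
    return pd.DataFrame(rows, columns=["genome", "orf", "label", "source"])


# ---------------------------------------------------------------------------
# Correlated-count generator for the compositional-correlation module


def simulate_correlated_counts(
    n_genomes: int,
    n_samples: int,
    depth: int,
    seed: int,
    correlated_pairs: Mapping[tuple[int, int], float] | None = None,
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Counts whose *basis* (pre-compositional) abundances have known
    pairwise correlations.

    Basis log-abundances are multivariate normal with unit variance and the
    requested correlations (zero elsewhere); each sample's abundances are
    exponentiated, normalized, and read counts drawn multinomially.
    Returns a genome x sample DataFrame.
    """
    cov = np.eye(n_genomes)
    for (i, j), rho in (correlated_pairs or {}).items():
        cov[i, j] = cov[j, i] = rho
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, 1.0, size=n_genomes)  # heterogeneous mean abundances
    logx = rng.multivariate_normal(means, cov * log_sd**2, size=n_samples)
    x = np.exp(logx)
    p = x / x.sum(axis=1, keepdims=True)
    counts = np.stack([rng.multinomial(depth, p[s]) for s in range(n_samples)], axis=1)
    return pd.DataFrame(
        counts,
        index=[f"G{i:03d}" for i in range(n_genomes)],
        columns=[f"S{s:03d}" for s in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# Writers / readers (plain-text, round-trippable)


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.basis_abundance.to_csv(outdir / "basis_abundance.tsv", sep="\t", index_label="genome")
    truth.condition_multiplier.to_csv(
        outdir / "condition_multiplier.tsv", sep="\t", index_label="genome"
    )
    rows = [
        (s, g, truth.true_fold[(s, g)]) for (s, g) in sorted(truth.induced_set)
    ]
    pd.DataFrame(rows, columns=["sample", "genome", "true_fold"]).to_csv(
        outdir / "induced.tsv", sep="\t", index=False
    )


def read_truth(indir: str | Path) -> SyntheticTruth:
    indir = Path(indir)
    basis = pd.read_csv(
        indir / "basis_abundance.tsv", sep="\t", index_col="genome"
    ).rename_axis(None)
    mult = pd.read_csv(
        indir / "condition_multiplier.tsv", sep="\t", index_col="genome"
    ).rename_axis(None)
    ind = pd.read_csv(indir / "induced.tsv", sep="\t")
    induced = {(r["sample"], r.genome) for _, r in ind.iterrows()}
    folds = {(r["sample"], r.genome): float(r.true_fold) for _, r in ind.iterrows()}
    return SyntheticTruth(basis, mult, induced, folds, tuple(basis.columns))


def write_community(genomes: Sequence[GenomeRecord], outdir: str | Path) -> None:
    """Community table TSV plus prophage regions BED (0-based half-open)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        (g.genome_id, g.klass, g.length, ",".join(c.contig_id for c in g.contigs))
        for g in genomes
    ]
    pd.DataFrame(rows, columns=["genome", "class", "length", "contigs"]).to_csv(
        outdir / "community.tsv", sep="\t", index=False
    )
    contig_rows = [
        (c.contig_id, c.length, g.genome_id) for g in genomes for c in g.contigs
    ]
    pd.DataFrame(contig_rows, columns=["contig", "length", "genome"]).to_csv(
        outdir / "contigs.tsv", sep="\t", index=False
    )
    with open(outdir / "prophage_regions.bed", "w") as fh:
        for g in genomes:
            for contig, start, end in g.prophage_regions:
                fh.write(f"{contig}\t{start}\t{end}\t{g.genome_id}\n")


def read_community(indir: str | Path) -> list[GenomeRecord]:
    indir = Path(indir)
    contigs = pd.read_csv(indir / "contigs.tsv", sep="\t")
    lengths = dict(zip(contigs.contig, contigs.length))
    community = pd.read_csv(indir / "community.tsv", sep="\t")
    regions: dict[str, list[tuple[str, int, int]]] = {}
    bed = indir / "prophage_regions.bed"
    if bed.exists():
        for line in bed.read_text().splitlines():
            if not line.strip():
                continue
            contig, start, end, genome = line.split("\t")
            regions.setdefault(genome, []).append((contig, int(start), int(end)))
    out = []
    for _, row in community.iterrows():
        cids = row.contigs.split(",")
        out.append(
            GenomeRecord(
                row.genome,
                row["class"],
                tuple(Contig(cid, int(lengths[cid])) for cid in cids),
                tuple(regions.get(row.genome, ())),
            )
        )
    return out
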