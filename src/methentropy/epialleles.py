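"""Epiallele extraction: 4-CpG loci and their 5-category pattern distributions.

An epiallele locus is a group of 4 CpGs spanning at most 60 bp that is covered
by at least 40 reads carrying a definite M/U call at all four positions.  The
16 binary patterns observed at a locus are collapsed to 5 categories by the
number of methylated CpGs (0..4); that 5-vector is the probability
distribution entering the Jensen-Shannon distance.

Window enumeration tiles the sorted distinct CpG positions of a chromosome in
non-overlapping consecutive groups of four (positions 1-4, 5-8, ...), keeping a
group only if its span fits the limit.  Disjoint loci make per-locus
statistics independent of one another.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyDistributionError, UsageError, ValidationError
from .io import EpireadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EpialleleLocus",
    "EpialleleDistribution",
    "find_loci",
    "count_patterns",
    "pool_samples",
    "extract_distributions",
    "write_locus_table",
    "read_locus_table",
]


@dataclass(frozen=True)
class EpialleleLocus:
    """Four CpG positions (1-based, increasing) on one chromosome, span <= 60 bp."""

    chromosome: str
    cpg_positions: tuple[int, int, int, int]
    max_span_bp: int = 60

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != 4:
            raise ValidationError("an epiallele locus has exactly 4 CpG positions")
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValidationError("locus positions must be strictly increasing")
        if self.span > self.max_span_bp:
            raise ValidationError(
                f"locus span {self.span} bp exceeds {self.max_span_bp} bp"
            )

    @property
    def span(self) -> int:
        return self.cpg_positions[-1] - self.cpg_positions[0]

    def key(self) -> tuple:
        return (self.chromosome,) + tuple(self.cpg_positions)


@dataclass
class EpialleleDistribution:
    """Counts of reads with 0..4 methylated CpGs at one locus in one sample."""

    locus: EpialleleLocus
    sample_id: str
    counts: np.ndarray  # shape (5,), non-negative ints
    pattern_table: Counter = field(default_factory=Counter, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5,):
            raise ValidationError("counts must be a 5-vector (0..4 methylated CpGs)")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise EmptyDistributionError(
                f"no qualifying reads at {self.locus.key()} in {self.sample_id}"
            )
        return self.counts / self.total


def _reads_covering(
    reads: Sequence[EpireadRecord], chromosome: str, positions: Sequence[int]
) -> list[EpireadRecord]:
    wanted = set(positions)
    out = []
    for r in reads:
        if r.chromosome != chromosome:
            continue
        if wanted.issubset(r.cpg_positions):
            out.append(r)
    return out


def find_loci(
    reads: Sequence[EpireadRecord],
    min_coverage: int = 40,
    max_span_bp: int = 60,
    n_cpgs: int = 4,
) -> list[EpialleleLocus]:
    """Locate epiallele loci in a read set.

    Distinct CpG positions per chromosome are sorted and tiled in
    non-overlapping groups of ``n_cpgs``; a group becomes a locus when its
    span is at most ``max_span_bp`` and at least ``min_coverage`` reads carry
    a call at all of its positions.  Ordering is deterministic by
    (chromosome, first position).
    """
    if n_cpgs != 4:
        raise ValidationError("only 4-CpG loci are supported")
    by_chrom: dict[str, set[int]] = {}
    for r in reads:
        by_chrom.setdefault(r.chromosome, set()).update(r.cpg_positions)
    loci: list[EpialleleLocus] = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        for i in range(0, len(positions) - n_cpgs + 1, n_cpgs):
            group = tuple(positions[i : i + n_cpgs])
            if group[-1] - group[0] > max_span_bp:
                continue
            covering = _reads_covering(reads, chrom, group)
            if len(covering) >= min_coverage:
                loci.append(EpialleleLocus(chrom, group, max_span_bp=max_span_bp))
    return loci


def count_patterns(
    reads: Sequence[EpireadRecord],
    locus: EpialleleLocus,
    sample_id: str = "sample",
) -> EpialleleDistribution:
    """Tabulate reads at a locus into the 5-category distribution.

    Only reads with a definite M/U call at all four positions contribute;
    partial reads are discarded, never imputed.  Raises
    :class:`EmptyDistributionError` if no read qualifies.
    """
    counts = np.zeros(5, dtype=np.int64)
    patterns: Counter = Counter()
    for r in _reads_covering(reads, locus.chromosome, locus.cpg_positions):
        pattern = "".join(r.state_at(p) for p in locus.cpg_positions)
        counts[pattern.count("M")] += 1
        patterns[pattern] += 1
    if counts.sum() == 0:
        raise EmptyDistributionError(
            f"no reads cover all 4 CpGs of {locus.key()} in {sample_id}"
        )
    return EpialleleDistribution(locus, sample_id, counts, patterns)


def pool_samples(distributions: Sequence[EpialleleDistribution]) -> EpialleleDistribution:
    """Pool several samples' distributions at one locus by summing counts.

    Mimics DNA-level pooling of individuals bioinformatically: the pooled
    frequencies are the read-weighted mixture of the individuals'.
    """
    if not distributions:
        raise UsageError("cannot pool an empty list of distributions")
    locus = distributions[0].locus
    if any(d.locus != locus for d in distributions[1:]):
        raise UsageError("pooled distributions must share one locus")
    counts = np.sum([d.counts for d in distributions], axis=0)
    patterns: Counter = Counter()
    for d in distributions:
        patterns.update(d.pattern_table)
    sample_id = "+".join(d.sample_id for d in distributions)
    return EpialleleDistribution(locus, sample_id, counts, patterns)


def extract_distributions(
    reads_by_sample: Mapping[str, Sequence[EpireadRecord]],
    min_coverage: int = 40,
    max_span_bp: int = 60,
    n_cpgs: int = 4,
) -> list[EpialleleDistribution]:
    """Per-sample epiallele distributions over a shared locus catalogue.

    Candidate loci are tiled from the union of CpG positions across samples,
    so the same physical locus gets one identity everywhere; the coverage
    filter is then applied per (locus, sample), keeping pairs with at least
    ``min_coverage`` complete reads.
    """
    by_chrom: dict[str, set[int]] = {}
    for reads in reads_by_sample.values():
        for r in reads:
            by_chrom.setdefault(r.chromosome, set()).update(r.cpg_positions)
    candidates: list[EpialleleLocus] = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        for i in range(0, len(positions) - n_cpgs + 1, n_cpgs):
            group = tuple(positions[i : i + n_cpgs])
            if group[-1] - group[0] <= max_span_bp:
                candidates.append(EpialleleLocus(chrom, group, max_span_bp=max_span_bp))
    out: list[EpialleleDistribution] = []
    for sample_id, reads in reads_by_sample.items():
        for locus in candidates:
            try:
                dist = count_patterns(reads, locus, sample_id)
            except EmptyDistributionError:
                continue
            if dist.total >= min_coverage:
                out.append(dist)
    logger.info(
        "extracted %d (locus, sample) distributions over %d candidate loci",
        len(out),
        len(candidates),
    )
    return out


# ---------------------------------------------------------------------------
# Locus table serialization (chrom, pos1..pos4, counts 0..4, total, sample)
# ---------------------------------------------------------------------------

_LOCUS_COLUMNS = [
    "chromosome", "pos1", "pos2", "pos3", "pos4",
    "n0", "n1", "n2", "n3", "n4", "total", "sample_id",
]


def write_locus_table(
    distributions: Sequence[EpialleleDistribution],
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("#" + "\t".join(_LOCUS_COLUMNS) + "\n")
        for d in distributions:
            p = d.locus.cpg_positions
            fh.write(
                f"{d.locus.chromosome}\t{p[0]}\t{p[1]}\t{p[2]}\t{p[3]}\t"
                + "\t".join(str(int(c)) for c in d.counts)
                + f"\t{d.total}\t{d.sample_id}\n"
            )


def read_locus_table(path: str | Path) -> list[EpialleleDistribution]:
    out: list[EpialleleDistribution] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            locus = EpialleleLocus(f[0], tuple(int(x) for x in f[1:5]))
            counts = np.array([int(x) for x in f[5:10]])
            out.append(EpialleleDistribution(locus, f[11], counts))
    return out
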