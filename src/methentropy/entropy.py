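"""Jensen-Shannon distance of epiallele distributions against a young reference.

The disorder of a locus is quantified by comparing its 5-category epiallele
frequency vector P (0..4 methylated CpGs) with a reference distribution built
from young samples.  The distance is the standard Jensen-Shannon distance,

    JSD(P, Q) = sqrt( (D(P, M) + D(Q, M)) / 2 ),   M = (P + Q) / 2,

with Kullback-Leibler divergences D in base-2 logarithms.  It is a metric on
[0, 1]: 0 iff the distributions coincide, 1 iff their supports are disjoint.
Unlike Shannon entropy it is sensitive to the direction of change — a fully
methylated and a fully unmethylated locus both have zero Shannon entropy but
sit at maximal JSD from one another.

Also here: JSD fold change with age per group, Brown-Forsythe variance-shift
tests, and the correlation of fold change with tissue turnover rates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epialleles import EpialleleDistribution, EpialleleLocus
from .exceptions import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .io import SampleSheet, TurnoverTable

logger = logging.getLogger(__name__)

__all__ = [
    "kl_divergence",
    "jensen_shannon_distance",
    "shannon_entropy",
    "ReferenceDistribution",
    "JSDRecord",
    "FoldChangeRecord",
    "build_reference",
    "jsd_records",
    "jsd_fold_change",
    "variance_shift_test",
    "correlate_turnover",
    "filter_high_jsd",
]


def _as_distribution(p, name: str, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D probability vector")
    if (p < 0).any():
        raise ValidationError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > atol:
        raise ValidationError(f"{name} does not sum to 1 (sum={p.sum()!r})")
    return p


def kl_divergence(p, m) -> float:
    """Kullback-Leibler divergence D(P, M) = sum P(l) * log2(P(l) / M(l)).

    Categories with P(l) = 0 contribute nothing.  If P(l) > 0 where
    M(l) = 0 the divergence is infinite; the midpoint construction in
    :func:`jensen_shannon_distance` makes that unreachable there.
    """
    p = _as_distribution(p, "P")
    m = _as_distribution(m, "M")
    if p.shape != m.shape:
        raise ValidationError("P and M must have the same length")
    support = p > 0
    if np.any(m[support] == 0):
        return float("inf")
    ps, ms = p[support], m[support]
    return float(np.sum(ps * np.log2(ps / ms)))


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance between two probability vectors, base 2.

    Equals 0 iff P == Q and 1 iff the supports are disjoint; symmetric and a
    metric (it satisfies the triangle inequality on the simplex).
    """
    p = _as_distribution(p, "P")
    q = _as_distribution(q, "Q")
    if p.shape != q.shape:
        raise ValidationError("P and Q must have the same length")
    m = 0.5 * (p + q)
    js = 0.5 * (kl_divergence(p, m) + kl_divergence(q, m))
    # floating-point noise can push the divergence a hair below 0 or above 1
    return float(np.sqrt(min(max(js, 0.0), 1.0)))


def shannon_entropy(p) -> float:
    """Shannon entropy -sum P(l) log2 P(l), in bits; zero terms for P(l)=0."""
    p = _as_distribution(p, "P")
    support = p > 0
    return float(-np.sum(p[support] * np.log2(p[support])))


# ---------------------------------------------------------------------------
# Reference distributions and per-sample JSD records
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDistribution:
    """Per-locus reference Q: unweighted mean of young samples' frequencies."""

    locus: EpialleleLocus
    q: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.q = _as_distribution(self.q, "Q", atol=1e-9)


@dataclass
class JSDRecord:
    locus: EpialleleLocus
    sample_id: str
    jsd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.jsd <= 1.0:
            raise ValidationError(f"jsd {self.jsd} outside [0, 1]")


@dataclass
class FoldChangeRecord:
    """Relative change of mean JSD between an old and a young group."""

    group: str
    tissue: str
    cell_type: str
    mean_jsd_old: float
    mean_jsd_young: float
    n_old: int
    n_young: int

    @property
    def fold_change(self) -> float:
        """(mean_old - mean_young) / mean_young."""
        return (self.mean_jsd_old - self.mean_jsd_young) / self.mean_jsd_young

    @property
    def ratio(self) -> float:
        """mean_old / mean_young, emitted alongside for transparency."""
        return self.mean_jsd_old / self.mean_jsd_young


def build_reference(
    distributions: Sequence[EpialleleDistribution],
    sheet: SampleSheet,
    reference_age: float,
    scope: str = "per_tissue",
) -> dict[tuple[str, tuple], ReferenceDistribution]:
    """Average reference-age samples' frequency vectors per locus.

    ``scope`` is ``per_tissue`` (default: each tissue gets its own young
    reference) or ``global`` (one reference across tissues).  Loci with no
    reference-age sample are dropped; the count is logged.  Keys of the
    returned mapping are ``(scope_key, locus.key())`` where scope_key is the
    tissue name or ``"global"``.
    """
    if scope not in ("per_tissue", "global"):
        raise ValidationError(f"unknown reference scope {scope!r}")
    groups: dict[tuple[str, tuple], list[np.ndarray]] = {}
    seen: set[tuple[str, tuple]] = set()
    for d in distributions:
        row = sheet.row(d.sample_id)
        key = (
            str(row["tissue"]) if scope == "per_tissue" else "global",
            d.locus.key(),
        )
        seen.add(key)
        if np.isclose(float(row["age_months"]), reference_age):
            groups.setdefault(key, []).append(d.frequencies)
    refs: dict[tuple[str, tuple], ReferenceDistribution] = {}
    locus_by_key = {d.locus.key(): d.locus for d in distributions}
    for key, freqs in groups.items():
        q = np.mean(freqs, axis=0)
        q = q / q.sum()
        refs[key] = ReferenceDistribution(locus_by_key[key[1]], q, len(freqs))
    dropped = len(seen) - len(refs)
    if dropped:
        logger.info(
            "build_reference: dropped %d (scope, locus) pairs with no age-%s sample",
            dropped,
            reference_age,
        )
    return refs


def jsd_records(
    distributions: Sequence[EpialleleDistribution],
    references: Mapping[tuple[str, tuple], ReferenceDistribution],
    sheet: SampleSheet,
    scope: str = "per_tissue",
) -> list[JSDRecord]:
    """JSD of each (locus, sample) distribution against its reference."""
    out: list[JSDRecord] = []
    for d in distributions:
        scope_key = sheet.tissue_of(d.sample_id) if scope == "per_tissue" else "global"
        ref = references.get((scope_key, d.locus.key()))
        if ref is None:
            continue
        out.append(JSDRecord(d.locus, d.sample_id, jensen_shannon_distance(d.frequencies, ref.q)))
    return out


def jsd_fold_change(
    records: Sequence[JSDRecord],
    sheet: SampleSheet,
    old_age: float,
    young_age: float,
) -> list[FoldChangeRecord]:
    """Per (tissue, cell_type) group: relative change of mean JSD with age.

    The mean runs over all (locus, sample) JSD values in the group; loci
    missing in a sample contribute nothing.  A group with zero mean young JSD
    has no defined fold change and raises :class:`UndefinedStatisticError`.
    """
    values: dict[tuple[str, str], dict[str, list[float]]] = {}
    for r in records:
        row = sheet.row(r.sample_id)
        group = (str(row["tissue"]), str(row["cell_type"]))
        age = float(row["age_months"])
        if np.isclose(age, old_age):
            bucket = "old"
        elif np.isclose(age, young_age):
            bucket = "young"
        else:
            continue
        values.setdefault(group, {"old": [], "young": []})[bucket].append(r.jsd)
    out: list[FoldChangeRecord] = []
    for (tissue, cell_type), buckets in sorted(values.items()):
        if not buckets["old"] or not buckets["young"]:
            logger.warning("group %s/%s lacks an age group; skipped", tissue, cell_type)
            continue
        mean_young = float(np.mean(buckets["young"]))
        mean_old = float(np.mean(buckets["old"]))
        if mean_young == 0:
            raise UndefinedStatisticError(
                f"group {tissue}/{cell_type}: mean young JSD is zero, fold change undefined"
            )
        out.append(
            FoldChangeRecord(
                group=f"{tissue}/{cell_type}",
                tissue=tissue,
                cell_type=cell_type,
                mean_jsd_old=mean_old,
                mean_jsd_young=mean_young,
                n_old=len(buckets["old"]),
                n_young=len(buckets["young"]),
            )
        )
    return out


def variance_shift_test(
    jsd_by_group: Mapping[str, Sequence[float]],
    center: str = "median",
) -> pd.DataFrame:
    """Pairwise equality-of-variance tests between JSD groups.

    Uses Levene's statistic on |x - center|; ``center='median'`` is the
    robust Brown-Forsythe variant (default), ``'mean'`` the classical one.
    p-values are Bonferroni-adjusted for the number of pairs tested.  Groups
    with fewer than 2 values are skipped with a warning.
    """
    if center not in ("median", "mean"):
        raise ValidationError(f"unknown center {center!r}")
    usable = {}
    for name, vals in jsd_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            logger.warning("group %r has < 2 values; skipped", name)
            continue
        usable[name] = vals
    pairs = list(itertools.combinations(sorted(usable), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        stat, p = stats.levene(usable[a], usable[b], center=center)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "statistic": float(stat),
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * m),
            }
        )
    return pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p", "p_bonferroni"])


def correlate_turnover(
    fold_changes: Sequence[FoldChangeRecord],
    turnover: TurnoverTable,
    factor_days: float = 30.0,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of JSD fold change with tissue turnover.

    Turnover enters as the ``factor_days``-day rate, i.e. ``factor_days``
    times the average per-day turnover (30-day rate by default).  Each fold
    change record is matched to its tissue's turnover; at least 3 shared
    tissues are required.  Returns (r, two-sided p, the matched table).
    """
    rate = turnover.thirty_day() * (factor_days / 30.0)
    rows = []
    for fc in fold_changes:
        if fc.tissue in rate.index:
            rows.append(
                {
                    "group": fc.group,
                    "tissue": fc.tissue,
                    "fold_change": fc.fold_change,
                    "turnover": float(rate.loc[fc.tissue]),
                }
            )
    table = pd.DataFrame(rows, columns=["group", "tissue", "fold_change", "turnover"])
    if table["tissue"].nunique() < 3:
        raise InsufficientDataError(
            f"only {table['tissue'].nunique()} tissues shared between fold changes "
            "and turnover table; need >= 3"
        )
    x = table["fold_change"].to_numpy()
    y = table["turnover"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in fold change or turnover")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), table


def filter_high_jsd(
    records: Sequence[JSDRecord],
    groups: Mapping[str, Iterable[str]],
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Loci whose JSD strictly exceeds ``threshold`` in at least one group.

    ``groups`` maps a group label to the sample ids it contains.  Returns a
    boolean frame (locus key x group) restricted to loci exceeded somewhere —
    the substrate of overlap/UpSet-style counts.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie strictly within (0, 1)")
    membership = {g: set(s) for g, s in groups.items()}
    flags: dict[tuple, dict[str, bool]] = {}
    for r in records:
        for g, samples in membership.items():
            if r.sample_id in samples:
                row = flags.setdefault(r.locus.key(), {k: False for k in membership})
                row[g] = row[g] or (r.jsd > threshold)
    df = pd.DataFrame.from_dict(flags, orient="index", columns=list(membership))
    if df.empty:
        return pd.DataFrame(columns=list(membership))
    return df[df.any(axis=1)]
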