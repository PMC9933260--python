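"""Per-CpG methylation drift statistics.

Coverage/presence filtering, two-condition differential methylation
(chi-square on pooled counts with Benjamini-Hochberg correction),
permutation-based testing of the age-methylation Spearman correlation with
empirical p = r/n, genomic-compartment annotation with Fisher's exact odds
ratios, and the methylation-expression linkage analyses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .io import CpGCountMatrix, RegionSet, SampleSheet, ExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "filter_sites",
    "differential_methylation",
    "permutation_age_test",
    "annotate_compartments",
    "ORResult",
    "compartment_odds_ratio",
    "expression_methylation_bins",
    "correlate_dm_expression",
    "stem_nonstem_concordance",
    "COMPARTMENT_LABELS",
]

COMPARTMENT_LABELS = (
    "Promoter-CpGi",
    "nonPromoter-CpGi",
    "Promoter-nonCpGi",
    "nonPromoter-nonCpGi",
)


def filter_sites(
    matrix: CpGCountMatrix,
    min_coverage: int = 20,
    min_presence: float = 0.75,
) -> CpGCountMatrix:
    """Coverage/presence filter.

    Cells with fewer than ``min_coverage`` total reads are marked absent;
    sites whose remaining present cells span at least ``min_presence`` of the
    samples (boundary inclusive) are kept.
    """
    if not 0.0 < min_presence <= 1.0:
        raise ValidationError("min_presence must lie in (0, 1]")
    if min_coverage < 0:
        raise ValidationError("min_coverage must be non-negative")
    covered = matrix.total >= min_coverage
    meth = matrix.meth.where(covered)
    total = matrix.total.where(covered)
    presence = covered.sum(axis=1) / len(matrix.samples)
    keep = (presence >= min_presence).to_numpy()
    logger.info(
        "filter_sites: kept %d of %d sites (min_coverage=%d, min_presence=%.2f)",
        int(keep.sum()), len(keep), min_coverage, min_presence,
    )
    return CpGCountMatrix(meth.loc[keep], total.loc[keep])


def _chi2_2x2(table: np.ndarray, correction: bool = True) -> tuple[float, float]:
    """2x2 chi-square with Yates continuity correction; degenerate margins -> (0, 1)."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def differential_methylation(
    matrix: CpGCountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    diff_cutoff: float = 5.0,
    q_cutoff: float = 0.05,
    variance_inflation: float = 1.0,
) -> pd.DataFrame:
    """Two-condition differential methylation per CpG site.

    Counts are pooled within each group and compared in a 2x2 chi-square
    (methylated/unmethylated x group) with continuity correction; p-values
    are Benjamini-Hochberg adjusted (column ``q``).  A site is significant
    when |meth_diff| strictly exceeds ``diff_cutoff`` percentage points and
    q < ``q_cutoff``.  ``variance_inflation`` > 1 deflates the chi-square
    statistic (stat / VIF) as a crude overdispersion allowance.  Sites with
    zero sequencing total in either group are skipped (count logged).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    for s in group_a + group_b:
        if s not in matrix.samples:
            raise ValidationError(f"sample {s!r} not in matrix")
    if variance_inflation < 1.0:
        raise ValidationError("variance_inflation must be >= 1")

    ma = matrix.meth[group_a].sum(axis=1, min_count=1)
    ta = matrix.total[group_a].sum(axis=1, min_count=1)
    mb = matrix.meth[group_b].sum(axis=1, min_count=1)
    tb = matrix.total[group_b].sum(axis=1, min_count=1)

    usable = (ta.fillna(0) > 0) & (tb.fillna(0) > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("differential_methylation: skipped %d sites with no data in a group", n_skipped)

    rows = []
    for (chrom, pos) in matrix.meth.index[usable]:
        a_m, a_t = float(ma.loc[(chrom, pos)]), float(ta.loc[(chrom, pos)])
        b_m, b_t = float(mb.loc[(chrom, pos)]), float(tb.loc[(chrom, pos)])
        stat, p = _chi2_2x2([[a_m, a_t - a_m], [b_m, b_t - b_m]])
        if variance_inflation > 1.0:
            stat = stat / variance_inflation
            p = float(stats.chi2.sf(stat, df=1))
        pct_a = 100.0 * a_m / a_t
        pct_b = 100.0 * b_m / b_t
        rows.append(
            {
                "chromosome": chrom,
                "position": pos,
                "pct_a": pct_a,
                "pct_b": pct_b,
                "meth_diff": pct_b - pct_a,
                "statistic": stat,
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chromosome", "position", "pct_a", "pct_b", "meth_diff", "statistic", "p"],
    )
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = (df["meth_diff"].abs() > diff_cutoff) & (df["q"] < q_cutoff)
    return df


# ---------------------------------------------------------------------------
# Permutation test of age correlation
# ---------------------------------------------------------------------------

def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between each row of x and each row of y.

    x: (s, c), y: (p, c) -> (s, p).  Rows with zero variance give NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / (xn[:, None] * yn[None, :])
    return r


def permutation_age_test(
    matrix: CpGCountMatrix,
    sheet: SampleSheet,
    n_perm: int = 1000,
    rho_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
    seed: int | None = None,
    shared_shuffles: bool = True,
) -> pd.DataFrame:
    """Permutation test of the per-site Spearman correlation with age.

    For every site, rho is the Spearman correlation (average ranks for ties)
    of percent methylation with age across the samples carrying data there.
    Age labels are shuffled ``n_perm`` times — by default one shuffle per
    replicate shared across all sites, preserving inter-site correlation
    under the null; ``shared_shuffles=False`` shuffles per site.  The
    empirical p-value is r/n with r the number of replicates whose |rho| is
    at least the observed |rho|.  Direction is ``hyper`` when
    rho >= +rho_cutoff with empirical p < p_cutoff, ``hypo`` symmetric,
    otherwise ``none``.  Sites with fewer than 3 distinct ages among covered
    samples, or constant methylation, get rho = NaN, empirical p = 1 and
    direction ``none``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not 0.0 < rho_cutoff < 1.0:
        raise ValidationError("rho_cutoff must lie in (0, 1)")
    samples = matrix.samples
    ages = np.array([sheet.age_of(s) for s in samples], dtype=float)
    pct = matrix.percent().to_numpy(dtype=float)
    n_sites, n_samples = pct.shape
    rng = np.random.default_rng(seed)

    shared_perms = np.array([rng.permutation(n_samples) for _ in range(n_perm)])

    rho = np.full(n_sites, np.nan)
    r_exceed = np.full(n_sites, n_perm, dtype=np.int64)

    present = ~np.isnan(pct)
    # group sites by identical presence mask so permutation ranks are shared
    mask_keys: dict[bytes, list[int]] = {}
    for i in range(n_sites):
        mask_keys.setdefault(present[i].tobytes(), []).append(i)

    for key, site_idx in mask_keys.items():
        mask = np.frombuffer(key, dtype=bool)
        cols = np.flatnonzero(mask)
        if cols.size < 2 or np.unique(ages[cols]).size < 3:
            continue  # rho undefined: fewer than 3 distinct ages
        sub = pct[np.ix_(site_idx, cols)]
        x_ranks = stats.rankdata(sub, axis=1)
        variable = np.ptp(sub, axis=1) > 0
        a_ranks = stats.rankdata(ages[cols])
        rho_obs = _pearson_rows(x_ranks, a_ranks[None, :])[:, 0]
        rho_obs[~variable] = np.nan

        if shared_shuffles:
            perm_ages = ages[shared_perms][:, cols]
        else:
            perm_ages = np.empty((n_perm, cols.size))
            for k in range(n_perm):
                perm_ages[k] = ages[rng.permutation(n_samples)][cols]
        pa_ranks = stats.rankdata(perm_ages, axis=1)
        rho_perm = _pearson_rows(x_ranks, pa_ranks)  # (sites_in_group, n_perm)
        with np.errstate(invalid="ignore"):
            exceed = (np.abs(rho_perm) >= np.abs(rho_obs)[:, None]).sum(axis=1)
        for j, i in enumerate(site_idx):
            if variable[j]:
                rho[i] = rho_obs[j]
                r_exceed[i] = int(exceed[j])

    empirical_p = r_exceed / n_perm
    empirical_p[np.isnan(rho)] = 1.0
    direction = np.where(
        np.isnan(rho),
        "none",
        np.where(
            (rho >= rho_cutoff) & (empirical_p < p_cutoff),
            "hyper",
            np.where((rho <= -rho_cutoff) & (empirical_p < p_cutoff), "hypo", "none"),
        ),
    )
    idx = matrix.meth.index
    return pd.DataFrame(
        {
            "chromosome": idx.get_level_values(0),
            "position": idx.get_level_values(1),
            "rho": rho,
            "r_exceed": r_exceed,
            "n_perm": n_perm,
            "empirical_p": empirical_p,
            "direction": direction,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genomic compartments and enrichment
# ---------------------------------------------------------------------------

def annotate_compartments(
    sites: Sequence[tuple[str, int]],
    cpg_islands: RegionSet,
    promoters: RegionSet,
) -> pd.Series:
    """Assign each CpG site to one of four mutually exclusive compartments.

    Membership is point-in-interval of the 1-based CpG position against the
    0-based half-open regions (a site at an interval's end coordinate falls
    outside).
    """
    labels = []
    by_chrom: dict[str, list[int]] = {}
    order: list[tuple[str, int]] = []
    for chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append(pos)
        order.append((chrom, pos))
    lab_map: dict[tuple[str, int], str] = {}
    for chrom, positions in by_chrom.items():
        arr = np.asarray(positions)
        in_cpgi = cpg_islands.contains(chrom, arr)
        in_prom = promoters.contains(chrom, arr)
        for pos, c, p in zip(positions, in_cpgi, in_prom):
            lab_map[(chrom, pos)] = (
                "Promoter-CpGi" if p and c
                else "nonPromoter-CpGi" if c
                else "Promoter-nonCpGi" if p
                else "nonPromoter-nonCpGi"
            )
    labels = [lab_map[s] for s in order]
    return pd.Series(labels, index=pd.MultiIndex.from_tuples(order), name="compartment")


@dataclass
class ORResult:
    """Enrichment of significant sites inside one genomic compartment."""

    compartment: str
    direction: str
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    haldane: bool  # True when a 0.5 pseudo-count rescued a zero cell


def compartment_odds_ratio(
    labels: pd.Series,
    significant_sites: Iterable[tuple[str, int]],
    direction: str = "gain",
) -> list[ORResult]:
    """Fisher's exact enrichment per compartment.

    The 2x2 table opposes CpGs in the compartment to all other CpGs, split by
    membership in ``significant_sites``: a = in-compartment significant,
    b = in-compartment not, c = out-of-compartment significant, d = out not.
    OR = (a d)/(b c); the 95% CI uses the log-OR normal approximation.  A
    zero cell is flagged and handled with the Haldane 0.5 correction for the
    OR and CI (the exact p is unaffected).
    """
    sig = set(significant_sites)
    unknown = sig - set(labels.index)
    if unknown:
        raise ValidationError(f"{len(unknown)} significant sites missing from labels")
    results = []
    for comp in COMPARTMENT_LABELS:
        in_comp = labels == comp
        is_sig = labels.index.isin(list(sig))
        a = int((in_comp & is_sig).sum())
        b = int((in_comp & ~is_sig).sum())
        c = int((~in_comp & is_sig).sum())
        d = int((~in_comp & ~is_sig).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = min(a, b, c, d) == 0
        if haldane:
            aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        else:
            aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        odds = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci = (float(np.exp(np.log(odds) - 1.96 * se)), float(np.exp(np.log(odds) + 1.96 * se)))
        results.append(
            ORResult(
                compartment=comp,
                direction=direction,
                table=(a, b, c, d),
                odds_ratio=float(odds),
                ci95=ci,
                p=float(p),
                haldane=haldane,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Expression linkage
# ---------------------------------------------------------------------------

METHYLATION_BINS = ((0, 10), (10, 20), (20, 50), (50, 80), (80, 100))


def _assign_bin(pct: float) -> str:
    """Left-closed right-open bins; the final bin is closed at 100."""
    for lo, hi in METHYLATION_BINS[:-1]:
        if lo <= pct < hi:
            return f"{lo}-{hi}"
    lo, hi = METHYLATION_BINS[-1]
    if lo <= pct <= hi:
        return f"{lo}-{hi}"
    raise ValidationError(f"percent methylation {pct} outside [0, 100]")


def expression_methylation_bins(
    expression: ExpressionTable,
    matrix: CpGCountMatrix,
    promoter_map: pd.DataFrame,
    cpg_islands: RegionSet,
) -> pd.DataFrame:
    """Mean expression of genes binned by promoter methylation.

    Each gene gets the mean percent methylation over the CpG sites inside
    its promoter interval (across all samples with data); genes fall into
    the bins 0-10, 10-20, 20-50, 50-80, 80-100 (left-closed right-open, last
    bin closed) and are split by whether the promoter overlaps a CpG island.
    Genes without promoter CpG data are excluded (count logged).
    """
    pct = matrix.percent()
    mean_expr = expression.mean_by_gene()
    rows = []
    n_excluded = 0
    for _, g in promoter_map.iterrows():
        gene = g["gene_id"]
        if gene not in mean_expr.index:
            n_excluded += 1
            continue
        try:
            chrom_sites = pct.loc[g["chromosome"]]
        except KeyError:
            n_excluded += 1
            continue
        pos = chrom_sites.index.to_numpy()
        inside = (pos - 1 >= g["start"]) & (pos - 1 < g["end"])
        vals = chrom_sites.loc[inside].to_numpy(dtype=float)
        if vals.size == 0 or np.all(np.isnan(vals)):
            n_excluded += 1
            continue
        meth = float(np.nanmean(vals))
        rows.append(
            {
                "gene_id": gene,
                "promoter_methylation": meth,
                "bin": _assign_bin(meth),
                "cpg_island": cpg_islands.overlaps(g["chromosome"], int(g["start"]), int(g["end"])),
                "log2_expression": float(mean_expr.loc[gene]),
            }
        )
    if n_excluded:
        logger.info("expression_methylation_bins: excluded %d genes without promoter CpG data", n_excluded)
    genes = pd.DataFrame(rows)
    if genes.empty:
        return pd.DataFrame(columns=["cpg_island", "bin", "mean_log2_expression", "n_genes"])
    out = (
        genes.groupby(["cpg_island", "bin"], sort=False)
        .agg(mean_log2_expression=("log2_expression", "mean"), n_genes=("gene_id", "size"))
        .reset_index()
    )
    bin_order = [f"{lo}-{hi}" for lo, hi in METHYLATION_BINS]
    out["bin"] = pd.Categorical(out["bin"], categories=bin_order, ordered=True)
    return out.sort_values(["cpg_island", "bin"]).reset_index(drop=True)


def correlate_dm_expression(
    delta_meth: Mapping[str, float],
    delta_expr: Mapping[str, float],
    min_genes: int = 3,
) -> tuple[float, float, int]:
    """Pearson correlation of per-gene methylation change with expression change."""
    genes = sorted(set(delta_meth) & set(delta_expr))
    if len(genes) < min_genes:
        raise InsufficientDataError(
            f"only {len(genes)} genes shared between deltas; need >= {min_genes}"
        )
    x = np.array([delta_meth[g] for g in genes], dtype=float)
    y = np.array([delta_expr[g] for g in genes], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in a delta vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(genes)


def stem_nonstem_concordance(
    matrix: CpGCountMatrix,
    sheet: SampleSheet,
    old_age: float,
    young_age: float,
    tissue: str | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation of per-site aging methylation change (old - young)
    between stem and nonstem samples.

    For each cell type, the per-site change is the difference of mean percent
    methylation between old and young samples; sites with both deltas defined
    enter the correlation.  Returns (r, p, n_sites).
    """
    pct = matrix.percent()
    deltas = {}
    for cell_type in ("stem", "nonstem"):
        old = sheet.samples_where(tissue=tissue, age_months=old_age, cell_type=cell_type)
        young = sheet.samples_where(tissue=tissue, age_months=young_age, cell_type=cell_type)
        old = [s for s in old if s in pct.columns]
        young = [s for s in young if s in pct.columns]
        if not old or not young:
            raise InsufficientDataError(f"no {cell_type} samples at both ages")
        deltas[cell_type] = pct[old].mean(axis=1) - pct[young].mean(axis=1)
    joined = pd.DataFrame(deltas).dropna()
    if len(joined) < 3:
        raise InsufficientDataError(f"only {len(joined)} sites with both deltas; need >= 3")
    x, y = joined["stem"].to_numpy(), joined["nonstem"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in a delta vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(joined)
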