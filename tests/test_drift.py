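"""Per-CpG drift statistics: filtering, differential methylation, permutation
testing, compartment enrichment and expression linkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methentropy as me
from methentropy.drift import _assign_bin
from methentropy.exceptions import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)


def matrix_from_arrays(meth, total, samples, positions=None, chrom="chr1"):
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    if positions is None:
        positions = 10 * (np.arange(meth.shape[0]) + 1)
    index = pd.MultiIndex.from_tuples([(chrom, int(p)) for p in positions])
    return me.CpGCountMatrix(
        pd.DataFrame(meth, index=index, columns=samples),
        pd.DataFrame(total, index=index, columns=samples),
    )


class TestFilterSites:
    def test_presence_boundary_inclusive(self):
        total = [[25, 25, 25, 10]]  # covered >= 20 in 3 of 4 samples: exactly 75%
        meth = [[5, 5, 5, 5]]
        m = me.filter_sites(matrix_from_arrays(meth, total, list("abcd")), 20, 0.75)
        assert m.n_sites == 1
        assert not m.present().iloc[0, 3]  # low-coverage cell masked

    def test_below_presence_dropped(self):
        total = [[25, 25, 10, 10]]
        meth = [[5, 5, 5, 5]]
        m = me.filter_sites(matrix_from_arrays(meth, total, list("abcd")), 20, 0.75)
        assert m.n_sites == 0

    def test_stricter_coverage_is_monotone(self, rng):
        total = rng.integers(0, 60, size=(200, 4))
        meth = rng.binomial(total, 0.3)
        m = matrix_from_arrays(meth, total, list("abcd"))
        kept20 = set(me.filter_sites(m, 20, 0.75).sites)
        kept30 = set(me.filter_sites(m, 30, 0.75).sites)
        assert kept30 <= kept20

    def test_invalid_presence_rejected(self):
        m = matrix_from_arrays([[20]], [[30]], ["a"])
        with pytest.raises(ValidationError):
            me.filter_sites(m, 20, 0.0)


class TestDifferentialMethylation:
    def test_identical_groups_not_significant(self):
        m = matrix_from_arrays([[50, 50]], [[100, 100]], ["a", "b"])
        res = me.differential_methylation(m, ["a"], ["b"])
        assert res["meth_diff"].iloc[0] == 0.0
        assert not res["significant"].iloc[0]

    def test_hand_computed_chi_square(self):
        # 10/100 vs 90/100: Yates-corrected chi-square = 4 * 39.5^2 / 50 = 124.82
        m = matrix_from_arrays([[10, 90]], [[100, 100]], ["a", "b"])
        res = me.differential_methylation(m, ["a"], ["b"])
        assert res["statistic"].iloc[0] == pytest.approx(124.82, abs=1e-9)
        assert res["meth_diff"].iloc[0] == pytest.approx(80.0)
        assert res["significant"].iloc[0]

    def test_small_difference_never_significant(self):
        # 4.8% vs 1.0%: |diff| = 3.8 < 5 percentage points, whatever q is
        m = matrix_from_arrays([[48, 10]], [[1000, 1000]], ["a", "b"])
        res = me.differential_methylation(m, ["a"], ["b"])
        assert res["meth_diff"].iloc[0] == pytest.approx(-3.8)
        assert res["q"].iloc[0] < 0.05 and not res["significant"].iloc[0]

    def test_agrees_with_textbook_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a_m, b_m = rng.integers(1, 200, 2)
            a_t = a_m + rng.integers(1, 200)
            b_t = b_m + rng.integers(1, 200)
            m = matrix_from_arrays([[a_m, b_m]], [[a_t, b_t]], ["a", "b"])
            res = me.differential_methylation(m, ["a"], ["b"])
            obs = np.array([[a_m, a_t - a_m], [b_m, b_t - b_m]], dtype=float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            d = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
            oracle = (d**2 / exp).sum()
            assert res["statistic"].iloc[0] == pytest.approx(oracle, abs=1e-9)
            assert res["p"].iloc[0] == pytest.approx(stats.chi2.sf(oracle, 1), abs=1e-9)

    def test_groups_pooled_and_missing_group_skipped(self):
        meth = [[10, 20, 30], [np.nan, np.nan, 5]]
        total = [[50, 50, 60], [np.nan, np.nan, 50]]
        m = matrix_from_arrays(meth, total, ["a1", "a2", "b"])
        res = me.differential_methylation(m, ["a1", "a2"], ["b"])
        assert len(res) == 1  # second site has no group-A data
        assert res["pct_a"].iloc[0] == pytest.approx(30.0)  # (10+20)/(50+50)

    def test_overlapping_groups_rejected(self):
        m = matrix_from_arrays([[1, 1]], [[10, 10]], ["a", "b"])
        with pytest.raises(ValidationError):
            me.differential_methylation(m, ["a"], ["a", "b"])

    def test_variance_inflation_deflates_significance(self):
        m = matrix_from_arrays([[30, 60]], [[100, 100]], ["a", "b"])
        plain = me.differential_methylation(m, ["a"], ["b"])
        inflated = me.differential_methylation(m, ["a"], ["b"], variance_inflation=5.0)
        assert inflated["statistic"].iloc[0] == pytest.approx(plain["statistic"].iloc[0] / 5)
        assert inflated["p"].iloc[0] > plain["p"].iloc[0]


def age_sheet(n_per_age=3, ages=(4.0, 12.0, 18.0, 24.0)):
    rows = []
    for a in ages:
        for k in range(n_per_age):
            rows.append((f"s{int(a)}_{k}", "colon", a, "stem", 1))
    return me.SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "tissue", "age_months", "cell_type", "pool_size"])
    )


class TestPermutationAgeTest:
    def test_monotone_methylation_has_rho_one(self):
        sheet = age_sheet()
        samples = sheet.sample_ids
        meth = np.arange(1, 13)[None, :] * 4
        total = np.full((1, 12), 100)
        m = matrix_from_arrays(meth, total, samples)
        res = me.permutation_age_test(m, sheet, n_perm=200, seed=1)
        # ages are tied in triples, methylation strictly increasing: rho < 1 exactly
        # but a perfectly age-sorted series maximizes it
        assert res["rho"].iloc[0] > 0.95
        assert res["direction"].iloc[0] == "hyper"

    def test_empirical_p_is_exceedance_fraction(self):
        sheet = age_sheet()
        rng = np.random.default_rng(0)
        meth = rng.integers(10, 90, size=(20, 12))
        m = matrix_from_arrays(meth, np.full((20, 12), 100), sheet.sample_ids)
        res = me.permutation_age_test(m, sheet, n_perm=250, seed=3)
        assert np.allclose(res["empirical_p"], res["r_exceed"] / 250)
        assert res["empirical_p"].between(0, 1).all()

    def test_moderate_rho_below_cutoff_is_none(self):
        sheet = age_sheet()
        rng = np.random.default_rng(5)
        found = None
        for _ in range(200):
            meth = rng.integers(10, 90, size=(1, 12))
            m = matrix_from_arrays(meth, np.full((1, 12), 100), sheet.sample_ids)
            res = me.permutation_age_test(m, sheet, n_perm=100, seed=1)
            rho = res["rho"].iloc[0]
            if not np.isnan(rho) and 0.3 < abs(rho) < 0.5:
                found = res
                break
        assert found is not None
        assert found["direction"].iloc[0] == "none"  # |rho| below 0.5 never called

    def test_constant_methylation_is_none_with_p_one(self):
        sheet = age_sheet()
        m = matrix_from_arrays(np.full((1, 12), 40), np.full((1, 12), 100), sheet.sample_ids)
        res = me.permutation_age_test(m, sheet, n_perm=100, seed=1)
        assert np.isnan(res["rho"].iloc[0])
        assert res["empirical_p"].iloc[0] == 1.0
        assert res["direction"].iloc[0] == "none"

    def test_fewer_than_three_ages_is_none(self):
        sheet = me.SampleSheet(
            pd.DataFrame(
                [(f"s{k}", "colon", a, "stem", 1) for k, a in enumerate([4.0] * 3 + [24.0] * 3)],
                columns=["sample_id", "tissue", "age_months", "cell_type", "pool_size"],
            )
        )
        m = matrix_from_arrays(
            [[10, 20, 30, 40, 50, 60]], np.full((1, 6), 100), sheet.sample_ids
        )
        res = me.permutation_age_test(m, sheet, n_perm=50, seed=1)
        assert res["direction"].iloc[0] == "none" and np.isnan(res["rho"].iloc[0])

    def test_raising_rho_cutoff_never_adds_calls(self, rng):
        sheet = age_sheet()
        meth = rng.integers(5, 95, size=(100, 12))
        m = matrix_from_arrays(meth, np.full((100, 12), 100), sheet.sample_ids)
        counts = []
        for cutoff in (0.3, 0.5, 0.7):
            res = me.permutation_age_test(m, sheet, n_perm=200, rho_cutoff=cutoff, seed=2)
            counts.append(int((res["direction"] != "none").sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_per_site_shuffles_mode(self, rng):
        sheet = age_sheet()
        meth = rng.integers(5, 95, size=(10, 12))
        m = matrix_from_arrays(meth, np.full((10, 12), 100), sheet.sample_ids)
        shared = me.permutation_age_test(m, sheet, n_perm=300, seed=2, shared_shuffles=True)
        persite = me.permutation_age_test(m, sheet, n_perm=300, seed=2, shared_shuffles=False)
        assert np.allclose(shared["rho"], persite["rho"], equal_nan=True)
        assert (np.abs(shared["empirical_p"] - persite["empirical_p"]) < 0.15).all()


class TestCompartments:
    def _regions(self):
        cpgi = me.RegionSet.from_intervals("cpgi", [("chr1", 100, 200)])
        prom = me.RegionSet.from_intervals("prom", [("chr1", 150, 300)])
        return cpgi, prom

    def test_four_way_labels(self):
        cpgi, prom = self._regions()
        sites = [("chr1", 160), ("chr1", 120), ("chr1", 250), ("chr1", 500)]
        labels = me.annotate_compartments(sites, cpgi, prom)
        assert labels.loc[("chr1", 160)] == "Promoter-CpGi"
        assert labels.loc[("chr1", 120)] == "nonPromoter-CpGi"
        assert labels.loc[("chr1", 250)] == "Promoter-nonCpGi"
        assert labels.loc[("chr1", 500)] == "nonPromoter-nonCpGi"

    def test_half_open_end_boundary(self):
        cpgi, prom = self._regions()
        # 1-based position 200 is the base at 0-based 199 (inside); 201 is outside
        labels = me.annotate_compartments([("chr1", 200), ("chr1", 201)], cpgi, prom)
        assert labels.loc[("chr1", 200)] == "Promoter-CpGi"
        assert labels.loc[("chr1", 201)] == "Promoter-nonCpGi"


def build_labels(spec):
    """spec: mapping compartment -> (n_sig, n_notsig); returns labels + sig set."""
    rows, sig = [], set()
    pos = 1
    for comp, (n_sig, n_not) in spec.items():
        for _ in range(n_sig):
            rows.append((("chr1", pos), comp))
            sig.add(("chr1", pos))
            pos += 1
        for _ in range(n_not):
            rows.append((("chr1", pos), comp))
            pos += 1
    labels = pd.Series(
        [c for _, c in rows], index=pd.MultiIndex.from_tuples([s for s, _ in rows])
    )
    return labels, sig


class TestOddsRatio:
    def test_worked_table(self):
        labels, sig = build_labels(
            {"Promoter-CpGi": (30, 70), "nonPromoter-nonCpGi": (10, 190)}
        )
        res = {r.compartment: r for r in me.compartment_odds_ratio(labels, sig)}
        r = res["Promoter-CpGi"]
        assert r.table == (30, 70, 10, 190)
        assert r.odds_ratio == pytest.approx(30 * 190 / (70 * 10))
        assert not r.haldane

    def test_independent_margins_give_or_one(self):
        labels, sig = build_labels(
            {"Promoter-CpGi": (20, 80), "nonPromoter-nonCpGi": (40, 160)}
        )
        r = {x.compartment: x for x in me.compartment_odds_ratio(labels, sig)}["Promoter-CpGi"]
        assert r.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane_flagged(self):
        labels, sig = build_labels(
            {"Promoter-CpGi": (0, 50), "nonPromoter-nonCpGi": (25, 125)}
        )
        r = {x.compartment: x for x in me.compartment_odds_ratio(labels, sig)}["Promoter-CpGi"]
        assert r.haldane and np.isfinite(r.odds_ratio)
        assert r.ci95[0] < r.odds_ratio < r.ci95[1]

    def test_fisher_p_matches_hypergeometric_enumeration(self, rng):
        def oracle(a, b, c, d):
            M, n, N = a + b + c + d, a + b, a + c
            support = range(max(0, n + N - M), min(n, N) + 1)
            pmf = {k: stats.hypergeom.pmf(k, M, n, N) for k in support}
            return float(sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-7)))

        checked = 0
        while checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if a + b + c + d == 0 or a + b + c + d > 60:
                continue
            if (a + b) == 0 or (c + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(oracle(a, b, c, d), abs=1e-9)
            checked += 1

    def test_unlabeled_significant_sites_rejected(self):
        labels, _ = build_labels({"Promoter-CpGi": (1, 1)})
        with pytest.raises(ValidationError):
            me.compartment_odds_ratio(labels, {("chrX", 999)})


class TestExpressionLinkage:
    @pytest.mark.parametrize(
        "pct,expected",
        [(0.0, "0-10"), (10.0, "10-20"), (19.99, "10-20"), (20.0, "20-50"),
         (80.0, "80-100"), (100.0, "80-100")],
    )
    def test_bin_boundaries(self, pct, expected):
        assert _assign_bin(pct) == expected

    def test_bins_split_by_island_status(self):
        # two genes: one CpG-island promoter at low methylation, one non-island high
        expr = me.ExpressionTable(
            pd.DataFrame(
                {
                    "gene_id": ["gA", "gA", "gB", "gB"],
                    "sample_id": ["s1", "s2", "s1", "s2"],
                    "log2_expression": [5.0, 6.0, 1.0, 2.0],
                }
            )
        )
        matrix = matrix_from_arrays(
            [[2, 2], [90, 90]], [[100, 100], [100, 100]], ["s1", "s2"],
            positions=[150, 450],
        )
        promoters = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chromosome": ["chr1", "chr1"],
                "start": [100, 400],
                "end": [200, 500],
            }
        )
        cpgi = me.RegionSet.from_intervals("cpgi", [("chr1", 100, 200)])
        out = me.expression_methylation_bins(expr, matrix, promoters, cpgi)
        island = out[out["cpg_island"]]
        non = out[~out["cpg_island"]]
        assert island["bin"].iloc[0] == "0-10"
        assert island["mean_log2_expression"].iloc[0] == pytest.approx(5.5)
        assert non["bin"].iloc[0] == "80-100"
        assert non["mean_log2_expression"].iloc[0] == pytest.approx(1.5)

    def test_gene_without_promoter_data_excluded(self):
        expr = me.ExpressionTable(
            pd.DataFrame({"gene_id": ["g"], "sample_id": ["s1"], "log2_expression": [3.0]})
        )
        matrix = matrix_from_arrays([[5]], [[100]], ["s1"], positions=[10_000])
        promoters = pd.DataFrame(
            {"gene_id": ["g"], "chromosome": ["chr1"], "start": [0], "end": [100]}
        )
        out = me.expression_methylation_bins(
            expr, matrix, promoters, me.RegionSet.from_intervals("c", [])
        )
        assert out.empty

    def test_exact_inverse_correlation(self):
        dm = {f"g{i}": float(i) for i in range(10)}
        de = {f"g{i}": -2.0 * i for i in range(10)}
        r, p, n = me.correlate_dm_expression(dm, de)
        assert r == pytest.approx(-1.0) and n == 10

    def test_independent_deltas_average_to_zero(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(30)]
            dm = dict(zip(genes, rng.normal(size=30)))
            de = dict(zip(genes, rng.normal(size=30)))
            r, _, _ = me.correlate_dm_expression(dm, de)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.06

    def test_too_few_genes_rejected(self):
        with pytest.raises(InsufficientDataError):
            me.correlate_dm_expression({"g1": 1.0, "g2": 2.0}, {"g1": 0.0, "g2": 1.0})

    def test_zero_variance_rejected(self):
        dm = {f"g{i}": 1.0 for i in range(5)}
        de = {f"g{i}": float(i) for i in range(5)}
        with pytest.raises(UndefinedStatisticError):
            me.correlate_dm_expression(dm, de)


class TestConcordance:
    def test_matches_direct_correlation(self, rng, sheet_factory):
        sheet = sheet_factory(
            [
                ("ys", "colon", 4.0, "stem", 1),
                ("os", "colon", 24.0, "stem", 1),
                ("yn", "colon", 4.0, "nonstem", 1),
                ("on", "colon", 24.0, "nonstem", 1),
            ]
        )
        n = 80
        base = rng.uniform(20, 80, n)
        shift = rng.normal(0, 10, n)
        pct = np.clip(
            np.column_stack([base, base + shift, base, base + shift + rng.normal(0, 3, n)]),
            1, 99,
        )
        total = np.full((n, 4), 1000)
        meth = np.round(pct / 100 * 1000)
        m = matrix_from_arrays(meth, total, ["ys", "os", "yn", "on"])
        r, p, n_sites = me.stem_nonstem_concordance(m, sheet, 24.0, 4.0)
        pcts = m.percent()
        direct = np.corrcoef(pcts["os"] - pcts["ys"], pcts["on"] - pcts["yn"])[0, 1]
        assert n_sites == n
        assert r == pytest.approx(direct, abs=1e-12)
        assert r > 0.8
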