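import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from methexpress import ValidationError
from methexpress.integrate import (
    ExpressionClass,
    category_table,
    chi_square,
    classify_expression,
    classify_meth_level,
    density_summary,
    prediction_probability,
    prediction_table,
    relationship_table,
)
from methexpress.regions import RegionClass
from .conftest import make_annotation, make_design


def make_records(rows):
    """Integration records from (cpg, gene, region, beta_f, beta_a,
    meth_q, expr_class, fold_change, expr_q) tuples."""
    rec = pd.DataFrame(
        rows,
        columns=["cpg_id", "gene", "region_class", "beta_fetal",
                 "beta_adult", "meth_q", "expr_class", "fold_change",
                 "expr_q"],
    )
    rec["delta_beta"] = rec["beta_adult"] - rec["beta_fetal"]
    rec["fetal_level"] = classify_meth_level(rec["beta_fetal"].to_numpy())
    rec["adult_level"] = classify_meth_level(rec["beta_adult"].to_numpy())
    return rec


def brute_force_prediction(records, direction, cut, region, fold_cuts,
                           q_cut=0.05, require_expr_q=True):
    """Independent per-row scan of the prediction probability."""
    qualifying = {}
    hits = {fc: set() for fc in fold_cuts}
    for _, r in records.iterrows():
        if r["meth_q"] > q_cut or r["region_class"] != region.value:
            continue
        db = r["delta_beta"]
        if direction == "decrease" and not db <= -cut:
            continue
        if direction == "increase" and not db >= cut:
            continue
        qualifying[r["cpg_id"]] = True
        if require_expr_q and r["expr_q"] > q_cut:
            continue
        for fc in fold_cuts:
            if direction == "decrease" and r["fold_change"] <= -fc:
                hits[fc].add(r["cpg_id"])
            if direction == "increase" and r["fold_change"] >= fc:
                hits[fc].add(r["cpg_id"])
    n = len(qualifying)
    if n == 0:
        return 0, None, None
    return n, len(hits[fold_cuts[0]]) / n, len(hits[fold_cuts[1]]) / n


def brute_force_category(records, context, region, tissue):
    col = "fetal_level" if tissue == "fetal" else "adult_level"
    counts = {"HYPO": 0, "INTERMEDIATE": 0, "HYPER": 0}
    for _, r in records.iterrows():
        if r["expr_class"] == context and r["region_class"] == region:
            counts[r[col]] += 1
    return counts


class TestClassification:
    def test_expression_classes(self):
        diff = pd.DataFrame(
            {"fold_change": [6.0, 1.05, 3.0, -7.0, -1.05],
             "q": [0.01, 0.2, 0.01, 0.001, 0.5]},
            index=["g1", "g2", "g3", "g4", "g5"],
        )
        cls = classify_expression(diff)
        assert cls["g1"] == "FETAL_OVER"
        assert cls["g2"] == "SIMILAR"
        assert cls["g3"] == "OTHER"   # significant but between thresholds
        assert cls["g4"] == "ADULT_OVER"
        assert cls["g5"] == "SIMILAR"

    def test_classification_is_total_partition(self):
        rng = np.random.default_rng(0)
        diff = pd.DataFrame({
            "fold_change": np.where(rng.random(300) < 0.5, 1, -1)
            * np.exp(rng.normal(0.5, 1, 300)),
            "q": rng.random(300),
        })
        cls = classify_expression(diff)
        assert cls.isin([c.value for c in ExpressionClass]).all()
        assert len(cls) == 300

    @pytest.mark.parametrize("beta,expected", [
        (0.25, "HYPO"), (0.0, "HYPO"), (0.30, "INTERMEDIATE"),
        (0.69, "INTERMEDIATE"), (0.70, "HYPER"), (1.0, "HYPER"),
    ])
    def test_meth_level_boundaries(self, beta, expected):
        assert classify_meth_level(beta) == expected

    def test_meth_level_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_meth_level(1.3)


@pytest.fixture
def toy_differential():
    """5-CpG / 3-gene joined fixture for the filtering hierarchy."""
    meth = pd.DataFrame(
        {
            "mean_fetal": [0.9, 0.5, 0.4, 0.8, 0.2],
            "mean_adult": [0.4, 0.45, 0.41, 0.3, 0.21],
            "q": [0.01, 0.01, 0.2, 0.01, 0.01],
        },
        index=[f"cg{i}" for i in range(5)],
    )
    meth["delta_beta"] = meth["mean_adult"] - meth["mean_fetal"]
    annot = make_annotation([
        ("cg0", "1", 1, "GENEA", "TSS200", ""),
        ("cg1", "1", 2, "GENEA", "Body", ""),
        ("cg2", "1", 3, "GENEB", "TSS1500", ""),
        ("cg3", "1", 4, "GENEB", "1stExon", ""),
        ("cg4", "1", 5, "GENEC", "Body", ""),
    ])
    from methexpress.regions import build_links
    links = build_links(annot)
    expr = pd.DataFrame(
        {"fold_change": [-6.0, 2.0, 1.01], "q": [0.01, 0.2, 0.9],
         "mean_fetal": [5, 8, 7], "mean_adult": [7.58, 7, 7]},
        index=["GENEA", "GENEB", "GENEC"],
    )
    return meth, links, expr


class TestRelationshipTable:
    def test_panel_a_includes_every_q_significant_gene(self, toy_differential):
        meth, links, expr = toy_differential
        tbl = relationship_table(meth, links, expr, q_cut=0.05)
        assert set(tbl["gene"]) == {"GENEA", "GENEB", "GENEC"}

    def test_dbeta_filter_never_increases_gene_count(self, toy_differential):
        meth, links, expr = toy_differential
        a = relationship_table(meth, links, expr, q_cut=0.05)
        b = relationship_table(meth, links, expr, q_cut=0.05,
                               min_abs_dbeta=0.2)
        assert len(b) <= len(a)
        assert set(b["gene"]) <= set(a["gene"])

    def test_panel_d_toy_fixture(self, toy_differential):
        """Only genes with a q-significant TSS/Ex1 CpG at |dbeta|>0.2
        survive the combined filter; brute-force check on 5 rows."""
        meth, links, expr = toy_differential
        d = relationship_table(meth, links, expr, q_cut=0.05,
                               min_abs_dbeta=0.2,
                               region=RegionClass.TSS_EX1)
        # cg0 (GENEA, TSS200, q .01, dbeta -.5) and cg3 (GENEB, 1stExon,
        # q .01, dbeta -.5) qualify; GENEC's only CpG is Body
        assert set(d["gene"]) == {"GENEA", "GENEB"}
        ga = d.set_index("gene").loc["GENEA"]
        assert ga["mean_beta_fetal"] == pytest.approx(0.9)
        assert ga["n_cpgs"] == 1

    def test_hierarchy_superset_chain(self, coupled_analysis):
        dm, links, de = (coupled_analysis["dm"], coupled_analysis["links"],
                         coupled_analysis["de"])
        genes = {}
        genes["a"] = set(relationship_table(dm, links, de)["gene"])
        genes["b"] = set(relationship_table(dm, links, de,
                                            min_abs_dbeta=0.2)["gene"])
        genes["c"] = set(relationship_table(
            dm, links, de, region=RegionClass.TSS_EX1)["gene"])
        genes["d"] = set(relationship_table(
            dm, links, de, min_abs_dbeta=0.2,
            region=RegionClass.TSS_EX1)["gene"])
        assert genes["a"] >= genes["b"] >= genes["d"]
        assert genes["a"] >= genes["c"] >= genes["d"]


class TestCategoryTable:
    def test_all_hypo_row(self):
        rows = [(f"cg{i}", "G1", "TSS_EX1", 0.1, 0.1, 0.01, "SIMILAR",
                 1.0, 0.5) for i in range(10)]
        tbl = category_table(make_records(rows))
        row = tbl[(tbl["context"] == "SIMILAR")
                  & (tbl["tissue"] == "fetal")
                  & (tbl["region_class"] == "TSS_EX1")].iloc[0]
        assert (row["pct_hypo"], row["pct_intermediate"], row["pct_hyper"]) \
            == (100, 0, 0)

    def test_rounding_half_up(self):
        betas = [0.1] * 5 + [0.5] * 2 + [0.9]
        rows = [(f"cg{i}", "G1", "TSS_EX1", b, b, 0.01, "SIMILAR", 1.0, 0.5)
                for i, b in enumerate(betas)]
        tbl = category_table(make_records(rows))
        row = tbl[(tbl["context"] == "SIMILAR")
                  & (tbl["tissue"] == "fetal")
                  & (tbl["region_class"] == "TSS_EX1")].iloc[0]
        assert (row["pct_hypo"], row["pct_intermediate"], row["pct_hyper"]) \
            == (63, 25, 13)

    def test_empty_context_not_divided(self):
        rows = [("cg0", "G1", "TSS_EX1", 0.1, 0.1, 0.01, "SIMILAR", 1.0, 0.5)]
        tbl = category_table(make_records(rows))
        empty = tbl[(tbl["context"] == "ADULT_OVER")
                    & (tbl["tissue"] == "fetal")
                    & (tbl["region_class"] == "TSS_EX1")].iloc[0]
        assert empty["n_cpgs"] == 0
        assert np.isnan(empty["pct_hypo"])

    def test_counts_match_brute_force(self, coupled_analysis):
        records = coupled_analysis["records"].head(100)
        tbl = category_table(records)
        for _, row in tbl.iterrows():
            expected = brute_force_category(records, row["context"],
                                            row["region_class"], row["tissue"])
            assert row["n_hypo"] == expected["HYPO"]
            assert row["n_intermediate"] == expected["INTERMEDIATE"]
            assert row["n_hyper"] == expected["HYPER"]


class TestChiSquare:
    def test_no_association(self):
        r = chi_square([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_hand_example(self):
        r = chi_square([[20, 10], [10, 20]])
        assert r.statistic == pytest.approx(20 / 3, abs=1e-3)
        assert r.df == 1
        assert r.p == pytest.approx(0.0098, abs=2e-4)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [5, 5]])

    def test_low_expected_flagged(self):
        assert chi_square([[1, 2], [2, 1]]).low_expected

    def test_closed_form_2x2(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 50, size=4)
            r = chi_square([[a, b], [c, d]])
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert r.statistic == pytest.approx(closed, rel=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        tbl = rng.integers(5, 40, size=(3, 3))
        r = chi_square(tbl)
        ref = chi2_contingency(tbl, correction=False)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert r.df == ref.dof


class TestPredictionProbability:
    def test_quarter_fixture(self):
        rows = [
            ("cg0", "G1", "TSS_EX1", 0.9, 0.4, 0.01, "ADULT_OVER", -6.0, 0.01),
            ("cg1", "G2", "TSS_EX1", 0.8, 0.3, 0.01, "SIMILAR", 1.0, 0.5),
            ("cg2", "G3", "TSS_EX1", 0.7, 0.2, 0.01, "SIMILAR", -1.05, 0.6),
            ("cg3", "G4", "TSS_EX1", 0.9, 0.5, 0.01, "OTHER", 1.5, 0.4),
            ("cg4", "G5", "UTR_GB", 0.9, 0.4, 0.01, "ADULT_OVER", -6.0, 0.01),
            ("cg5", "G6", "TSS_EX1", 0.2, 0.5, 0.01, "SIMILAR", 1.0, 0.5),
        ]
        r = prediction_probability(make_records(rows), "decrease", 0.2,
                                   RegionClass.TSS_EX1)
        assert r.n_cpgs == 4
        assert r.p_ge2fold == pytest.approx(0.25)

    def test_five_fold_nested_in_two_fold(self, coupled_analysis):
        tbl = prediction_table(coupled_analysis["records"])
        filled = tbl[~tbl["empty"]]
        assert (filled["p_ge5fold"] <= filled["p_ge2fold"] + 1e-12).all()

    def test_empty_guard(self):
        rows = [("cg0", "G1", "TSS_EX1", 0.5, 0.5, 0.9, "SIMILAR", 1.0, 0.5)]
        r = prediction_probability(make_records(rows), "decrease", 0.2,
                                   RegionClass.TSS_EX1)
        assert r.empty and r.n_cpgs == 0 and r.p_ge2fold is None

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for rep in range(10):
            n = int(rng.integers(5, 100))
            rows = []
            for i in range(n):
                bf, ba = rng.random(), rng.random()
                fc = float(np.where(rng.random() < 0.5, 1, -1)
                           * np.exp(rng.normal(1, 1)))
                rows.append((f"cg{rng.integers(0, n)}", f"G{i}",
                             str(rng.choice(["TSS_EX1", "UTR_GB"])),
                             bf, ba, float(rng.random()) * 0.2,
                             "SIMILAR", fc, float(rng.random()) * 0.2))
            rec = make_records(rows)
            for direction in ("decrease", "increase"):
                for region in (RegionClass.TSS_EX1, RegionClass.UTR_GB):
                    r = prediction_probability(rec, direction, 0.2, region)
                    n_bf, p2, p5 = brute_force_prediction(
                        rec, direction, 0.2, region, (2.0, 5.0))
                    assert r.n_cpgs == n_bf
                    if n_bf:
                        assert r.p_ge2fold == pytest.approx(p2)
                        assert r.p_ge5fold == pytest.approx(p5)
                    else:
                        assert r.empty


class TestDensitySummary:
    def test_single_value_unit_mass(self):
        rows = [("cg0", "G1", "TSS_EX1", 0.12, 0.12, 0.01, "SIMILAR",
                 1.0, 0.5)]
        dens = density_summary(make_records(rows))
        fetal = dens[dens["tissue"] == "fetal"]
        hot = fetal[fetal["density"] > 0]
        assert len(hot) == 1
        assert hot.iloc[0]["bin_left"] == pytest.approx(0.10)
        assert hot.iloc[0]["density"] == pytest.approx(20.0)  # 1/0.05

    def test_densities_integrate_to_one(self, coupled_analysis):
        dens = density_summary(coupled_analysis["records"])
        for _, grp in dens.groupby(["tissue", "context", "stratum"]):
            area = (grp["density"]
                    * (grp["bin_right"] - grp["bin_left"])).sum()
            assert area == pytest.approx(1.0, abs=1e-9)

    def test_coupled_adult_over_context_is_fetal_hypermethylated(
            self, coupled_analysis):
        """Adult-overexpressed genes carry fetal TSS/Ex1 hypermethylation
        (mass in [0.7,1]) well above the similarly-expressed background."""
        records = coupled_analysis["records"]
        filt = records[(records["meth_q"] <= 0.05)
                       & (records["delta_beta"].abs() > 0.2)]
        dens = density_summary(filt)

        def hyper_mass(context):
            sub = dens[(dens["tissue"] == "fetal")
                       & (dens["context"] == context)
                       & (dens["stratum"] == "TSS_EX1")
                       & (dens["bin_left"] >= 0.7 - 1e-9)]
            return (sub["density"]
                    * (sub["bin_right"] - sub["bin_left"])).sum()

        assert hyper_mass("ADULT_OVER") > hyper_mass("SIMILAR") + 0.2
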