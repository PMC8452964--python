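"""Expression normalization and the differential test battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmdscape import differential as diff
from pmdscape import simulate


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _counts_frame(rows, samples):
    return pd.DataFrame(rows, columns=samples)


def test_rpkm_closed_form_single_sample():
    counts = pd.DataFrame({"s1": [10, 999_990]}, index=["g1", "g2"])
    lengths = pd.Series([1000, 100_000], index=["g1", "g2"])
    strata = pd.Series(["pc", "pc"], index=["g1", "g2"])
    res = diff.normalize_expression(counts, lengths, strata, pseudocount=0.0)
    # library = 1 M reads, 1-kb gene with 10 reads -> RPKM 10, log2 = 3.32
    assert np.isclose(res["rpkm"].loc["g1", "s1"], 10.0)
    assert np.isclose(res["log2_rpkm"].loc["g1", "s1"], np.log2(10), atol=1e-9)


def test_rpkm_invariant_to_library_scaling():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(5, 1000, size=(50, 3)),
                          index=[f"g{i}" for i in range(50)], columns=list("abc"))
    lengths = pd.Series(rng.integers(500, 5000, size=50), index=counts.index)
    strata = pd.Series("pc", index=counts.index)
    res1 = diff.normalize_expression(counts, lengths, strata)
    res2 = diff.normalize_expression(counts * 2, lengths, strata)
    pd.testing.assert_frame_equal(res1["rpkm"], res2["rpkm"])


def test_expression_filter_drops_low_genes():
    counts = pd.DataFrame({"a": [4, 5, 0], "b": [4, 0, 100]}, index=["lo", "mid", "hi"])
    lengths = pd.Series([1000] * 3, index=counts.index)
    strata = pd.Series("pc", index=counts.index)
    res = diff.normalize_expression(counts, lengths, strata, min_reads=5, min_samples=1)
    assert "lo" not in res["kept"] and {"mid", "hi"} <= set(res["kept"])


def test_small_stratum_passes_through_unscaled(caplog):
    counts = pd.DataFrame({"a": [10, 20, 100, 200, 300, 400],
                           "b": [30, 60, 100, 200, 300, 400]},
                          index=[f"g{i}" for i in range(6)])
    strata = pd.Series(["linc", "linc", "pc", "pc", "pc", "pc"], index=counts.index)
    lengths = pd.Series([1000] * 6, index=counts.index)
    with caplog.at_level("WARNING"):
        res = diff.normalize_expression(counts, lengths, strata)
    assert "unscaled" in caplog.text
    # lincRNA stratum kept its raw counts
    pd.testing.assert_frame_equal(res["scaled"].loc[["g0", "g1"]],
                                  counts.loc[["g0", "g1"]].astype(float))


def test_upper_quartile_scaling_equalizes_strata_quartiles():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        {"a": rng.integers(10, 100, 40), "b": rng.integers(10, 100, 40) * 3},
        index=[f"g{i}" for i in range(40)],
    )
    strata = pd.Series("pc", index=counts.index)
    lengths = pd.Series(1000, index=counts.index)
    res = diff.normalize_expression(counts, lengths, strata)
    uq = res["scaled"].quantile(0.75)
    assert np.isclose(uq["a"], uq["b"], rtol=1e-9)


# ---------------------------------------------------------------------------
# reliability filter
# ---------------------------------------------------------------------------


def _region_matrix(data, bios, techs):
    cols = pd.MultiIndex.from_tuples([(b, t) for b in bios for t in techs])
    return pd.DataFrame(data, columns=cols)


def test_reliability_filter_matches_anova_oracle():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(30, 6))
    X = _region_matrix(data, ["b1", "b2", "b3"], ["t1", "t2"])
    res = diff.reliability_filter(X)
    for i in range(30):
        groups = [data[i, 0:2], data[i, 2:4], data[i, 4:6]]
        F, p = stats.f_oneway(*groups)
        assert np.isclose(res["F"].iloc[i], F, rtol=1e-9)
        assert np.isclose(res["p"].iloc[i], p, rtol=1e-9)


def test_reliability_filter_retains_consistent_regions():
    # technical replicates identical, biological samples far apart -> retained
    row = [[0.0, 0.0, 5.0, 5.0, 10.0, 10.0]] * 3
    X = _region_matrix(np.array(row), ["b1", "b2", "b3"], ["t1", "t2"])
    res = diff.reliability_filter(X)
    assert res["reliable"].all()


def test_reliability_filter_counts_incomplete_regions():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(5, 4)).astype(object)
    data[0][1] = np.nan
    X = _region_matrix(np.array(data, dtype=float), ["b1", "b2"], ["t1", "t2"])
    res = diff.reliability_filter(X)
    assert res.attrs["n_excluded"] == 1 and len(res) == 4


def test_reliability_filter_validates_design():
    X = _region_matrix(np.zeros((3, 2)), ["b1", "b2"], ["t1"])
    with pytest.raises(ValueError):
        diff.reliability_filter(X)


# ---------------------------------------------------------------------------
# DHR linear model
# ---------------------------------------------------------------------------


def _dhr_data(rng, n_regions=30, n_cg=5, delta=0.0, planted=()):
    rows = []
    for r in range(n_regions):
        base_cg = rng.normal(1.0, 0.3, size=n_cg)
        for ci in range(n_cg):
            for cell in ("N", "S"):
                for cond in ("normoxia", "hypoxia"):
                    v = base_cg[ci] + rng.normal(0, 0.1)
                    if r in planted and cond == "hypoxia":
                        v += delta
                    rows.append((f"r{r}", f"cg{ci}", cell, cond, v))
    return pd.DataFrame(rows, columns=["region", "cg_id", "cell", "condition", "value"])


def test_dhr_planted_condition_effect_detected_with_direction():
    rng = np.random.default_rng(4)
    data = _dhr_data(rng, n_regions=20, delta=1.5, planted={0, 1, 2})
    res = diff.dhr_test(data)
    cond = res["anova"][res["anova"].term == "condition"].set_index("region")
    assert cond.loc[["r0", "r1", "r2"], "significant"].all()
    tk = res["tukey"]
    hyp = tk[(tk.term == "condition") & (tk.region == "r0")].iloc[0]
    # alphabetical groups: group1=hypoxia, group2=normoxia; hypoxia is higher
    assert hyp.reject and hyp.direction == "Down"


def test_dhr_single_cg_region_still_estimable():
    rng = np.random.default_rng(5)
    data = _dhr_data(rng, n_regions=1, n_cg=1)
    res = diff.dhr_test(data)
    assert len(res["anova"]) == 2  # both terms tested, no crash
    assert res["n_skipped"] == 0


def test_dhr_f_matches_explicit_nested_ols():
    rng = np.random.default_rng(6)
    data = _dhr_data(rng, n_regions=1, n_cg=4, delta=0.8, planted={0})
    res = diff.dhr_test(data)["anova"].set_index("term")
    sub = data[data.region == "r0"]
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fit = smf.ols("value ~ C(cell) + C(condition) + C(cg_id)", data=sub).fit()
    tab = anova_lm(fit, typ=2)
    assert np.isclose(res.loc["cell", "F"], tab.loc["C(cell)", "F"], rtol=1e-8)
    assert np.isclose(res.loc["condition", "F"], tab.loc["C(condition)", "F"], rtol=1e-8)


# ---------------------------------------------------------------------------
# DHG paired t-test
# ---------------------------------------------------------------------------


def test_dhg_zero_variance_conventions():
    pairs = pd.DataFrame(
        {
            "gene": ["same"] * 3 + ["shift"] * 3,
            "stratum": "pc",
            "x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "y": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
        }
    )
    res = diff.dhg_paired_ttest(pairs).set_index("gene")
    assert res.loc["same", "p"] == 1.0
    assert res.loc["shift", "p"] == 0.0  # constant non-zero difference
    assert res.loc["shift", "direction"] == "Down"  # x - y = -1


def test_dhg_matches_textbook_paired_t():
    rng = np.random.default_rng(7)
    x = rng.normal(size=12)
    y = x + rng.normal(0.3, 0.5, size=12)
    pairs = pd.DataFrame({"gene": "g", "stratum": "pc", "x": x, "y": y})
    res = diff.dhg_paired_ttest(pairs)
    d = x - y
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
    assert np.isclose(res["t"].iloc[0], t_oracle, rtol=1e-10)
    assert np.isclose(res["p"].iloc[0], p_oracle, rtol=1e-10)


def test_dhg_bh_within_stratum_and_skips_single_pairs():
    rng = np.random.default_rng(8)
    rows = []
    for g in range(6):
        for _ in range(5):
            rows.append((f"g{g}", "pc" if g < 3 else "linc",
                         rng.normal(), rng.normal()))
    rows.append(("lonely", "pc", 0.0, 1.0))
    pairs = pd.DataFrame(rows, columns=["gene", "stratum", "x", "y"])
    res = diff.dhg_paired_ttest(pairs)
    assert "lonely" not in set(res["gene"])
    for stratum, sub in res.groupby("stratum"):
        q_by_p = sub.sort_values("p")["q"].values
        assert (np.diff(q_by_p) >= -1e-12).all()  # BH is monotone within stratum
        assert (sub["q"] >= sub["p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# DEG exact test
# ---------------------------------------------------------------------------


def test_deg_equal_counts_null():
    counts = pd.DataFrame({"a1": [50], "a2": [50], "b1": [50], "b2": [50]}, index=["g"])
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    res = diff.deg_exact_test(counts, groups)
    assert np.isclose(res.loc["g", "log2fc"], 0.0)
    assert np.isclose(res.loc["g", "p"], 1.0)


def test_deg_label_symmetry():
    rng = np.random.default_rng(9)
    counts = pd.DataFrame(
        rng.integers(0, 300, size=(25, 4)),
        index=[f"g{i}" for i in range(25)], columns=["a1", "a2", "b1", "b2"],
    )
    g1 = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    g2 = pd.Series(["B", "B", "A", "A"], index=counts.columns)
    r1 = diff.deg_exact_test(counts, g1)
    r2 = diff.deg_exact_test(counts, g2)
    np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-12)
    # the first-encountered group is the numerator: reordering flips the sign
    r3 = diff.deg_exact_test(counts, g1.reindex(["b1", "b2", "a1", "a2"]))
    np.testing.assert_allclose(r1["log2fc"], -r3["log2fc"], rtol=1e-9)


def test_deg_converges_to_exact_poisson_split():
    """At vanishing dispersion the conditional law is Binomial(t, nA/(nA+nB))."""
    rng = np.random.default_rng(10)
    max_dp = 0.0
    for _ in range(20):
        sa, sb = int(rng.integers(0, 80)), int(rng.integers(0, 80))
        if sa + sb == 0:
            continue
        p_nb = diff._exact_nb_pvalue(sa, sb, 2, 2, 1e-12)
        t = sa + sb
        pmf = stats.binom.pmf(np.arange(t + 1), t, 0.5)
        p_pois = pmf[pmf <= pmf[sa] * (1 + 1e-10)].sum()
        max_dp = max(max_dp, abs(p_nb - p_pois))
    assert max_dp < 0.01


def test_deg_fold_change_gate():
    # equal library sizes anchored by a large stable gene
    counts = pd.DataFrame({"a": [100, 9900], "b": [12, 9988]}, index=["g", "anchor"])
    groups = pd.Series(["A", "B"], index=["a", "b"])
    res = diff.deg_exact_test(counts, groups)
    assert abs(res.loc["g", "log2fc"]) > 0.5  # log2(100/12) ~ 3.06


def test_deg_skips_zero_genes_and_requires_two_groups():
    counts = pd.DataFrame({"a": [0, 5], "b": [0, 1]}, index=["z", "g"])
    groups = pd.Series(["A", "B"], index=["a", "b"])
    res = diff.deg_exact_test(counts, groups)
    assert "z" not in res.index
    with pytest.raises(ValueError):
        diff.deg_exact_test(counts, pd.Series(["A", "A"], index=["a", "b"]))


# ---------------------------------------------------------------------------
# influence model
# ---------------------------------------------------------------------------


def _toy_flags(rng, n):
    return pd.DataFrame(
        {
            "hmch": rng.random(n) < 0.4,
            "pmd_inside": rng.random(n) < 0.3,
            "pmd_edge": rng.random(n) < 0.2,
            "enhancer": rng.random(n) < 0.3,
        },
        index=[f"g{i}" for i in range(n)],
    )


def test_influence_glm_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    flags = _toy_flags(rng, 40)
    y = pd.Series(rng.normal(size=40), index=flags.index)
    model = diff.fit_influence_glm(y, flags)
    X = flags.astype(float)
    X["hmch_x_pmd"] = (flags["hmch"] & (flags["pmd_inside"] | flags["pmd_edge"])).astype(float)
    X.insert(0, "const", 1.0)
    beta = np.linalg.solve(X.T.values @ X.values, X.T.values @ y.values)
    np.testing.assert_allclose(model.params.values, beta, rtol=1e-8)


def test_influence_glm_null_coefficients_small():
    rng = np.random.default_rng(12)
    checks, hits = 0, 0
    for _ in range(20):
        flags = _toy_flags(rng, 200)
        y = pd.Series(rng.normal(size=200), index=flags.index)
        model = diff.fit_influence_glm(y, flags)
        within = model.params.drop("const").abs() < 2 * model.bse.drop("const")
        checks += len(within)
        hits += int(within.sum())
    assert hits / checks >= 0.88  # ~95% nominal per-coefficient 2-SE coverage


def test_influence_glm_drops_collinear_predictor():
    rng = np.random.default_rng(13)
    flags = _toy_flags(rng, 50)
    flags["pmd_edge"] = flags["pmd_inside"]  # perfectly collinear after interaction? no:
    flags["enhancer"] = flags["hmch"]        # force exact collinearity
    y = pd.Series(rng.normal(size=50), index=flags.index)
    model = diff.fit_influence_glm(y, flags)
    assert "enhancer" in model.dropped


def test_influence_glm_recovers_planted_effects(small_genome, small_methylomes, small_truth):
    cfg = simulate.SimulationConfig(
        seed=14, chrom_lengths=dict(small_genome.layout.lengths),
        beta_hmch=0.8, beta_pmd_inside=-1.2, n_samples=8,
    )
    feats = simulate.gene_epigenome_features(
        small_genome, small_methylomes["cell0"], small_truth["cell0"]
    )
    mat, betas = simulate.simulate_expression(cfg, feats, np.random.default_rng(14))
    # log2 of the mean count per kb is the GLM's response scale
    y = np.log2(mat.mean(axis=1) / (feats["length"] / 1000.0) + 0.25)
    model = diff.fit_influence_glm(y, feats)
    if "pmd_inside" in model.params:
        planted_log2 = betas["pmd_inside"] / np.log(2)
        assert abs(model.params["pmd_inside"] - planted_log2) < 3 * model.bse["pmd_inside"] + 0.3


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def test_correlation_monotone_transform_gives_rho_one():
    genes = [f"g{i}" for i in range(20)]
    expr = pd.Series(np.linspace(0, 5, 20), index=genes)
    feats = pd.DataFrame({"body_ucg": np.exp(expr.values)}, index=genes)
    classes = pd.Series("Inside", index=genes)
    res = diff.correlate_modification_expression(classes, feats, expr)
    assert np.isclose(res["rho"].iloc[0], 1.0)


def test_correlation_matches_rank_oracle_and_flags_constant():
    rng = np.random.default_rng(15)
    genes = [f"g{i}" for i in range(20)]
    expr = pd.Series(rng.normal(size=20), index=genes)
    feats = pd.DataFrame(
        {"f": rng.normal(size=20), "const": np.ones(20)}, index=genes
    )
    classes = pd.Series("Outside", index=genes)
    res = diff.correlate_modification_expression(classes, feats, expr).set_index("feature")
    rho, p = stats.spearmanr(feats["f"], expr)
    assert np.isclose(res.loc["f", "rho"], rho)
    assert np.isclose(res.loc["f", "p"], p)
    assert not res.loc["const", "defined"]
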