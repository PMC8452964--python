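"""Differential statistics linking h-density, expression and genome features.

Covers: stratified upper-quartile + RPKM expression normalization; the
technical-reliability ANOVA filter for 1-kb regions; the region-level linear
model with Tukey HSD contrasts (DHRs); the per-gene paired t-test over CpG
sites (DHGs); an exact conditional negative-binomial test at fixed, known
dispersion (DEGs); the Gaussian influence model of epigenomic covariates on
expression; and Spearman correlations between modification fractions and
expression by PMD gene class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------


def normalize_expression(counts: pd.DataFrame, lengths: pd.Series, strata: pd.Series,
                         min_reads: int = 5, min_samples: int = 1,
                         pseudocount: float = 0.25) -> dict:
    """Stratified upper-quartile scaling followed by log2 RPKM.

    Per stratum (gene type), genes with at least ``min_reads`` reads in at
    least ``min_samples`` samples are kept; each sample's counts in the
    stratum are scaled so its upper quartile of kept-gene counts matches the
    geometric mean of the per-sample upper quartiles.  RPKM uses the scaled
    counts and scaled total library size.  Strata with fewer than four
    expressed genes pass through unscaled with a warning.

    Returns a dict with ``log2_rpkm``, ``rpkm``, ``scaled`` (DataFrames over
    kept genes) and ``kept`` (index).
    """
    counts = counts.astype(float)
    expressed = (counts >= min_reads).sum(axis=1) >= min_samples
    kept = counts.index[expressed]
    scaled_parts = []
    for stratum in strata.loc[kept].unique():
        genes = kept[strata.loc[kept] == stratum]
        sub = counts.loc[genes]
        if len(genes) < 4:
            logger.warning("stratum %r has %d expressed genes; left unscaled",
                           stratum, len(genes))
            scaled_parts.append(sub)
            continue
        uq = sub.quantile(0.75, axis=0)
        if (uq <= 0).any():
            logger.warning("stratum %r has a zero upper quartile; left unscaled", stratum)
            scaled_parts.append(sub)
            continue
        ref = np.exp(np.mean(np.log(uq)))
        scaled_parts.append(sub * (ref / uq))
    scaled = pd.concat(scaled_parts).loc[kept]
    libsize = scaled.sum(axis=0)
    rpkm = scaled.div(lengths.loc[kept] / 1e3, axis=0).div(libsize / 1e6, axis=1)
    log2_rpkm = np.log2(rpkm + pseudocount)
    return {"log2_rpkm": log2_rpkm, "rpkm": rpkm, "scaled": scaled, "kept": kept}


# ---------------------------------------------------------------------------
# technical-reliability filter
# ---------------------------------------------------------------------------


def reliability_filter(region_means: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per 1-kb region: biological sample vs technical residual.

    ``region_means`` has one row per region and a two-level column MultiIndex
    ``(biological sample, technical replicate)`` of region-mean h-density.
    Regions where the between-sample variance significantly exceeds the
    within-sample (technical) variance at BH ``q < alpha`` are flagged
    ``reliable``.  Regions missing values in any replicate are dropped and
    counted in ``attrs['n_excluded']``.
    """
    if region_means.columns.nlevels != 2:
        raise ValueError("columns must be a (bio, tech) MultiIndex")
    bios = region_means.columns.get_level_values(0)
    groups = bios.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 biological samples")
    if min((bios == g).sum() for g in groups) < 2:
        raise ValueError("need >= 2 technical replicates per biological sample")
    complete = region_means.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    X = region_means[complete]
    grand = X.mean(axis=1)
    ss_between = pd.Series(0.0, index=X.index)
    ss_within = pd.Series(0.0, index=X.index)
    df_between = len(groups) - 1
    df_within = 0
    for g in groups:
        sub = X.loc[:, bios == g]
        m = sub.mean(axis=1)
        ss_between += len(sub.columns) * (m - grand) ** 2
        ss_within += ((sub.sub(m, axis=0)) ** 2).sum(axis=1)
        df_within += len(sub.columns) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / (ss_within / df_within)
    F = F.replace([np.inf], np.finfo(float).max)
    p = stats.f.sf(F, df_between, df_within)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"F": F, "p": p, "q": q, "reliable": q < alpha}, index=X.index)
    out.attrs["n_excluded"] = n_excluded
    return out


# ---------------------------------------------------------------------------
# region-level linear model + Tukey HSD (DHRs)
# ---------------------------------------------------------------------------


def _dummies(values: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(values))
    cols = [np.asarray(values == lev, dtype=float) for lev in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(values), 0))), levels


def dhr_test(data: pd.DataFrame, alpha: float = 0.05,
             value_col: str = "value") -> dict:
    """Per-region fixed-effects linear model of h-density with Tukey post hoc.

    ``data`` is long format with columns ``region``, ``cg_id``, ``cell``,
    ``condition`` and the response (technical-replicate-averaged h-density).
    Per region, a linear model with categorical cell type, condition and
    cytosine identity (blocking factor) is fitted; each non-blocking term gets
    a type-II F test, BH-adjusted across regions.  Tukey's HSD over the factor
    levels is run on regions significant for that term, giving the differing
    level pairs and the direction of change.  Rank-deficient regions (missing
    design cells) are skipped and logged.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factor_cols = ["cell", "condition"]
    records = []
    skipped = 0
    for region, sub in data.groupby("region", sort=False):
        y = sub[value_col].values.astype(float)
        # full design: intercept + cell + condition + cg blocking
        blocks = []
        for col in factor_cols:
            d, _ = _dummies(sub[col].values)
            blocks.append(d)
        n_cg = sub["cg_id"].nunique()
        if n_cg >= 2:
            d_cg, _ = _dummies(sub["cg_id"].values)
            blocks.append(d_cg)
        X_full = np.column_stack([np.ones(len(y))] + blocks)
        rank_full = np.linalg.matrix_rank(X_full)
        if rank_full < X_full.shape[1]:
            skipped += 1
            logger.info("region %r skipped: rank-deficient design", region)
            continue
        rss_full, df_resid = _ols_rss(X_full, y)
        if df_resid <= 0:
            skipped += 1
            continue
        for ti, term in enumerate(factor_cols):
            reduced_blocks = [b for k, b in enumerate(blocks) if k != ti]
            X_red = np.column_stack([np.ones(len(y))] + reduced_blocks)
            rss_red, _ = _ols_rss(X_red, y)
            df_term = blocks[ti].shape[1]
            if df_term == 0:
                continue
            F = ((rss_red - rss_full) / df_term) / (rss_full / df_resid)
            p = stats.f.sf(F, df_term, df_resid)
            records.append((region, term, float(F), float(p)))
    table = pd.DataFrame(records, columns=["region", "term", "F", "p"])
    table["q"] = np.nan
    for term in factor_cols:
        sel = table["term"] == term
        if sel.any():
            table.loc[sel, "q"] = multipletests(table.loc[sel, "p"], method="fdr_bh")[1]
    table["significant"] = table["q"] < alpha

    tukey_rows = []
    for row in table[table["significant"]].itertuples():
        sub = data[data["region"] == row.region]
        if sub[row.term].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub[value_col].values, sub[row.term].values, alpha=alpha)
        levels = list(res.groupsunique)
        from itertools import combinations

        for (i, j), md, pv, rej in zip(
            combinations(range(len(levels)), 2), res.meandiffs, res.pvalues, res.reject
        ):
            tukey_rows.append(
                (row.region, row.term, levels[i], levels[j], float(md),
                 float(pv), bool(rej), "Up" if md > 0 else "Down")
            )
    tukey = pd.DataFrame(
        tukey_rows,
        columns=["region", "term", "group1", "group2", "meandiff", "p_adj",
                 "reject", "direction"],
    )
    return {"anova": table, "tukey": tukey, "n_skipped": skipped}


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), len(y) - rank


# ---------------------------------------------------------------------------
# paired t-test per gene (DHGs)
# ---------------------------------------------------------------------------


def dhg_paired_ttest(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-test over the CpG sites of each gene, BH within gene-type stratum.

    ``pairs`` columns: ``gene``, ``stratum``, ``x``, ``y`` — one row per CpG
    with the technical-replicate-averaged h-density under the two paired
    states (conditions or cell types).  Zero-variance conventions: identical
    vectors give ``p = 1``; a constant non-zero difference gives ``p = 0``.
    Genes with fewer than two pairs are skipped.
    """
    rows = []
    for (gene, stratum), sub in pairs.groupby(["gene", "stratum"], sort=False):
        d = sub["x"].values.astype(float) - sub["y"].values.astype(float)
        d = d[np.isfinite(d)]
        if len(d) < 2:
            continue
        if np.allclose(d.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
            t = 0.0 if p == 1.0 else np.inf * np.sign(d.mean())
        else:
            t, p = stats.ttest_rel(sub["x"].values, sub["y"].values)
        rows.append((gene, stratum, len(d), float(np.mean(d)), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "stratum", "n_pairs", "mean_diff", "t", "p"])
    out["q"] = np.nan
    for stratum in out["stratum"].unique():
        sel = out["stratum"] == stratum
        out.loc[sel, "q"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    out["direction"] = np.where(out["mean_diff"] > 0, "Up", "Down")
    return out


# ---------------------------------------------------------------------------
# exact NB test at fixed dispersion (DEGs)
# ---------------------------------------------------------------------------


def _exact_nb_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Exact conditional two-group NB test at known dispersion.

    Group sums are NB with sizes ``n_g / dispersion``; conditionally on the
    total, the distribution over splits does not depend on the mean, giving a
    negative-hypergeometric-like law.  The two-sided p sums the probabilities
    of all splits no more likely than the observed one (double-tail).  As
    ``dispersion -> 0`` this converges to the exact binomial split of a
    Poisson total.
    """
    t = s_a + s_b
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if dispersion <= 0:
        logp = (
            gammaln(t + 1) - gammaln(s + 1) - gammaln(t - s + 1)
            + s * np.log(n_a / (n_a + n_b)) + (t - s) * np.log(n_b / (n_a + n_b))
        )
    else:
        r_a, r_b = n_a / dispersion, n_b / dispersion
        logp = (
            gammaln(s + r_a) - gammaln(s + 1) - gammaln(r_a)
            + gammaln(t - s + r_b) - gammaln(t - s + 1) - gammaln(r_b)
        )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(prob[prob <= prob[s_a] * (1 + 1e-10)].sum())


def deg_exact_test(counts: pd.DataFrame, groups: pd.Series, dispersion: float = 1e-4,
                   lfc_min: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
    """Exact NB test between two groups at a fixed, known dispersion.

    Library sizes are equalized by scaling every sample to the geometric mean
    library size (counts re-rounded to integers) before summing within groups.
    A gene is significant when BH ``q < alpha`` and ``|log2 FC| > lfc_min``.
    Genes with zero total count are skipped.
    """
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a_cols = groups.index[groups == labels[0]]
    b_cols = groups.index[groups == labels[1]]
    lib = counts.sum(axis=0).astype(float)
    ref = np.exp(np.mean(np.log(lib)))
    scaled = counts * (ref / lib)
    s_a = scaled[a_cols].sum(axis=1).round().astype(int)
    s_b = scaled[b_cols].sum(axis=1).round().astype(int)
    n_a, n_b = len(a_cols), len(b_cols)
    rows = []
    for gene in counts.index:
        sa, sb = int(s_a.loc[gene]), int(s_b.loc[gene])
        if sa + sb == 0:
            continue
        p = _exact_nb_pvalue(sa, sb, n_a, n_b, dispersion)
        lfc = np.log2(((sa + 0.5) / n_a) / ((sb + 0.5) / n_b))
        rows.append((gene, sa, sb, float(lfc), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "sum_a", "sum_b", "log2fc", "p"]).set_index("gene")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else np.nan
    out["significant"] = (out["q"] < alpha) & (out["log2fc"].abs() > lfc_min)
    out["direction"] = np.where(out["log2fc"] > 0, "Up", "Down")
    return out


# ---------------------------------------------------------------------------
# influence model
# ---------------------------------------------------------------------------


@dataclass
class InfluenceModel:
    """Fitted Gaussian linear model of expression on binary epigenome predictors."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_obs: int
    dropped: list


def fit_influence_glm(log2_expr: pd.Series, flags: pd.DataFrame) -> InfluenceModel:
    """OLS of log2 expression on binary epigenomic predictors plus interaction.

    Predictors: ``hmch`` (baseline: genes without 5hmCH), ``pmd_inside`` and
    ``pmd_edge`` (baseline: genes outside PMDs), ``enhancer`` (baseline: no
    enhancer overlap) and the interaction ``hmch_x_pmd`` (5hmCH genes inside
    or on the edge of a PMD, baseline 5hmCH-free genes outside PMDs).
    Collinear columns are dropped with a warning.
    """
    import statsmodels.api as sm

    genes = log2_expr.index.intersection(flags.index)
    y = log2_expr.loc[genes].values.astype(float)
    X = pd.DataFrame(index=genes)
    for col in ("hmch", "pmd_inside", "pmd_edge", "enhancer"):
        X[col] = flags.loc[genes, col].astype(float)
    X["hmch_x_pmd"] = (
        flags.loc[genes, "hmch"] & (flags.loc[genes, "pmd_inside"] | flags.loc[genes, "pmd_edge"])
    ).astype(float)
    dropped = []
    keep = []
    for col in X.columns:
        trial = X[keep + [col]].values
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(genes)), trial])) == len(keep) + 2:
            keep.append(col)
        else:
            dropped.append(col)
            logger.warning("dropping collinear predictor %r", col)
    design = sm.add_constant(X[keep])
    fit = sm.OLS(y, design).fit()
    return InfluenceModel(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        n_obs=len(genes), dropped=dropped,
    )


# ---------------------------------------------------------------------------
# modification-expression correlation
# ---------------------------------------------------------------------------


def correlate_modification_expression(gene_classes: pd.Series, features: pd.DataFrame,
                                      expression: pd.Series) -> pd.DataFrame:
    """Spearman correlation of modification fractions with expression per gene class.

    One row per (PMD localization class) x (feature column); constant feature
    vectors yield an undefined correlation and are flagged.
    """
    rows = []
    genes = gene_classes.index.intersection(features.index).intersection(expression.index)
    for cls in gene_classes.loc[genes].unique():
        members = genes[gene_classes.loc[genes] == cls]
        for feat in features.columns:
            x = features.loc[members, feat].values.astype(float)
            y = expression.loc[members].values.astype(float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                rows.append((cls, feat, np.nan, np.nan, len(x), False))
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append((cls, feat, float(rho), float(p), len(x), True))
    return pd.DataFrame(rows, columns=["group", "feature", "rho", "p", "n", "defined"])
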