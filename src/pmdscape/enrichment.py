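"""Fisher and permutation enrichment machinery and replication-timing grouping.

Every Fisher test stores its 2x2 contingency table; the odds ratio is
``(a*d)/(b*c)`` with a Haldane-Anscombe 0.5 correction applied (and flagged)
only when a cell is zero, while the p-value always comes from the exact
(uncorrected) hypergeometric table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, overlap, tile_genome


@dataclass
class EnrichmentResult:
    label: str
    a: int  # in set & in element
    b: int  # in set & not in element
    c: int  # not in set & in element
    d: int  # neither
    odds_ratio: float
    log2_or: float
    p: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to the OR


def fisher_table(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentResult:
    """Exact Fisher test of a 2x2 table with OR reporting conventions."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    return EnrichmentResult(
        label=label, a=a, b=b, c=c, d=d,
        odds_ratio=float(or_), log2_or=float(np.log2(or_)), p=float(p),
        corrected=corrected,
    )


def _results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# h-density percentile enrichment
# ---------------------------------------------------------------------------


def topq_element_enrichment(regions: pd.DataFrame, elements: dict[str, pd.DataFrame],
                            q_percentile: float = 95.0,
                            value_col: str = "value") -> pd.DataFrame:
    """Fisher enrichment of high-signal regions in genomic elements.

    ``regions`` are signal-aggregated tiles (e.g. 50-bp h-density means); per
    element the 2x2 table over regions crosses {overlaps element} with
    {signal above the q-th percentile}.  The result depends only on the rank
    of the signal, so it is invariant to monotone transforms.
    """
    vals = regions[value_col].values
    thresh = np.percentile(vals, q_percentile)
    above = vals > thresh
    results = []
    for label, element in elements.items():
        if len(element) == 0:
            continue
        hits = np.zeros(len(regions), dtype=bool)
        pairs = overlap(regions[["chrom", "start", "end"]], element[["chrom", "start", "end"]])
        hits[pairs["index_a"].unique()] = True
        a = int((above & hits).sum())
        b = int((above & ~hits).sum())
        c = int((~above & hits).sum())
        d = int((~above & ~hits).sum())
        results.append(fisher_table(a, b, c, d, label=label))
    out = _results_frame(results)
    if len(out):
        out["q_bh"] = _bh(out["p"].values)
    return out


def region_set_enrichment(in_set: np.ndarray, in_element: np.ndarray | dict,
                          label: str = "") -> pd.DataFrame:
    """Fisher 2x2 over an explicit universe of units (regions or genes).

    ``in_set`` is a boolean vector over the universe; ``in_element`` either a
    boolean vector or a dict of named boolean vectors.  ``in_set`` must be a
    genuine subset of the universe (a boolean mask guarantees it).
    """
    in_set = np.asarray(in_set, dtype=bool)
    if isinstance(in_element, dict):
        items = in_element.items()
    else:
        items = [(label, in_element)]
    results = []
    for name, vec in items:
        vec = np.asarray(vec, dtype=bool)
        if len(vec) != len(in_set):
            raise ValueError("set and universe sizes differ")
        a = int((in_set & vec).sum())
        b = int((in_set & ~vec).sum())
        c = int((~in_set & vec).sum())
        d = int((~in_set & ~vec).sum())
        results.append(fisher_table(a, b, c, d, label=name))
    out = _results_frame(results)
    out["q_bh"] = _bh(out["p"].values)
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1] if len(p) else p


# ---------------------------------------------------------------------------
# 5hmCH gene enrichment
# ---------------------------------------------------------------------------


def hmch_gene_enrichment(ch_sites: pd.DataFrame, hmch_mask: np.ndarray,
                         genes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Fisher test of 5hmCH membership against gene overlap.

    The universe is all candidate CH cytosines.  A gene is 5hmCH-enriched when
    its odds ratio exceeds 1 at unadjusted ``p < alpha``; a
    BH q-value is reported alongside for transparency.  Genes containing no CH
    cytosines are skipped.
    """
    hmch_mask = np.asarray(hmch_mask, dtype=bool)
    chrom = ch_sites["chrom"].values
    pos = ch_sites["pos"].values
    results = []
    for g in genes.itertuples():
        in_gene = (chrom == g.chrom) & (pos >= g.start) & (pos < g.end)
        if not in_gene.any():
            continue
        a = int((hmch_mask & in_gene).sum())
        b = int((hmch_mask & ~in_gene).sum())
        c = int((~hmch_mask & in_gene).sum())
        d = int((~hmch_mask & ~in_gene).sum())
        results.append(fisher_table(a, b, c, d, label=g.gene_id))
    out = _results_frame(results)
    if len(out):
        out["q_bh"] = _bh(out["p"].values)
        out["enriched"] = (out["odds_ratio"] > 1) & (out["p"] < alpha)
    return out


def hmch_element_enrichment(ch_sites: pd.DataFrame, hmch_mask: np.ndarray,
                            elements: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-element enrichment run separately per CH context and then averaged.

    For each element the Fisher test is computed within each dinucleotide
    context (CA, CT, CC) and the estimates are averaged (arithmetic mean of
    the per-context odds ratios) into a single enrichment value.
    """
    rows = []
    for label, element in elements.items():
        hit = np.zeros(len(ch_sites), dtype=bool)
        for e in element.itertuples():
            hit |= ((ch_sites["chrom"].values == e.chrom)
                    & (ch_sites["pos"].values >= e.start)
                    & (ch_sites["pos"].values < e.end))
        ors, ps = [], []
        for ctx in ("CA", "CT", "CC"):
            sel = ch_sites["context"].values == ctx
            if not sel.any():
                continue
            res = fisher_table(
                int((hmch_mask & hit & sel).sum()), int((hmch_mask & ~hit & sel).sum()),
                int((~hmch_mask & hit & sel).sum()), int((~hmch_mask & ~hit & sel).sum()),
                label=f"{label}:{ctx}",
            )
            ors.append(res.odds_ratio)
            ps.append(res.p)
        if ors:
            rows.append((label, float(np.mean(ors)), float(np.mean(ps)), len(ors)))
    return pd.DataFrame(rows, columns=["label", "mean_odds_ratio", "mean_p", "n_contexts"])


# ---------------------------------------------------------------------------
# replication-timing groups
# ---------------------------------------------------------------------------


def replication_groups(signal: pd.DataFrame, layout: GenomeLayout,
                       bin_width: int = 1_000_000, n_groups: int = 5) -> pd.DataFrame:
    """Quantile-bin a replication-timing signal into ordered groups.

    The signal (bedGraph-like) is averaged in ``bin_width`` tiles; covered
    bins are split into ``n_groups`` rank quantiles with group 1 the highest
    signal (earliest replication).  Ties break by genomic bin order, so the
    grouping is deterministic; group sizes differ by at most one.  Bins
    without signal stay unassigned (group 0).
    """
    tiles = tile_genome(layout, bin_width)
    sums = np.zeros(len(tiles))
    weights = np.zeros(len(tiles))
    pairs = overlap(tiles[["chrom", "start", "end"]], signal[["chrom", "start", "end"]])
    if len(pairs):
        w = pairs["overlap"].values.astype(float)
        np.add.at(sums, pairs["index_a"].values,
                  w * signal["value"].values[pairs["index_b"].values])
        np.add.at(weights, pairs["index_a"].values, w)
    mean = np.full(len(tiles), np.nan)
    nz = weights > 0
    mean[nz] = sums[nz] / weights[nz]
    group = np.zeros(len(tiles), dtype=int)
    covered = np.where(nz)[0]
    if len(covered):
        # sort by (-signal, genomic order): stable, deterministic tie-break
        order = covered[np.lexsort((covered, -mean[covered]))]
        # equal-size quantile split of the rank-ordered bins
        splits = np.array_split(order, n_groups)
        for gi, idx in enumerate(splits, start=1):
            group[idx] = gi
    out = tiles.copy()
    out["signal"] = mean
    out["group"] = group
    return out


# ---------------------------------------------------------------------------
# permutation overlap test
# ---------------------------------------------------------------------------


def permutation_overlap(set_a: set, set_b: set, universe: list, n_perm: int = 10_000,
                        seed: int = 0) -> dict:
    """Permutation p-value for the overlap of two gene sets within a universe.

    The null redraws ``|A|`` genes uniformly from the universe ``n_perm``
    times; ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    universe = list(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("sets must be subsets of the universe")
    if len(set_a) > len(universe):
        raise ValueError("|A| exceeds universe size")
    rng = np.random.default_rng(seed)
    b_mask = np.array([g in set_b for g in universe])
    observed = len(set_a & set_b)
    k = len(set_a)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        draw = rng.choice(len(universe), size=k, replace=False)
        null[i] = int(b_mask[draw].sum())
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {
        "observed": observed, "p": p, "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else float("nan"),
        "n_perm": n_perm,
    }
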