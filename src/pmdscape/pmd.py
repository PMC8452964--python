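"""Partially methylated domain (PMD) calling and PMD-centric summaries.

A PMD is a merged run of 10-kb windows each holding at least 30% identified
uCGs among at least five CpGs; qualifying windows closer than 10 kb are
concatenated and the resulting region is kept only if strictly larger than
10 kb and free of assembly gaps.  The strict size filter means a lone
qualifying window never becomes a PMD on its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeLayout, merge_intervals, overlap, tile_genome


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------


def compute_window_fractions(ucg_called: np.ndarray, cg_units: pd.DataFrame,
                             layout: GenomeLayout, width: int = 10_000) -> pd.DataFrame:
    """Per-tile CpG counts, identified-uCG counts and uCG percentage.

    ``ucg_called`` is a boolean vector over ``cg_units`` rows: a CpG counts as
    an identified uCG when it has at least one supporting call, irrespective
    of coverage.  Tiles overlapping an assembly gap are flagged.  Tiles with
    zero CpGs have an undefined fraction and never qualify.
    """
    tiles = tile_genome(layout, width)
    cg_count = np.zeros(len(tiles), dtype=np.int64)
    ucg_count = np.zeros(len(tiles), dtype=np.int64)
    tile_index = {}
    for i, row in enumerate(tiles.itertuples()):
        tile_index.setdefault(row.chrom, []).append((row.start, i))
    for chrom, sub_idx in tile_index.items():
        starts = np.array([s for s, _ in sub_idx])
        rows = np.array([i for _, i in sub_idx])
        sel = cg_units["chrom"].values == chrom
        if not sel.any():
            continue
        pos = cg_units["pos"].values[sel]
        called = ucg_called[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = j >= 0
        np.add.at(cg_count, rows[j[ok]], 1)
        np.add.at(ucg_count, rows[j[ok]], called[ok].astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cg_count > 0, 100.0 * ucg_count / np.maximum(cg_count, 1), np.nan)
    gaps = layout.gaps
    gap_flag = np.zeros(len(tiles), dtype=bool)
    if gaps is not None and len(gaps):
        pairs = overlap(tiles[["chrom", "start", "end"]], gaps)
        gap_flag[pairs["index_a"].unique()] = True
    out = tiles.copy()
    out["cg_count"] = cg_count
    out["ucg_count"] = ucg_count
    out["ucg_pct"] = frac
    out["overlaps_gap"] = gap_flag
    return out


def call_pmds(windows: pd.DataFrame, layout: GenomeLayout, min_ucg_pct: float = 30.0,
              min_cg: int = 5, merge_gap: int = 10_000, min_size: int = 10_000) -> pd.DataFrame:
    """Merge qualifying windows into PMDs and apply size and gap filters.

    A window qualifies when ``ucg_pct >= min_ucg_pct`` and ``cg_count >=
    min_cg``.  Qualifying windows whose inter-window distance is below
    ``merge_gap`` (adjacent tiles have distance 0) are concatenated; regions
    strictly larger than ``min_size`` bp that do not overlap assembly gaps
    survive.  Each PMD reports its size, CpG count and uCG fraction.
    """
    qual = (
        (windows["cg_count"] >= min_cg)
        & windows["ucg_pct"].notna()
        & (windows["ucg_pct"] >= min_ucg_pct)
    )
    rows = []
    for chrom, sub in windows[qual].groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur = None
        for w in sub.itertuples():
            if cur is None:
                cur = [w.start, w.end, w.cg_count, w.ucg_count]
            elif w.start - cur[1] < merge_gap:
                cur[1] = w.end
                cur[2] += w.cg_count
                cur[3] += w.ucg_count
            else:
                rows.append((chrom, *cur))
                cur = [w.start, w.end, w.cg_count, w.ucg_count]
        if cur is not None:
            rows.append((chrom, *cur))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "cg_count", "ucg_count"])
    if len(regions) == 0:
        return _empty_pmds()
    regions = regions[(regions["end"] - regions["start"]) > min_size].reset_index(drop=True)
    gaps = layout.gaps
    if gaps is not None and len(gaps) and len(regions):
        pairs = overlap(regions[["chrom", "start", "end"]], gaps)
        bad = set(pairs["index_a"])
        regions = regions[~regions.index.isin(bad)].reset_index(drop=True)
    if len(regions) == 0:
        return _empty_pmds()
    regions["size"] = regions["end"] - regions["start"]
    with np.errstate(invalid="ignore", divide="ignore"):
        regions["ucg_frac"] = regions["ucg_count"] / np.maximum(regions["cg_count"], 1)
    return regions[["chrom", "start", "end", "size", "cg_count", "ucg_count", "ucg_frac"]]


def _empty_pmds() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "size", "cg_count", "ucg_count", "ucg_frac"]
    )


# ---------------------------------------------------------------------------
# shared / unique PMD sets
# ---------------------------------------------------------------------------


def pmd_overlap_tiles(pmd_sets: dict[str, pd.DataFrame], layout: GenomeLayout,
                      width: int = 10_000) -> tuple[pd.DataFrame, pd.Series]:
    """Label genome tiles with the subset of cell types whose PMDs cover them.

    Returns the tile membership matrix (one boolean column per set) and the
    Venn-style fractions of each non-empty membership pattern over the union
    of covered tiles.
    """
    if len(pmd_sets) < 2:
        raise ValueError("need at least two PMD sets")
    tiles = tile_genome(layout, width)
    member = pd.DataFrame(index=tiles.index)
    for name, pmds in pmd_sets.items():
        flag = np.zeros(len(tiles), dtype=bool)
        if len(pmds):
            pairs = overlap(tiles[["chrom", "start", "end"]], pmds[["chrom", "start", "end"]])
            flag[pairs["index_a"].unique()] = True
        member[name] = flag
    covered = member.any(axis=1)
    patterns = member[covered].apply(
        lambda r: "&".join(sorted(c for c in member.columns if r[c])), axis=1
    )
    summary = patterns.value_counts(normalize=True) if covered.any() else pd.Series(dtype=float)
    out = pd.concat([tiles, member], axis=1)
    return out, summary


def unique_pmds_2cell(pmds_a: pd.DataFrame, pmds_b: pd.DataFrame,
                      window_frac_a: pd.DataFrame, window_frac_b: pd.DataFrame,
                      quantile: float = 0.75) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type-specific PMDs between a pair of subpopulations.

    A-candidates are A-PMDs with zero overlap with any B-PMD; a candidate is
    retained when its uCG fraction in A exceeds the ``quantile`` of B's uCG
    fractions over the same candidate regions (and symmetrically for B).  uCG
    "signal" for the comparison is the region-level uCG fraction recomputed
    from the window tables.
    """
    ua = _unique_against(pmds_a, pmds_b, window_frac_a, window_frac_b, quantile)
    ub = _unique_against(pmds_b, pmds_a, window_frac_b, window_frac_a, quantile)
    return ua, ub


def _region_ucg_fraction(regions: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """uCG fraction of arbitrary regions from a 10-kb window table."""
    frac = np.full(len(regions), np.nan)
    pairs = overlap(regions[["chrom", "start", "end"]],
                    windows[["chrom", "start", "end"]])
    if len(pairs) == 0:
        return frac
    cg = np.zeros(len(regions))
    ucg = np.zeros(len(regions))
    np.add.at(cg, pairs["index_a"].values, windows["cg_count"].values[pairs["index_b"].values])
    np.add.at(ucg, pairs["index_a"].values, windows["ucg_count"].values[pairs["index_b"].values])
    nz = cg > 0
    frac[nz] = ucg[nz] / cg[nz]
    return frac


def _unique_against(pmds_x, pmds_y, win_x, win_y, quantile):
    if len(pmds_x) == 0:
        return pmds_x.copy()
    if len(pmds_y):
        pairs = overlap(pmds_x[["chrom", "start", "end"]], pmds_y[["chrom", "start", "end"]])
        cand = pmds_x[~pmds_x.index.isin(set(pairs["index_a"]))].reset_index(drop=True)
    else:
        cand = pmds_x.reset_index(drop=True)
    if len(cand) == 0:
        return cand
    fx = _region_ucg_fraction(cand, win_x)
    fy = _region_ucg_fraction(cand, win_y)
    fy_valid = fy[np.isfinite(fy)]
    if len(fy_valid) == 0:
        return cand
    thresh = np.nanquantile(fy_valid, quantile)
    keep = np.isfinite(fx) & (fx > thresh)
    return cand[keep].reset_index(drop=True)


def unique_pmds_4cell(pmd_sets: dict[str, pd.DataFrame], layout: GenomeLayout,
                      width: int = 10_000) -> dict[str, pd.DataFrame]:
    """Tiles covered by exactly one cell type's PMDs, merged into runs per cell."""
    member, _ = pmd_overlap_tiles(pmd_sets, layout, width)
    names = list(pmd_sets)
    counts = member[names].sum(axis=1)
    out = {}
    for name in names:
        solo = member[(counts == 1) & member[name]]
        out[name] = merge_intervals(solo[["chrom", "start", "end"]])
    return out


# ---------------------------------------------------------------------------
# profiles, gene classes, boundaries
# ---------------------------------------------------------------------------


def pmd_ucg_profile(pmds: pd.DataFrame, windows: pd.DataFrame, flank: int = 50_000,
                    body_bins: int = 20, flank_tile: int = 10_000) -> pd.DataFrame:
    """Mean uCG fraction over 20 equal body windows plus tiled 50-kb flanks.

    Every PMD contributes ``body_bins`` equally sized windows regardless of
    its length; flank windows are fixed ``flank_tile``-bp tiles.  Values are
    averaged over PMDs.  Raises on an empty PMD set or PMDs too short to
    split.
    """
    if len(pmds) == 0:
        raise ValueError("empty PMD set")
    if ((pmds["end"] - pmds["start"]) < body_bins).any():
        raise ValueError(f"PMD shorter than {body_bins} bp cannot be split")
    n_flank = flank // flank_tile
    labels, sums, cnts = [], {}, {}
    for w in range(-n_flank, 0):
        labels.append(("upstream", w))
    for b in range(body_bins):
        labels.append(("body", b))
    for w in range(n_flank):
        labels.append(("downstream", w))
    acc = {lab: [] for lab in labels}
    for pmd in pmds.itertuples():
        size = pmd.end - pmd.start
        edges = pmd.start + np.round(np.linspace(0, size, body_bins + 1)).astype(int)
        for b in range(body_bins):
            reg = pd.DataFrame({"chrom": [pmd.chrom], "start": [edges[b]], "end": [edges[b + 1]]})
            acc[("body", b)].append(_region_ucg_fraction(reg, windows)[0])
        for w in range(1, n_flank + 1):
            s, e = pmd.start - w * flank_tile, pmd.start - (w - 1) * flank_tile
            if s >= 0:
                reg = pd.DataFrame({"chrom": [pmd.chrom], "start": [s], "end": [e]})
                acc[("upstream", -w)].append(_region_ucg_fraction(reg, windows)[0])
            s, e = pmd.end + (w - 1) * flank_tile, pmd.end + w * flank_tile
            reg = pd.DataFrame({"chrom": [pmd.chrom], "start": [s], "end": [e]})
            acc[("downstream", w - 1)].append(_region_ucg_fraction(reg, windows)[0])
    rows = []
    for lab in labels:
        vals = np.array(acc[lab], dtype=float)
        vals = vals[np.isfinite(vals)]
        rows.append((*lab, float(vals.mean()) if len(vals) else np.nan, len(vals)))
    return pd.DataFrame(rows, columns=["zone", "index", "ucg_frac", "n"])


def classify_gene_pmd_localization(genes: pd.DataFrame, pmds: pd.DataFrame,
                                   promoter: int = 2000) -> pd.Series:
    """Classify each gene by its position relative to the PMD landscape.

    Classes: ``Outside`` (no overlap), ``Inside`` (gene body fully within one
    PMD), and edge classes for boundary-crossing genes — ``Edge-Promoter``
    when a PMD covers the 2-kb promoter and at most 20% of the body from the
    5' end, ``Edge-End`` when a PMD covers 20-40% of the body measured from
    the 3' end, ``Edge-other`` otherwise.
    """
    out = {}
    for g in genes.itertuples():
        sub = pmds[(pmds["chrom"] == g.chrom)
                   & (pmds["start"] < g.end) & (pmds["end"] > g.start)]
        if len(sub) == 0:
            out[g.gene_id] = "Outside"
            continue
        if ((sub["start"] <= g.start) & (sub["end"] >= g.end)).any():
            out[g.gene_id] = "Inside"
            continue
        glen = g.end - g.start
        plus = g.strand == "+"
        label = "Edge-other"
        for p in sub.itertuples():
            ov_start, ov_end = max(p.start, g.start), min(p.end, g.end)
            body_cov = (ov_end - ov_start) / glen
            if plus:
                prom = (g.start - promoter, g.start)
                covers_prom = p.start <= prom[0] and p.end >= prom[1]
                from_5p = ov_start <= g.start
                from_3p = ov_end >= g.end
            else:
                prom = (g.end, g.end + promoter)
                covers_prom = p.start <= prom[0] and p.end >= prom[1]
                from_5p = ov_end >= g.end
                from_3p = ov_start <= g.start
            if covers_prom and from_5p and body_cov <= 0.20:
                label = "Edge-Promoter"
                break
            if from_3p and 0.20 <= body_cov <= 0.40:
                label = "Edge-End"
                break
        out[g.gene_id] = label
    return pd.Series(out, name="pmd_class")


def boundary_windows(pmds: pd.DataFrame, edge: int = 3000,
                     n_bands: int = 0, max_band_distance: int = 1_000_000) -> dict[str, pd.DataFrame]:
    """Inner/outer edge windows of every PMD boundary, plus optional distance bands.

    For a PMD ``[s, e)`` the inner windows are ``[s, s+edge)`` and
    ``[e-edge, e)`` (truncated at the PMD midpoint when the PMD is shorter
    than twice the edge), the outer windows ``[s-edge, s)`` and ``[e, e+edge)``.
    With ``n_bands > 0``, log-spaced outward distance bands up to
    ``max_band_distance`` are emitted for enrichment-decay curves.
    """
    inner, outer = [], []
    bands: dict[int, list] = {k: [] for k in range(n_bands)}
    if n_bands:
        edges_bp = np.unique(
            np.round(np.logspace(np.log10(edge), np.log10(max_band_distance), n_bands + 1)).astype(int)
        )
    for p in pmds.itertuples():
        mid = (p.start + p.end) // 2
        inner.append((p.chrom, p.start, min(p.start + edge, mid)))
        inner.append((p.chrom, max(p.end - edge, mid), p.end))
        outer.append((p.chrom, max(p.start - edge, 0), p.start))
        outer.append((p.chrom, p.end, p.end + edge))
        for k in range(n_bands):
            lo, hi = edges_bp[k], edges_bp[k + 1]
            bands[k].append((p.chrom, max(p.start - hi, 0), max(p.start - lo, 0)))
            bands[k].append((p.chrom, p.end + lo, p.end + hi))
    out = {
        "inner": pd.DataFrame(inner, columns=["chrom", "start", "end"]),
        "outer": pd.DataFrame(outer, columns=["chrom", "start", "end"]),
    }
    for k in range(n_bands):
        df = pd.DataFrame(bands[k], columns=["chrom", "start", "end"])
        out[f"band_{k}"] = df[df["start"] < df["end"]].reset_index(drop=True)
    return {k: v[v["start"] < v["end"]].reset_index(drop=True) for k, v in out.items()}
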