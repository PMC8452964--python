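"""Read-start evidence to called sites and kernel-normalized h-density tracks.

h-density at a CpG is the ratio of two kernel density estimates evaluated at
the site: a read-count-weighted density of CpG coverage (Epanechnikov kernel
on a uniform per-chromosome grid, then Gaussian-smoothed onto the CpG
positions) divided by the unweighted CpG-site density computed the same way.
Because the weights are normalized to sum to one within a sample, the track is
exactly invariant to global library-size changes, and the denominator removes
the bias of uneven CpG spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout

DEFAULT_MIN_READS = {"uCG": 1, "5hmCG": 1, "5hmCH": 2}


# ---------------------------------------------------------------------------
# read-to-site assignment and site calling
# ---------------------------------------------------------------------------


def assign_reads_to_sites(reads: pd.DataFrame, sites: pd.DataFrame,
                          max_offset: int = 3) -> tuple[np.ndarray, int]:
    """Assign read starts to the nearest same-strand cytosine 0..max_offset nt downstream.

    "Downstream" is in read orientation: a plus-strand read start at ``r``
    matches the nearest site at ``r .. r + max_offset`` on the plus strand; a
    minus-strand read start matches ``r - max_offset .. r`` on the minus
    strand.  Returns per-site coverage (sum of assigned counts, aligned to
    ``sites`` rows) and the number of unassigned reads.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    coverage = np.zeros(len(sites), dtype=np.int64)
    unassigned = 0
    site_groups = {
        key: sub.sort_values("pos")
        for key, sub in sites.groupby(["chrom", "strand"], sort=False)
    }
    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        grp = site_groups.get((chrom, strand))
        if grp is None:
            unassigned += int(sub["count"].sum())
            continue
        spos = grp["pos"].values
        srows = grp.index.values
        rpos = sub["pos"].values
        cnt = sub["count"].values
        if strand == "+":
            idx = np.searchsorted(spos, rpos, side="left")
            ok = idx < len(spos)
            dist = np.where(ok, spos[np.minimum(idx, len(spos) - 1)] - rpos, max_offset + 1)
        else:
            idx = np.searchsorted(spos, rpos, side="right") - 1
            ok = idx >= 0
            dist = np.where(ok, rpos - spos[np.maximum(idx, 0)], max_offset + 1)
        hit = ok & (dist >= 0) & (dist <= max_offset)
        np.add.at(coverage, srows[np.clip(idx, 0, len(spos) - 1)[hit]], cnt[hit])
        unassigned += int(cnt[~hit].sum())
    return coverage, unassigned


@dataclass
class SiteCalls:
    """Called modified sites for one sample and one mark."""

    mark: str
    min_reads: int
    called: np.ndarray            # bool per site-table row
    coverage: np.ndarray

    @property
    def n_called(self) -> int:
        return int(self.called.sum())

    def fraction_identified(self, context_mask: np.ndarray) -> float:
        """Fraction of sites in a context class (e.g. all CGs) that are called."""
        denom = int(context_mask.sum())
        return float((self.called & context_mask).sum() / denom) if denom else float("nan")


def call_sites(coverage: np.ndarray, mark: str, min_reads: int | None = None) -> SiteCalls:
    """Flag sites with coverage >= min_reads as carrying the mark.

    Default thresholds: uCG and 5hmCG need a single read (uCGs are counted
    irrespective of coverage when windows are scored); 5hmCH needs two.
    """
    if mark not in DEFAULT_MIN_READS:
        raise ValueError(f"unknown mark {mark!r}")
    if min_reads is None:
        min_reads = DEFAULT_MIN_READS[mark]
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return SiteCalls(mark=mark, min_reads=min_reads,
                     called=coverage >= min_reads, coverage=coverage)


def unit_coverage(coverage: np.ndarray, sites: pd.DataFrame, cg_units: pd.DataFrame) -> np.ndarray:
    """Sum strand-level CG coverage onto CpG units (keyed by plus-strand C position)."""
    out = np.zeros(len(cg_units), dtype=np.int64)
    cg_mask = (sites["context"] == "CG").values
    pos = sites["pos"].values.copy()
    minus = (sites["strand"] == "-").values
    pos[minus] -= 1  # collapse the minus-strand C onto its unit coordinate
    key = pd.MultiIndex.from_arrays([cg_units["chrom"], cg_units["pos"]])
    lut = pd.Series(np.arange(len(cg_units)), index=key)
    sel = np.where(cg_mask)[0]
    unit_idx = lut.reindex(
        pd.MultiIndex.from_arrays([sites["chrom"].values[sel], pos[sel]])
    ).values
    ok = ~pd.isna(unit_idx)
    np.add.at(out, unit_idx[ok].astype(int), coverage[sel][ok])
    return out


# ---------------------------------------------------------------------------
# h-density
# ---------------------------------------------------------------------------


def _epanechnikov_grid(pos: np.ndarray, weights: np.ndarray, origin: float,
                       spacing: float, n_grid: int, bw: float) -> np.ndarray:
    """Weighted Epanechnikov KDE evaluated on a uniform grid."""
    dens = np.zeros(n_grid)
    base = np.floor((pos - origin) / spacing).astype(np.int64)
    kmax = int(np.ceil(bw / spacing)) + 1
    for off in range(-kmax, kmax + 1):
        j = base + off
        ok = (j >= 0) & (j < n_grid)
        if not ok.any():
            continue
        u = (origin + j[ok] * spacing - pos[ok]) / bw
        k = 0.75 * (1.0 - u * u)
        k[np.abs(u) > 1.0] = 0.0
        np.add.at(dens, j[ok], weights[ok] * k / bw)
    return dens


def _gaussian_interpolate(grid: np.ndarray, origin: float, spacing: float,
                          query: np.ndarray, sigma: float) -> np.ndarray:
    """Nadaraya-Watson smoothing of grid values at query positions (truncated 5 sigma)."""
    n_grid = len(grid)
    base = np.floor((query - origin) / spacing).astype(np.int64)
    kmax = max(int(np.ceil(5.0 * sigma / spacing)), 1)
    num = np.zeros(len(query))
    den = np.zeros(len(query))
    for off in range(-kmax, kmax + 1):
        j = base + off
        ok = (j >= 0) & (j < n_grid)
        if not ok.any():
            continue
        d = (origin + j[ok] * spacing - query[ok]) / sigma
        w = np.exp(-0.5 * d * d)
        num[ok] += w * grid[j[ok]]
        den[ok] += w
    out = np.full(len(query), np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def compute_h_density(coverage: np.ndarray, sites: pd.DataFrame, layout: GenomeLayout,
                      grid_spacing: float = 120.0, bw_weighted: float = 180.0,
                      bw_cg: float = 80.0, grid_origin: float = 0.0,
                      smoothing_sigma: float | None = None) -> pd.DataFrame:
    """Two-stage kernel-normalized h-density at every CpG site.

    Stage 1 evaluates an Epanechnikov-kernel density on a uniform grid whose
    spacing (default 120 bp, roughly a 249-Mb chromosome over 2^21 points)
    fixes the resolution independently of chromosome length; read counts,
    normalized to sum to one over the sample, are the weights.  Stage 2
    Gaussian-smooths the grid values onto the CpG positions with one shared
    bandwidth, ``smoothing_sigma`` (default: the coverage bandwidth) — using
    the narrower CpG bandwidth here would leave grid-phase ripple in the
    denominator and hence in the ratio.  The same two stages without weights
    and with the ``bw_cg`` Epanechnikov bandwidth give the CpG density;
    h-density is their ratio.  Sites where the unweighted density vanishes are
    returned non-finite and flagged.

    ``coverage`` is aligned to the rows of ``sites``; only CG-context rows
    enter the track.
    """
    if bw_weighted <= 0 or bw_cg <= 0 or grid_spacing <= 0:
        raise ValueError("bandwidths and grid spacing must be positive")
    if smoothing_sigma is None:
        smoothing_sigma = bw_weighted
    cg = sites[sites["context"] == "CG"]
    cov_cg = coverage[cg.index.values].astype(float)
    total = cov_cg.sum()
    if total == 0:
        raise ValueError("no CG coverage: cannot normalize weights")
    weights = cov_cg / total
    n_cg_total = len(cg)

    rows = []
    for chrom, sub in cg.groupby("chrom", sort=False):
        L = layout.lengths[chrom]
        n_grid = max(int(np.ceil((L - grid_origin) / grid_spacing)), 2)
        pos = sub["pos"].values.astype(float)
        w = weights[np.isin(cg.index.values, sub.index.values)]
        # stage 1 + 2, weighted
        g_w = _epanechnikov_grid(pos, w, grid_origin, grid_spacing, n_grid, bw_weighted)
        val_w = _gaussian_interpolate(g_w, grid_origin, grid_spacing, pos, smoothing_sigma)
        # stage 1 + 2, unweighted CpG density (uniform weights over all CpGs)
        uw = np.full(len(pos), 1.0 / n_cg_total)
        g_u = _epanechnikov_grid(pos, uw, grid_origin, grid_spacing, n_grid, bw_cg)
        val_u = _gaussian_interpolate(g_u, grid_origin, grid_spacing, pos, smoothing_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = val_w / val_u
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sub["pos"].values,
                    "strand": sub["strand"].values,
                    "weighted": val_w,
                    "unweighted": val_u,
                    "value": h,
                    "finite": np.isfinite(h),
                }
            )
        )
    track = pd.concat(rows, ignore_index=True)
    track.attrs["bw_weighted"] = bw_weighted
    track.attrs["bw_cg"] = bw_cg
    track.attrs["grid_spacing"] = grid_spacing
    return track


def aggregate_regions(track: pd.DataFrame, width: int = 50,
                      log2_floor: float = -30.0) -> pd.DataFrame:
    """Average surviving h-density in non-overlapping tiles of ``width`` bp.

    Sites with non-finite values or log2 h-density below the floor are
    discarded first; tiles without surviving sites are omitted.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    vals = track["value"].values.astype(float)
    positive = np.isfinite(vals) & (vals > 0)
    logv = np.full(len(vals), -np.inf)
    logv[positive] = np.log2(vals[positive])
    keep = positive & (logv >= log2_floor)
    sub = track[keep].copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "value", "n_sites"])
    sub["start"] = (sub["pos"] // width) * width
    agg = (
        sub.groupby(["chrom", "start"], sort=True, observed=True)["value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    agg["end"] = agg["start"] + width
    agg = agg.rename(columns={"mean": "value", "size": "n_sites"})
    return agg[["chrom", "start", "end", "value", "n_sites"]]


# ---------------------------------------------------------------------------
# gene-centric profiles
# ---------------------------------------------------------------------------

GENE_ELEMENT_CLASSES = [
    "upstream", "utr5", "first_exon", "first_intron",
    "other_exons", "other_introns", "utr3", "downstream",
]


def _track_lookup(track: pd.DataFrame):
    """Per-chromosome (sorted positions, values) for fast range queries."""
    out = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out[chrom] = (sub["pos"].values, sub["value"].values)
    return out


def _range_values(lookup, chrom, start, end):
    if chrom not in lookup:
        return np.empty(0)
    pos, val = lookup[chrom]
    i, j = np.searchsorted(pos, [start, end])
    return val[i:j]


def profile_gene_elements(track: pd.DataFrame, annotations, flank: int = 2000) -> pd.Series:
    """Mean h-density per gene-associated element class.

    Classes (strand-aware order along the gene): upstream flank, 5'UTR, first
    exon, first intron, other exons, other introns, 3'UTR, downstream flank.
    UTRs take precedence over the exons containing them.  Genes without
    introns simply contribute nothing to the intron classes.
    """
    lookup = _track_lookup(track)
    buckets: dict[str, list] = {c: [] for c in GENE_ELEMENT_CLASSES}
    exons_by_gene = dict(tuple(annotations.exons.groupby("gene_id", sort=False)))
    utr5_by_gene = dict(tuple(annotations.utr5.groupby("gene_id", sort=False))) if len(annotations.utr5) else {}
    utr3_by_gene = dict(tuple(annotations.utr3.groupby("gene_id", sort=False))) if len(annotations.utr3) else {}

    for g in annotations.genes.itertuples():
        plus = g.strand == "+"
        up = (g.start - flank, g.start) if plus else (g.end, g.end + flank)
        down = (g.end, g.end + flank) if plus else (g.start - flank, g.start)
        buckets["upstream"].append(_range_values(lookup, g.chrom, max(up[0], 0), up[1]))
        buckets["downstream"].append(_range_values(lookup, g.chrom, max(down[0], 0), down[1]))

        utr_ranges = []
        for name, table in (("utr5", utr5_by_gene.get(g.gene_id)),
                            ("utr3", utr3_by_gene.get(g.gene_id))):
            if table is None:
                continue
            for r in table.itertuples():
                buckets[name].append(_range_values(lookup, g.chrom, r.start, r.end))
                utr_ranges.append((r.start, r.end))

        ex = exons_by_gene.get(g.gene_id)
        if ex is None:
            continue
        ex = ex.sort_values("start", ascending=plus)
        exon_list = list(zip(ex["start"], ex["end"]))
        for k, (es, ee) in enumerate(exon_list):
            vals = _range_values(lookup, g.chrom, es, ee)
            if len(vals):
                pos, _ = lookup[g.chrom]
                pvals = pos[np.searchsorted(pos, es):np.searchsorted(pos, ee)]
                in_utr = np.zeros(len(pvals), dtype=bool)
                for us, ue in utr_ranges:
                    in_utr |= (pvals >= us) & (pvals < ue)
                vals = vals[~in_utr]
            buckets["first_exon" if k == 0 else "other_exons"].append(vals)
        # introns between genomically consecutive exons, ordered along the strand
        ex_sorted = sorted(exon_list)
        introns = [
            (ex_sorted[k][1], ex_sorted[k + 1][0])
            for k in range(len(ex_sorted) - 1)
            if ex_sorted[k + 1][0] > ex_sorted[k][1]
        ]
        if not plus:
            introns = introns[::-1]
        for k, (is_, ie) in enumerate(introns):
            buckets["first_intron" if k == 0 else "other_introns"].append(
                _range_values(lookup, g.chrom, is_, ie)
            )

    means = {}
    for cls in GENE_ELEMENT_CLASSES:
        vals = np.concatenate(buckets[cls]) if buckets[cls] else np.empty(0)
        vals = vals[np.isfinite(vals)]
        means[cls] = float(vals.mean()) if len(vals) else float("nan")
    return pd.Series(means, name="mean_h_density")


def metagene_anova(tracks_by_group: dict[str, pd.DataFrame], annotations,
                   body_bins: int = 100, flank: int = 10_000,
                   flank_bins: int = 20) -> pd.DataFrame:
    """Per-relative-position one-way ANOVA of mean h-density across groups.

    Each gene body is rescaled to 0-100% (``body_bins`` bins); fixed-bp flanks
    upstream of the TSS and downstream of the TTS contribute ``flank_bins``
    bins each.  Genes are the observations of the per-bin ANOVA.  Bins where
    fewer than two groups have data are flagged with NaN statistics.
    """
    if len(tracks_by_group) < 2:
        raise ValueError("need at least two groups")
    genes = annotations.genes
    n_bins = body_bins + 2 * flank_bins
    per_group = {}
    for name, track in tracks_by_group.items():
        lookup = _track_lookup(track)
        mat = np.full((len(genes), n_bins), np.nan)
        for gi, g in enumerate(genes.itertuples()):
            if g.chrom not in lookup:
                continue
            pos, val = lookup[g.chrom]
            lo, hi = g.start - flank, g.end + flank
            i, j = np.searchsorted(pos, [lo, hi])
            p, v = pos[i:j].astype(float), val[i:j]
            ok = np.isfinite(v)
            p, v = p[ok], v[ok]
            if len(p) == 0:
                continue
            rel = np.empty(len(p))
            body = (p >= g.start) & (p < g.end)
            rel[body] = (p[body] - g.start) / (g.end - g.start)
            before = p < g.start
            rel[before] = -(g.start - p[before]) / flank  # in (-1, 0)
            after = p >= g.end
            rel[after] = 1.0 + (p[after] - g.end) / flank  # in [1, 2)
            if g.strand == "-":
                rel = 1.0 - rel
            binidx = np.empty(len(p), dtype=int)
            pre = rel < 0
            binidx[pre] = np.clip(((rel[pre] + 1.0) * flank_bins).astype(int), 0, flank_bins - 1)
            mid = (rel >= 0) & (rel < 1.0)
            binidx[mid] = flank_bins + np.clip((rel[mid] * body_bins).astype(int), 0, body_bins - 1)
            post = rel >= 1.0
            binidx[post] = flank_bins + body_bins + np.clip(
                ((rel[post] - 1.0) * flank_bins).astype(int), 0, flank_bins - 1
            )
            sums = np.zeros(n_bins)
            cnts = np.zeros(n_bins)
            np.add.at(sums, binidx, v)
            np.add.at(cnts, binidx, 1)
            with np.errstate(invalid="ignore"):
                mat[gi] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        per_group[name] = mat

    rel_pos = np.concatenate([
        np.linspace(-1, 0, flank_bins, endpoint=False) + 0.5 / flank_bins,
        np.linspace(0, 1, body_bins, endpoint=False) + 0.5 / body_bins,
        np.linspace(1, 2, flank_bins, endpoint=False) + 0.5 / flank_bins,
    ])
    records = []
    for b in range(n_bins):
        samples = []
        for name in tracks_by_group:
            col = per_group[name][:, b]
            col = col[np.isfinite(col)]
            if len(col) >= 2:
                samples.append(col)
        if len(samples) >= 2:
            F, p = stats.f_oneway(*samples)
            records.append((b, rel_pos[b], float(F), float(p), True))
        else:
            records.append((b, rel_pos[b], np.nan, np.nan, False))
    return pd.DataFrame(records, columns=["bin", "rel_pos", "F", "p", "defined"])
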