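"""Genome layout, interval containers, standard-format I/O and derived annotations.

All coordinates inside the package are 0-based half-open ``[start, end)``.
BED and bedGraph input is taken as-is; GTF (1-based, closed) is converted at
the parsing boundary.  Interval collections are plain :class:`pandas.DataFrame`
objects with at least the columns ``chrom``, ``start``, ``end`` and optionally
``strand``, ``name``, ``score`` — the lingua franca of every other module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeLayout:
    """Chromosome names and lengths plus assembly-gap intervals.

    Gaps are normalized (sorted, merged) at construction; PMD calling uses
    them to veto domains that cross unassembled sequence.
    """

    lengths: dict[str, int]
    gaps: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.gaps is None:
            self.gaps = pd.DataFrame(columns=INTERVAL_COLUMNS).astype(
                {"start": int, "end": int}
            )
        else:
            self.gaps = self.gaps[INTERVAL_COLUMNS].copy()
            for _, row in self.gaps.iterrows():
                L = self.lengths.get(row.chrom)
                if L is None:
                    raise ValueError(f"gap on unknown chromosome {row.chrom!r}")
                if not (0 <= row.start < row.end <= L):
                    raise ValueError(f"gap {row.start}-{row.end} outside chromosome {row.chrom}")
            self.gaps = merge_intervals(self.gaps)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def validate_intervals(self, intervals: pd.DataFrame) -> None:
        """Assert the package-wide coordinate convention for a table."""
        validate_intervals(intervals, self)


@dataclass
class AnnotationSet:
    """Gene models plus named interval sets (CGIs, enhancers, arbitrary BED sets).

    ``genes`` columns: gene_id, chrom, start, end, strand, gene_type.
    ``exons`` columns: gene_id, chrom, start, end (within the parent gene);
    ``utr5``/``utr3`` the same.  ``cgi`` and ``enhancers`` are interval tables
    (enhancers carry a ``name`` column giving the class, e.g. ``Enh``,
    ``ADRN_S-Enh``, ``MES_S-Enh``).  Anything else lives in ``extra``.
    """

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    exons: pd.DataFrame = field(default_factory=pd.DataFrame)
    utr5: pd.DataFrame = field(default_factory=pd.DataFrame)
    utr3: pd.DataFrame = field(default_factory=pd.DataFrame)
    cgi: pd.DataFrame = field(default_factory=pd.DataFrame)
    enhancers: pd.DataFrame = field(default_factory=pd.DataFrame)
    extra: dict[str, pd.DataFrame] = field(default_factory=dict)

    def tss(self) -> pd.Series:
        """Strand-aware transcription start coordinate per gene (indexed by gene_id)."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"] - 1),
            index=g["gene_id"],
            name="tss",
        )

    def tts(self) -> pd.Series:
        """Strand-aware transcription termination coordinate per gene."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["end"] - 1, g["start"]),
            index=g["gene_id"],
            name="tts",
        )


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout | None = None) -> None:
    """Global coordinate validator: 0 <= start < end (<= chromosome length)."""
    if len(df) == 0:
        return
    if (df["start"] < 0).any():
        raise ValueError("negative start coordinate")
    if (df["start"] >= df["end"]).any():
        raise ValueError("empty or inverted interval (start >= end)")
    if layout is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            L = layout.lengths.get(chrom)
            if L is None:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if (sub["end"] > L).any():
                raise ValueError(f"interval beyond end of chromosome {chrom}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` file into a :class:`GenomeLayout`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeLayout(lengths=dict(zip(df["chrom"], df["length"].astype(int))))


def read_bed(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read BED3/4/5/6 into an interval table (natively 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                rec = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if len(parts) > 3:
                rec["name"] = parts[3]
            if len(parts) > 4:
                rec["score"] = parts[4]
            if len(parts) > 5:
                rec["strand"] = parts[5]
            rows.append(rec)
    if not rows:
        logger.warning("empty BED file: %s", path)
        return pd.DataFrame(columns=INTERVAL_COLUMNS).astype({"start": int, "end": int})
    df = pd.DataFrame(rows)
    validate_intervals(df, layout)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write an interval table as BED (3-6 columns depending on what is present)."""
    cols = ["chrom", "start", "end"]
    for c in ("name", "score", "strand"):
        if c in df.columns:
            cols.append(c)
        else:
            break
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, value_name: str = "value") -> pd.DataFrame:
    """Read bedGraph (chrom, start, end, value); value column float."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", value_name],
    )
    if len(df) == 0:
        logger.warning("empty bedGraph file: %s", path)
    validate_intervals(df)
    return df


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(path, sep="\t", header=False, index=False)


def read_gtf(path, layout: GenomeLayout | None = None) -> AnnotationSet:
    """Parse a GTF-like file into gene models.

    Recognized feature types: ``gene``, ``exon``, ``five_prime_utr`` (or
    ``5UTR``), ``three_prime_utr`` (or ``3UTR``).  Requires ``gene_id`` in the
    attribute field; ``gene_type`` defaults to ``protein_coding``.  GTF is
    1-based closed and converted to 0-based half-open here.
    """
    genes, exons, utr5, utr3 = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GTF line does not have 9 fields")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrd = _parse_gtf_attrs(attrs)
            gid = attrd.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            rec = {"gene_id": gid, "chrom": chrom, "start": start0, "end": end0}
            if feature == "gene":
                rec["strand"] = strand
                rec["gene_type"] = attrd.get("gene_type", "protein_coding")
                genes.append(rec)
            elif feature == "exon":
                exons.append(rec)
            elif feature in ("five_prime_utr", "5UTR", "UTR5"):
                utr5.append(rec)
            elif feature in ("three_prime_utr", "3UTR", "UTR3"):
                utr3.append(rec)
    ann = AnnotationSet(
        genes=pd.DataFrame(genes),
        exons=pd.DataFrame(exons),
        utr5=pd.DataFrame(utr5),
        utr3=pd.DataFrame(utr3),
    )
    if len(ann.genes):
        validate_intervals(ann.genes, layout)
    return ann


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_gtf(ann: AnnotationSet, path) -> None:
    """Write gene/exon/UTR records back to GTF (converting to 1-based closed)."""
    with open(path, "w") as fh:
        for feature, table in (
            ("gene", ann.genes),
            ("exon", ann.exons),
            ("five_prime_utr", ann.utr5),
            ("three_prime_utr", ann.utr3),
        ):
            if len(table) == 0:
                continue
            strands = (
                table["strand"]
                if "strand" in table.columns
                else ann.genes.set_index("gene_id").loc[table["gene_id"], "strand"].values
            )
            for (_, row), strand in zip(table.iterrows(), np.asarray(strands)):
                gtype = row.get("gene_type", "protein_coding")
                attrs = f'gene_id "{row.gene_id}"; gene_type "{gtype}";'
                fh.write(
                    f"{row.chrom}\tpmdscape\t{feature}\t{row.start + 1}\t{row.end}"
                    f"\t.\t{strand}\t.\t{attrs}\n"
                )


def read_intervals(path, kind: str = "bed", **kwargs):
    """Dispatching reader: ``kind`` in {bed, bedgraph, gtf, chrom.sizes}."""
    readers = {
        "bed": read_bed,
        "bedgraph": read_bedgraph,
        "gtf": read_gtf,
        "chrom.sizes": read_chrom_sizes,
    }
    if kind not in readers:
        raise ValueError(f"unknown format tag {kind!r}")
    return readers[kind](path, **kwargs)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome; returns sorted table."""
    if len(df) == 0:
        return df.copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def overlap(a: pd.DataFrame, b: pd.DataFrame, strand_specific: bool = False) -> pd.DataFrame:
    """All pairs of intervals from ``a`` and ``b`` overlapping by >= 1 bp.

    Returns a table with columns ``index_a``, ``index_b`` (positional row
    indices into the inputs) and ``overlap`` (bp).  Half-open semantics:
    ``[0,10)`` and ``[10,20)`` do not overlap.  When ``strand_specific`` both
    tables must carry a ``strand`` column and only same-strand pairs pair up.
    """
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=["index_a", "index_b", "overlap"]).astype(int)
    keys = ["chrom", "strand"] if strand_specific else ["chrom"]
    ia_all, ib_all, ov_all = [], [], []
    a_idx = np.arange(len(a))
    b_idx = np.arange(len(b))
    a_groups = {k: g for k, g in zip(*_group_rows(a, keys, a_idx))}
    b_groups = {k: g for k, g in zip(*_group_rows(b, keys, b_idx))}
    for key, (a_rows,) in a_groups.items():
        if key not in b_groups:
            continue
        (b_rows,) = b_groups[key]
        a_start = a["start"].values[a_rows]
        a_end = a["end"].values[a_rows]
        order_b = np.argsort(b["start"].values[b_rows], kind="stable")
        b_rows = b_rows[order_b]
        b_start = b["start"].values[b_rows]
        b_end = b["end"].values[b_rows]
        # sweep: candidates have b_start < a_end and running-max b_end > a_start
        hi = np.searchsorted(b_start, a_end, side="left")
        cummax_end = np.maximum.accumulate(b_end)
        lo = np.searchsorted(cummax_end, a_start, side="right")
        for i in range(len(a_rows)):
            cand = np.arange(lo[i], hi[i])
            sel = cand[b_end[cand] > a_start[i]]
            if len(sel) == 0:
                continue
            ov = np.minimum(a_end[i], b_end[sel]) - np.maximum(a_start[i], b_start[sel])
            ia_all.append(np.full(len(sel), a_rows[i]))
            ib_all.append(b_rows[sel])
            ov_all.append(ov)
    if not ia_all:
        return pd.DataFrame(columns=["index_a", "index_b", "overlap"]).astype(int)
    return pd.DataFrame(
        {
            "index_a": np.concatenate(ia_all),
            "index_b": np.concatenate(ib_all),
            "overlap": np.concatenate(ov_all),
        }
    ).sort_values(["index_a", "index_b"], ignore_index=True)


def _group_rows(df: pd.DataFrame, keys: list[str], idx: np.ndarray):
    labels = list(zip(*(df[k].values for k in keys)))
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return list(groups.keys()), [(idx[np.array(v)],) for v in groups.values()]


def covered_fraction(query: pd.DataFrame, cover: pd.DataFrame) -> np.ndarray:
    """Fraction of each query interval covered by the (merged) cover set."""
    cover = merge_intervals(cover)
    pairs = overlap(query, cover)
    tot = np.zeros(len(query))
    if len(pairs):
        np.add.at(tot, pairs["index_a"].values, pairs["overlap"].values)
    return tot / (query["end"].values - query["start"].values)


def tile_genome(layout: GenomeLayout, width: int) -> pd.DataFrame:
    """Non-overlapping tiles ``[0,w), [w,2w), ...`` per chromosome.

    A trailing partial tile is kept but flagged ``partial=True`` so callers
    that need full-width windows can drop it.
    """
    if width <= 0:
        raise ValueError("tile width must be positive")
    rows = []
    for chrom, L in layout.lengths.items():
        starts = np.arange(0, L, width)
        ends = np.minimum(starts + width, L)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), (e - s) < width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


# ---------------------------------------------------------------------------
# derived annotations
# ---------------------------------------------------------------------------


def derive_flanks(ann: AnnotationSet, layout: GenomeLayout, flank: int = 2000) -> dict[str, pd.DataFrame]:
    """Derive CGI shores/shelves and gene promoter/downstream regions.

    Shores are the ``flank``-bp regions either side of a CGI (CGI itself
    excluded); shelves the next ``flank`` bp beyond the shores.  Where
    neighbouring CGIs collide, higher-priority features win: shore intervals
    have any CGI subtracted, shelf intervals have CGIs and shores subtracted.
    Promoters are the ``flank`` bp upstream of the TSS (strand-aware);
    downstream regions the ``flank`` bp past the TTS.  Everything is clipped
    to chromosome bounds.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out: dict[str, pd.DataFrame] = {}
    if len(ann.cgi):
        cgi = ann.cgi
        shore_raw = _flank_pairs(cgi, flank, 0)
        shelf_raw = _flank_pairs(cgi, flank, flank)
        shores = subtract_intervals(_clip(shore_raw, layout), cgi)
        shelves = subtract_intervals(
            _clip(shelf_raw, layout), pd.concat([cgi[INTERVAL_COLUMNS], shores], ignore_index=True)
        )
        out["cgi_shore"] = shores
        out["cgi_shelf"] = shelves
    if len(ann.genes):
        g = ann.genes
        plus = g["strand"].values == "+"
        tss = np.where(plus, g["start"].values, g["end"].values)
        tts = np.where(plus, g["end"].values, g["start"].values)
        prom_start = np.where(plus, tss - flank, tss)
        prom_end = np.where(plus, tss, tss + flank)
        down_start = np.where(plus, tts, tts - flank)
        down_end = np.where(plus, tts + flank, tts)
        prom = pd.DataFrame(
            {"chrom": g["chrom"], "start": prom_start, "end": prom_end,
             "name": g["gene_id"], "strand": g["strand"]}
        )
        down = pd.DataFrame(
            {"chrom": g["chrom"], "start": down_start, "end": down_end,
             "name": g["gene_id"], "strand": g["strand"]}
        )
        out["promoter"] = _clip(prom, layout)
        out["downstream"] = _clip(down, layout)
    return out


def _flank_pairs(df: pd.DataFrame, width: int, offset: int) -> pd.DataFrame:
    left = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start"] - offset - width, "end": df["start"] - offset}
    )
    right = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["end"] + offset, "end": df["end"] + offset + width}
    )
    return pd.concat([left, right], ignore_index=True)


def _clip(df: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    df = df.copy()
    lens = df["chrom"].map(layout.lengths)
    df["start"] = np.maximum(df["start"], 0)
    df["end"] = np.minimum(df["end"], lens)
    return df[df["start"] < df["end"]].reset_index(drop=True)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Subtract the merged cover of ``b`` from every interval in ``a``."""
    if len(a) == 0:
        return a.copy()
    if len(b) == 0:
        return a[INTERVAL_COLUMNS].reset_index(drop=True)
    b = merge_intervals(b)
    rows = []
    for chrom, sub in a.groupby("chrom", sort=False):
        bc = b[b["chrom"] == chrom]
        bs, be = bc["start"].values, bc["end"].values
        for s, e in zip(sub["start"], sub["end"]):
            cur = s
            for gs, ge in zip(bs, be):
                if ge <= cur or gs >= e:
                    continue
                if gs > cur:
                    rows.append((chrom, cur, min(gs, e)))
                cur = max(cur, ge)
                if cur >= e:
                    break
            if cur < e:
                rows.append((chrom, cur, e))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


# ---------------------------------------------------------------------------
# cytosine site tables
# ---------------------------------------------------------------------------

CONTEXTS = ("CG", "CA", "CT", "CC")


def validate_sites(sites: pd.DataFrame) -> None:
    """Check a cytosine site table: unique (chrom, strand, pos); known contexts."""
    if not set(sites["context"]).issubset(CONTEXTS):
        raise ValueError("unknown dinucleotide context")
    if sites.duplicated(["chrom", "strand", "pos"]).any():
        raise ValueError("duplicate cytosine positions on one strand")
    cg = sites[sites["context"] == "CG"]
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"]
    for chrom, sub in plus.groupby("chrom", sort=False):
        mpos = set(minus[minus["chrom"] == chrom]["pos"])
        missing = set(sub["pos"] + 1) - mpos
        if missing:
            raise ValueError(
                f"CpG palindrome symmetry violated on {chrom}: {len(missing)} sites"
            )
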