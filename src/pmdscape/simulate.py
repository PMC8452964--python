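"""Synthetic genomes, methylomes, TOP-seq-style reads and coupled expression.

The generator emulates the statistical structure of tagging-based single-base
sequencing of modified cytosines in a heterogeneous tumour cell population:

* a CpG landscape with a sparse background and dense CpG-island clusters;
* per-cell-type methylomes with planted partially methylated domains (PMDs) —
  large regions whose unmethylated-CpG (uCG) fraction is high inside and low
  outside;
* 5hmCG preferentially at enhancers and gene 3' ends, and a small set of
  non-CpG (5hmCH) sites enriched in introns and on the coding strand;
* read starts falling 0-3 nt upstream of each tagged cytosine, with Poisson
  coverage per tagged site and a low Poisson noise floor elsewhere;
* negative-binomial expression counts whose log-means carry planted effects of
  the epigenomic covariates (5hmCH status, PMD localization, enhancers).

Everything is deterministic under the configured seed, and every generated
object carries its ground truth so downstream estimators can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import AnnotationSet, GenomeLayout, merge_intervals

STATE_M, STATE_U, STATE_H = 0, 1, 2  # methylated / unmethylated / hydroxymethylated CpG


@dataclass
class SimulationConfig:
    """All knobs of the generator, with desk-scale defaults.

    Coverage defaults follow low-coverage tagging libraries: ``lam`` is the
    expected read count per tagged site and ``noise`` the Poisson rate at
    untagged sites (1% of ``lam``).
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 2_000_000})
    # CpG landscape
    cg_spacing: float = 100.0          # mean bp between background CpGs
    cgi_per_mb: float = 6.0            # CpG-island count per Mb
    cgi_length: int = 1000
    cgi_density_factor: float = 8.0    # CG density multiplier inside CGIs
    ch_per_cg: float = 1.5             # candidate CH cytosines per CpG
    # layout
    gap_per_chrom: int = 0
    gap_length: int = 50_000
    # genes / enhancers
    genes_per_mb: float = 8.0
    gene_min_len: int = 3_000
    gene_max_len: int = 20_000
    enhancers_per_mb: float = 4.0
    enhancer_len: int = 1_000
    # methylome
    n_cell_types: int = 2
    pmd_fraction: float = 0.30         # genome fraction covered by planted PMDs
    pmd_min_len: int = 50_000
    pmd_max_len: int = 500_000
    pmd_shared_fraction: float = 0.5   # planted PMDs common to all cell types
    pmd_min_separation: int = 30_000
    ucg_inside: float = 0.45
    ucg_outside: float = 0.12
    # hydroxymethylome
    hmcg_enhancer: float = 0.35        # P(5hmCG | CpG at enhancer or gene 3' end)
    hmcg_background: float = 0.03
    hmch_sites: int = 200
    hmch_intron_weight: float = 4.0
    hmch_coding_strand_odds: float = 1.2
    # reads
    lam: float = 3.0                   # Poisson coverage per tagged site
    noise: float = 0.03                # Poisson rate per untagged site
    max_offset: int = 3                # read start 0..3 nt upstream of the site
    n_bio: int = 1
    n_tech: int = 2
    # expression
    n_samples: int = 6
    expr_baseline_log: float = 3.0
    expr_baseline_sd: float = 0.7
    expr_dispersion: float = 0.05
    beta_hmch: float = 0.0
    beta_pmd_inside: float = 0.0
    beta_pmd_edge: float = 0.0
    beta_enhancer: float = 0.0
    beta_hmch_pmd: float = 0.0         # interaction: 5hmCH gene inside a PMD

    def __post_init__(self) -> None:
        for name in ("pmd_fraction", "ucg_inside", "ucg_outside",
                     "hmcg_enhancer", "hmcg_background", "pmd_shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lam < 0 or self.noise < 0:
            raise ValueError("rates must be non-negative")
        for name in ("beta_hmch", "beta_pmd_inside", "beta_pmd_edge",
                     "beta_enhancer", "beta_hmch_pmd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimulatedGenome:
    """Genome layout plus cytosine landscape and annotations."""

    layout: GenomeLayout
    cg_units: pd.DataFrame        # one row per CpG: chrom, pos (plus-strand C)
    ch_sites: pd.DataFrame        # chrom, pos, strand, context in {CA, CT, CC}
    annotations: AnnotationSet
    rt_signal: pd.DataFrame       # bedGraph-like smooth replication-timing signal

    def site_table(self) -> pd.DataFrame:
        """Full cytosine site table (both CpG strands + CH sites)."""
        cg = self.cg_units
        plus = pd.DataFrame(
            {"chrom": cg["chrom"], "pos": cg["pos"], "strand": "+", "context": "CG"}
        )
        minus = pd.DataFrame(
            {"chrom": cg["chrom"], "pos": cg["pos"] + 1, "strand": "-", "context": "CG"}
        )
        return pd.concat([plus, minus, self.ch_sites], ignore_index=True)


@dataclass
class Methylome:
    """Per-cell-type cytosine states over a :class:`SimulatedGenome`."""

    cell_type: str
    cg_state: np.ndarray          # int8 per CpG unit: 0 = mCG, 1 = uCG, 2 = 5hmCG
    hmch_mask: np.ndarray         # bool per ch_sites row

    def tagged(self, mode: str) -> np.ndarray:
        if mode == "u":
            return self.cg_state == STATE_U
        if mode == "hm":
            return self.cg_state == STATE_H
        raise ValueError(f"unknown assay mode {mode!r}")


@dataclass
class TruthSet:
    """Immutable ground truth written alongside each simulation."""

    pmds: dict                    # cell type -> interval DataFrame
    methylomes: dict              # cell type -> Methylome
    expression_effects: dict = field(default_factory=dict)
    mixture_proportion: float | None = None


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Place CpGs (background + CGI clusters), genes, enhancers, RT signal and gaps."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    min_len_needed = max(config.gene_max_len + 4000, config.cgi_length * 2,
                         config.gap_length * config.gap_per_chrom * 2)
    for chrom, L in config.chrom_lengths.items():
        if L < min_len_needed:
            raise ValueError(f"chromosome {chrom} too short ({L} bp) for requested features")

    gap_rows, cgi_rows, cg_rows, ch_rows = [], [], [], []
    gene_rows, exon_rows, utr5_rows, utr3_rows, enh_rows, rt_rows = [], [], [], [], [], []
    gene_counter = 0

    for chrom, L in config.chrom_lengths.items():
        # assembly gaps
        gaps = []
        for _ in range(config.gap_per_chrom):
            s = int(rng.integers(0, L - config.gap_length))
            gaps.append((s, s + config.gap_length))
        gaps.sort()
        for s, e in gaps:
            gap_rows.append((chrom, s, e))

        # CpG islands
        n_cgi = rng.poisson(config.cgi_per_mb * L / 1e6)
        cgi_starts = np.sort(rng.integers(0, L - config.cgi_length, size=n_cgi))
        cgis = [(int(s), int(s) + config.cgi_length) for s in cgi_starts]
        for s, e in cgis:
            cgi_rows.append((chrom, s, e))

        # CpG positions: homogeneous background + extra density inside CGIs
        n_bg = rng.poisson(L / config.cg_spacing)
        pos = rng.integers(0, L - 1, size=n_bg)
        extra_rate = (config.cgi_density_factor - 1.0) / config.cg_spacing
        for s, e in cgis:
            n_extra = rng.poisson(extra_rate * (e - s))
            pos = np.concatenate([pos, rng.integers(s, e - 1, size=n_extra)])
        pos = np.unique(pos)
        pos = pos[np.concatenate([[True], np.diff(pos) >= 2])]  # CpG units cannot overlap
        in_gap = np.zeros(len(pos), dtype=bool)
        for s, e in gaps:
            in_gap |= (pos >= s) & (pos < e)
        pos = pos[~in_gap]
        for p in pos:
            cg_rows.append((chrom, int(p)))

        # candidate CH cytosines, avoiding CpG positions
        n_ch = rng.poisson(config.ch_per_cg * len(pos))
        ch_pos = np.unique(rng.integers(0, L, size=n_ch))
        ch_pos = ch_pos[~np.isin(ch_pos, pos) & ~np.isin(ch_pos, pos + 1)]
        strands = rng.choice(["+", "-"], size=len(ch_pos))
        ctx = rng.choice(["CA", "CT", "CC"], size=len(ch_pos))
        for p, st, cx in zip(ch_pos, strands, ctx):
            ch_rows.append((chrom, int(p), st, cx))

        # non-overlapping genes
        n_genes = rng.poisson(config.genes_per_mb * L / 1e6)
        occupied = list(gaps)
        for _ in range(n_genes):
            glen = int(rng.integers(config.gene_min_len, config.gene_max_len))
            for _attempt in range(40):
                s = int(rng.integers(2000, L - glen - 2000))
                if all(e0 <= s or s + glen <= s0 for s0, e0 in occupied):
                    break
            else:
                continue
            e = s + glen
            occupied.append((s, e))
            strand = rng.choice(["+", "-"])
            gid = f"G{gene_counter:05d}"
            gene_counter += 1
            gtype = rng.choice(
                ["protein_coding", "lincRNA", "pseudogene"], p=[0.8, 0.1, 0.1]
            )
            gene_rows.append((gid, chrom, s, e, strand, gtype))
            # exon chain: first/last exons anchored at the gene ends
            n_ex = int(rng.integers(2, 7))
            cuts = np.sort(rng.integers(200, glen - 200, size=2 * (n_ex - 1)))
            bounds = np.concatenate([[0], cuts, [glen]])
            for k in range(n_ex):
                es, ee = int(bounds[2 * k]), int(bounds[2 * k + 1])
                if ee - es < 20:
                    ee = es + 20
                exon_rows.append((gid, chrom, s + es, s + min(ee, glen)))
            first, last = (s, s + 200), (e - 300, e)
            if strand == "+":
                utr5_rows.append((gid, chrom, *first))
                utr3_rows.append((gid, chrom, *last))
            else:
                utr5_rows.append((gid, chrom, *last))
                utr3_rows.append((gid, chrom, *first))
        # enhancers anywhere (real enhancers are frequently intronic/intragenic)
        n_enh = rng.poisson(config.enhancers_per_mb * L / 1e6)
        classes = rng.choice(["Enh", "ADRN_S-Enh", "MES_S-Enh"], size=n_enh, p=[0.6, 0.2, 0.2])
        for cls in classes:
            s = int(rng.integers(0, L - config.enhancer_len))
            enh_rows.append((chrom, s, s + config.enhancer_len, cls))

        # smooth replication-timing field: a few low-frequency sinusoids
        bin_w = 10_000
        starts = np.arange(0, L, bin_w)
        x = starts / L
        signal = np.zeros(len(starts))
        for _ in range(4):
            freq = rng.uniform(0.5, 4.0)
            phase = rng.uniform(0, 2 * np.pi)
            signal += rng.normal(0, 1) * np.sin(2 * np.pi * freq * x + phase)
        for s, v in zip(starts, signal):
            rt_rows.append((chrom, int(s), int(min(s + bin_w, L)), float(v)))

    layout = GenomeLayout(
        lengths=dict(config.chrom_lengths),
        gaps=pd.DataFrame(gap_rows, columns=["chrom", "start", "end"]) if gap_rows else None,
    )
    ann = AnnotationSet(
        genes=pd.DataFrame(
            gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]
        ),
        exons=pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"]),
        utr5=pd.DataFrame(utr5_rows, columns=["gene_id", "chrom", "start", "end"]),
        utr3=pd.DataFrame(utr3_rows, columns=["gene_id", "chrom", "start", "end"]),
        cgi=pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]),
        enhancers=pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name"]),
    )
    return SimulatedGenome(
        layout=layout,
        cg_units=pd.DataFrame(cg_rows, columns=["chrom", "pos"]),
        ch_sites=pd.DataFrame(ch_rows, columns=["chrom", "pos", "strand", "context"]),
        annotations=ann,
        rt_signal=pd.DataFrame(rt_rows, columns=["chrom", "start", "end", "value"]),
    )


# ---------------------------------------------------------------------------
# methylomes with planted PMDs
# ---------------------------------------------------------------------------


def plant_pmds(genome: SimulatedGenome, config: SimulationConfig,
               rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Plant disjoint PMD intervals and assign them shared/cell-type-specific.

    Returns one interval table per cell type; shared PMDs appear in every
    table.  Intervals keep ``pmd_min_separation`` bp apart so that domain
    calling with a 10-kb merge rule cannot fuse two distinct truths, and they
    avoid assembly gaps.
    """
    cells = [f"cell{k}" for k in range(config.n_cell_types)]
    placed: dict[str, list] = {c: [] for c in cells}
    # deterministic proportional scheduling: the realized shared fraction tracks
    # the configured one, and specific PMDs rotate over cell types, so every
    # cell type owns specific domains whenever enough PMDs are planted
    n_shared = n_planted = specific_counter = 0
    for chrom, L in genome.layout.lengths.items():
        gaps = genome.layout.gaps
        gaps_c = gaps[gaps["chrom"] == chrom][["start", "end"]].values.tolist()
        target = config.pmd_fraction * L
        covered = 0.0
        occupied = list(gaps_c)
        attempts = 0
        while covered < target and attempts < 2000:
            attempts += 1
            length = int(rng.integers(config.pmd_min_len, config.pmd_max_len))
            if length >= L:
                break
            s = int(rng.integers(0, L - length))
            e = s + length
            sep = config.pmd_min_separation
            if any(e0 + sep > s and e + sep > s0 for s0, e0 in occupied):
                continue
            occupied.append((s, e))
            covered += length
            n_planted += 1
            if config.n_cell_types == 1:
                owners = cells
            elif n_shared < config.pmd_shared_fraction * n_planted:
                owners = cells
                n_shared += 1
            else:
                owners = [cells[specific_counter % len(cells)]]
                specific_counter += 1
            for c in owners:
                placed[c].append((chrom, s, e))
    out = {}
    for c in cells:
        df = pd.DataFrame(placed[c], columns=["chrom", "start", "end"])
        out[c] = df.sort_values(["chrom", "start"], ignore_index=True)
    return out


def _mask_in_intervals(chroms: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of positions falling inside any interval (per chromosome)."""
    mask = np.zeros(len(pos), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(sub["start"].values)
        order = np.argsort(sub["start"].values, kind="stable")
        ends = sub["end"].values[order]
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        inside[ok] = pos[sel][ok] < ends[idx[ok]]
        mask[sel] = inside
    return mask


def simulate_methylomes(genome: SimulatedGenome, config: SimulationConfig,
                        truth_pmds: dict[str, pd.DataFrame],
                        rng: np.random.Generator) -> dict[str, Methylome]:
    """Draw per-CpG states given planted PMDs, plus the 5hmCH site set.

    Inside a cell type's PMDs ``P(uCG) = ucg_inside``, outside ``ucg_outside``.
    Among the remaining (methylated) CpGs, those at enhancers or gene 3' ends
    are hydroxymethylated with probability ``hmcg_enhancer``, others with
    ``hmcg_background``.  5hmCH sites are drawn from the candidate CH pool with
    intron and coding-strand preference.
    """
    cg = genome.cg_units
    chroms = cg["chrom"].values
    pos = cg["pos"].values
    ann = genome.annotations

    enh_or_3p = pd.concat(
        [genome.annotations.enhancers[["chrom", "start", "end"]],
         ann.utr3[["chrom", "start", "end"]]] if len(ann.utr3) else
        [genome.annotations.enhancers[["chrom", "start", "end"]]],
        ignore_index=True,
    )
    hot_mask = _mask_in_intervals(chroms, pos, enh_or_3p) if len(enh_or_3p) else np.zeros(len(cg), bool)

    # 5hmCH sampling weights: intron and coding-strand preference
    ch = genome.ch_sites
    ch_w = np.ones(len(ch))
    if len(ann.genes) and len(ann.exons):
        introns = _introns(ann)
        in_intron = _mask_in_intervals(ch["chrom"].values, ch["pos"].values, introns)
        ch_w[in_intron] *= config.hmch_intron_weight
        coding = _coding_strand_mask(ch, ann.genes)
        ch_w[coding] *= config.hmch_coding_strand_odds

    out = {}
    for cell, pmds in truth_pmds.items():
        if len(pmds):
            for chrom_name, sub in pmds.groupby("chrom"):
                iv = sub.sort_values("start")[["start", "end"]].values
                if (iv[1:, 0] < iv[:-1, 1]).any():
                    raise ValueError(f"overlapping planted PMDs for {cell} on {chrom_name}")
        inside = _mask_in_intervals(chroms, pos, pmds) if len(pmds) else np.zeros(len(cg), bool)
        p_u = np.where(inside, config.ucg_inside, config.ucg_outside)
        state = np.where(rng.random(len(cg)) < p_u, STATE_U, STATE_M).astype(np.int8)
        meth = state == STATE_M
        p_h = np.where(hot_mask, config.hmcg_enhancer, config.hmcg_background)
        hm = meth & (rng.random(len(cg)) < p_h)
        state[hm] = STATE_H

        n_hmch = min(config.hmch_sites, len(ch))
        hmch_mask = np.zeros(len(ch), dtype=bool)
        if n_hmch > 0 and len(ch):
            p = ch_w / ch_w.sum()
            chosen = rng.choice(len(ch), size=n_hmch, replace=False, p=p)
            hmch_mask[chosen] = True
        out[cell] = Methylome(cell_type=cell, cg_state=state, hmch_mask=hmch_mask)
    return out


def _introns(ann: AnnotationSet) -> pd.DataFrame:
    """Gene-body minus exons, per gene."""
    rows = []
    exons_by_gene = dict(tuple(ann.exons.groupby("gene_id", sort=False)))
    for _, g in ann.genes.iterrows():
        ex = exons_by_gene.get(g.gene_id)
        if ex is None:
            continue
        ex = ex.sort_values("start")
        cur = g.start
        for _, r in ex.iterrows():
            if r.start > cur:
                rows.append((g.chrom, cur, r.start))
            cur = max(cur, r.end)
        if cur < g.end:
            rows.append((g.chrom, cur, g.end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _coding_strand_mask(ch: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """CH sites lying in a gene whose strand matches the site strand."""
    mask = np.zeros(len(ch), dtype=bool)
    for strand in ("+", "-"):
        sub = genes[genes["strand"] == strand][["chrom", "start", "end"]]
        if len(sub) == 0:
            continue
        sel = ch["strand"].values == strand
        mask[sel] = _mask_in_intervals(ch["chrom"].values[sel], ch["pos"].values[sel], sub)
    return mask


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def simulate_reads(genome: SimulatedGenome, methylome: Methylome, config: SimulationConfig,
                   rng: np.random.Generator, mode: str = "hm") -> pd.DataFrame:
    """One technical replicate of TOP-seq-style read starts.

    Tagged CpG units emit Poisson(``lam``) reads split uniformly between the
    two strands; tagged CH sites emit Poisson(``lam``) on their own strand.
    Every read start lies 0..``max_offset`` nt upstream of its cytosine
    (5' of the C on the read's strand).  Untagged sites emit Poisson(``noise``).
    Returns a table ``chrom, pos, strand, count``.
    """
    if config.lam == 0 and config.noise == 0:
        import warnings

        warnings.warn("lam=0 and noise=0: empty read table")
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count"])

    cg = genome.cg_units
    tagged = methylome.tagged(mode)
    rates = np.where(tagged, config.lam, config.noise)
    counts = rng.poisson(rates)
    idx = np.repeat(np.arange(len(cg)), counts)
    strand_is_plus = rng.random(len(idx)) < 0.5
    offs = rng.integers(0, config.max_offset + 1, size=len(idx))
    base = cg["pos"].values[idx]
    read_pos = np.where(strand_is_plus, base - offs, base + 1 + offs)
    frames = [
        pd.DataFrame(
            {
                "chrom": cg["chrom"].values[idx],
                "pos": read_pos,
                "strand": np.where(strand_is_plus, "+", "-"),
            }
        )
    ]
    if mode == "hm" and len(genome.ch_sites):
        ch = genome.ch_sites
        ch_rates = np.where(methylome.hmch_mask, config.lam, config.noise)
        ch_counts = rng.poisson(ch_rates)
        cidx = np.repeat(np.arange(len(ch)), ch_counts)
        coffs = rng.integers(0, config.max_offset + 1, size=len(cidx))
        plus = ch["strand"].values[cidx] == "+"
        cpos = np.where(plus, ch["pos"].values[cidx] - coffs, ch["pos"].values[cidx] + coffs)
        frames.append(
            pd.DataFrame(
                {"chrom": ch["chrom"].values[cidx], "pos": cpos,
                 "strand": ch["strand"].values[cidx]}
            )
        )
    reads = pd.concat(frames, ignore_index=True)
    reads = reads[reads["pos"] >= 0]
    out = (
        reads.groupby(["chrom", "pos", "strand"], sort=True, observed=True)
        .size()
        .reset_index(name="count")
    )
    return out


def simulate_replicates(genome: SimulatedGenome, config: SimulationConfig,
                        truth_pmds: dict[str, pd.DataFrame],
                        rng: np.random.Generator, mode: str = "hm") -> tuple[dict, dict]:
    """Biological x technical replicate structure for every cell type.

    Biological replicates redraw the stochastic layer of the methylome (site
    states given the planted PMDs); technical replicates redraw only the read
    sampling.  Returns ``(reads, methylomes)`` where ``reads[cell][(b, t)]``
    is a read table and ``methylomes[cell][b]`` the underlying truth.
    """
    reads: dict = {}
    meths: dict = {}
    for b in range(config.n_bio):
        bio_meth = simulate_methylomes(genome, config, truth_pmds, rng)
        for cell, m in bio_meth.items():
            meths.setdefault(cell, {})[b] = m
            for t in range(config.n_tech):
                reads.setdefault(cell, {})[(b, t)] = simulate_reads(
                    genome, m, config, rng, mode=mode
                )
    return reads, meths


def simulate_true_mixture(genome: SimulatedGenome, meth_a: Methylome, meth_b: Methylome,
                          p: float, config: SimulationConfig, rng: np.random.Generator,
                          mode: str = "u") -> pd.DataFrame:
    """Ground-truth read-level mixture: reads from A with probability ``p``.

    Implemented by Poisson thinning — the site read count is
    ``Poisson(p * rate_A + (1 - p) * rate_B)``, exactly the law of pooling a
    fraction ``p`` of A's reads with ``1 - p`` of B's.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mixing proportion must lie in [0, 1]")
    cg = genome.cg_units
    rate_a = np.where(meth_a.tagged(mode), config.lam, config.noise)
    rate_b = np.where(meth_b.tagged(mode), config.lam, config.noise)
    rates = p * rate_a + (1.0 - p) * rate_b
    counts = rng.poisson(rates)
    idx = np.repeat(np.arange(len(cg)), counts)
    strand_is_plus = rng.random(len(idx)) < 0.5
    offs = rng.integers(0, config.max_offset + 1, size=len(idx))
    base = cg["pos"].values[idx]
    read_pos = np.where(strand_is_plus, base - offs, base + 1 + offs)
    reads = pd.DataFrame(
        {
            "chrom": cg["chrom"].values[idx],
            "pos": read_pos,
            "strand": np.where(strand_is_plus, "+", "-"),
        }
    )
    reads = reads[reads["pos"] >= 0]
    return (
        reads.groupby(["chrom", "pos", "strand"], sort=True, observed=True)
        .size()
        .reset_index(name="count")
    )


def thin_reads(reads: pd.DataFrame, keep_frac: float, rng: np.random.Generator) -> pd.DataFrame:
    """Binomially thin a read table: each read survives with ``keep_frac``."""
    if not 0.0 <= keep_frac <= 1.0:
        raise ValueError("keep_frac must lie in [0, 1]")
    out = reads.copy()
    out["count"] = rng.binomial(reads["count"].values, keep_frac)
    return out[out["count"] > 0].reset_index(drop=True)


def pool_reads(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate read tables (summing counts at identical read starts)."""
    allr = pd.concat(tables, ignore_index=True)
    return (
        allr.groupby(["chrom", "pos", "strand"], sort=True, observed=True)["count"]
        .sum()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def gene_epigenome_features(genome: SimulatedGenome, methylome: Methylome,
                            truth_pmds: pd.DataFrame) -> pd.DataFrame:
    """Binary epigenomic covariates per gene, from the ground truth.

    Columns: ``hmch`` (gene carries a true 5hmCH site), ``pmd_inside``,
    ``pmd_edge`` (gene crosses a PMD boundary), ``enhancer`` (overlap with any
    enhancer), plus gene length.
    """
    ann = genome.annotations
    g = ann.genes
    ch = genome.ch_sites
    hmch_pos = ch[methylome.hmch_mask]
    hmch = np.zeros(len(g), dtype=bool)
    inside = np.zeros(len(g), dtype=bool)
    edge = np.zeros(len(g), dtype=bool)
    enh = np.zeros(len(g), dtype=bool)
    for i, row in enumerate(g.itertuples()):
        sub = hmch_pos[(hmch_pos["chrom"] == row.chrom)
                       & (hmch_pos["pos"] >= row.start) & (hmch_pos["pos"] < row.end)]
        hmch[i] = len(sub) > 0
        pm = truth_pmds[truth_pmds["chrom"] == row.chrom]
        for s, e in zip(pm["start"], pm["end"]):
            if s <= row.start and row.end <= e:
                inside[i] = True
            elif (s < row.end) and (e > row.start):
                edge[i] = True
        en = ann.enhancers[ann.enhancers["chrom"] == row.chrom]
        enh[i] = bool(((en["start"] < row.end) & (en["end"] > row.start)).any())
    return pd.DataFrame(
        {
            "gene_id": g["gene_id"].values,
            "length": (g["end"] - g["start"]).values,
            "hmch": hmch,
            "pmd_inside": inside,
            "pmd_edge": edge,
            "enhancer": enh,
        }
    ).set_index("gene_id")


def simulate_expression(config: SimulationConfig, features: pd.DataFrame,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial gene x sample counts with planted covariate effects.

    ``log mean = baseline_g + X beta + log(length/1kb)``; the gene-length term
    acts as an offset so doubling a gene's length doubles its expected count.
    Returns the count matrix and the planted effect dictionary.
    """
    betas = {
        "hmch": config.beta_hmch,
        "pmd_inside": config.beta_pmd_inside,
        "pmd_edge": config.beta_pmd_edge,
        "enhancer": config.beta_enhancer,
        "hmch:pmd": config.beta_hmch_pmd,
    }
    X = features[["hmch", "pmd_inside", "pmd_edge", "enhancer"]].astype(float).values
    inter = (features["hmch"] & (features["pmd_inside"] | features["pmd_edge"])).astype(float).values
    eta = (
        X @ np.array([betas["hmch"], betas["pmd_inside"], betas["pmd_edge"], betas["enhancer"]])
        + inter * betas["hmch:pmd"]
    )
    baseline = rng.normal(config.expr_baseline_log, config.expr_baseline_sd, size=len(features))
    log_mu = baseline + eta + np.log(features["length"].values / 1000.0)
    mu = np.exp(log_mu)
    phi = config.expr_dispersion
    counts = np.empty((len(features), config.n_samples), dtype=int)
    for j in range(config.n_samples):
        if phi > 0:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, j] = rng.poisson(mu)
    mat = pd.DataFrame(
        counts, index=features.index, columns=[f"s{j}" for j in range(config.n_samples)]
    )
    return mat, betas
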