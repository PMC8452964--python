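"""Pairwise cell-mixture deconvolution via in-silico swap calibration.

The estimator answers: what fraction of a heterogeneous parental sample is
made of each of its two daughter cell types?  It exploits cell-type-specific
PMDs: uCG calls concentrate inside a daughterline's own unique PMDs, and that
concentration dilutes monotonically as the other cell type is mixed in.

Calibration swaps the uCG identification status of a random fraction ``f`` of
CpG sites between the two daughterlines — a synthetic mixture whose
composition is known exactly — and records the resulting uCG concentration
statistic over a grid of ``f``.  The curve is treated purely as an empirical
transfer function: the parental sample's observed statistic is inverted
through it by piecewise-linear interpolation, and the approach is validated by
recovery of the mixing proportion on true read-level mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .pmd import call_pmds, compute_window_fractions, unique_pmds_2cell
from .simulate import _mask_in_intervals


def _as_rep_list(calls) -> list[np.ndarray]:
    if isinstance(calls, np.ndarray):
        return [np.asarray(calls, dtype=bool)]
    return [np.asarray(c, dtype=bool) for c in calls]


def intersect_replicates(calls) -> np.ndarray:
    """uCG identified in all technical replicates (site-wise AND)."""
    reps = _as_rep_list(calls)
    out = reps[0].copy()
    for r in reps[1:]:
        out &= r
    return out


# ---------------------------------------------------------------------------
# swapping
# ---------------------------------------------------------------------------


def swap_mixture(calls_a, calls_b, f: float, seed: int) -> tuple:
    """Exchange uCG identification status of a random site fraction ``f``.

    ``calls_a``/``calls_b`` are boolean arrays over a shared CpG-unit table
    (or lists of such arrays, one per technical replicate; replicates are
    swapped at the same selected sites).  Deterministic under ``seed`` and an
    involution: applying the same swap twice restores the inputs.  Sites where
    A and B agree are unchanged by construction.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("swap fraction must lie strictly inside (0, 1)")
    a_reps, b_reps = _as_rep_list(calls_a), _as_rep_list(calls_b)
    if len(a_reps) != len(b_reps):
        raise ValueError("replicate counts differ between daughterlines")
    n = len(a_reps[0])
    for arr in a_reps + b_reps:
        if len(arr) != n:
            raise ValueError("mismatched site tables")
    rng = np.random.default_rng(seed)
    k = int(round(f * n))
    sel = np.zeros(n, dtype=bool)
    sel[rng.choice(n, size=k, replace=False)] = True
    a_out, b_out = [], []
    for a, b in zip(a_reps, b_reps):
        a2, b2 = a.copy(), b.copy()
        a2[sel], b2[sel] = b[sel], a[sel]
        a_out.append(a2)
        b_out.append(b2)
    if isinstance(calls_a, np.ndarray):
        return a_out[0], b_out[0]
    return a_out, b_out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Swap fraction -> mean uCG concentration in a daughterline's unique PMDs."""

    daughter: str
    f: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    interpolated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f": self.f, "mean": self.mean, "sd": self.sd,
             "interpolated": self.interpolated}
        )


def _region_masks(cg_units: pd.DataFrame, unique_pmds: pd.DataFrame,
                  reference_pmds: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    chroms = cg_units["chrom"].values
    pos = cg_units["pos"].values
    zero = np.zeros(len(pos), dtype=bool)
    in_u = _mask_in_intervals(chroms, pos, unique_pmds) if len(unique_pmds) else zero
    in_ref = _mask_in_intervals(chroms, pos, reference_pmds) if len(reference_pmds) else zero
    return in_u, in_ref


def _concentration_from_masks(calls: np.ndarray, in_u: np.ndarray, in_ref: np.ndarray,
                              site_mask: np.ndarray | None = None) -> float:
    sel = calls & in_ref
    if site_mask is not None:
        sel = sel & site_mask
    denom = int(sel.sum())
    if denom == 0:
        return float("nan")
    return float((sel & in_u).sum() / denom)


def ucg_concentration(calls: np.ndarray, cg_units: pd.DataFrame,
                      unique_pmds: pd.DataFrame, reference_pmds: pd.DataFrame,
                      site_mask: np.ndarray | None = None) -> float:
    """Fraction of called uCG sites in the reference PMDs that fall in the unique PMDs.

    ``reference_pmds`` is the motherline PMD set (or its proxy, the union of
    the daughterline PMDs): the statistic is the share of PMD-resident uCG
    evidence concentrated in the cell-type-specific domains.
    """
    in_u, in_ref = _region_masks(cg_units, unique_pmds, reference_pmds)
    sel = calls & in_ref
    if site_mask is not None:
        sel = sel & site_mask
    denom = int(sel.sum())
    if denom == 0:
        return float("nan")
    return float((sel & in_u).sum() / denom)


def build_calibration(calls_a, calls_b, cg_units: pd.DataFrame, layout: GenomeLayout,
                      unique_a: pd.DataFrame, unique_b: pd.DataFrame,
                      reference_pmds: pd.DataFrame,
                      f_grid: np.ndarray | None = None, n_resample: int = 200,
                      subsample_frac: float = 0.01, seed: int = 0,
                      recompute_pmds: bool = False,
                      pmd_kwargs: dict | None = None) -> dict[str, CalibrationCurve]:
    """Calibration curves for both daughterlines over a swap-fraction grid.

    For each ``f``: swap the technical-replicate call sets, intersect
    replicates, and measure the uCG concentration statistic in each
    daughterline's unique 2-cell-PMDs, with mean and SD estimated from
    ``n_resample`` random site subsamples of size ``subsample_frac``.

    By default the unique 2-cell-PMDs and the reference set are held fixed at
    the pure-daughterline regions, which keeps the curve defined and monotone
    over the whole grid; ``recompute_pmds=True`` instead re-calls PMDs de novo
    in every swap mixture (undefined values at f where a unique set vanishes
    are linearly interpolated and flagged).
    """
    if f_grid is None:
        f_grid = np.arange(1, 100, 2) / 100.0
    a_reps, b_reps = _as_rep_list(calls_a), _as_rep_list(calls_b)
    n = len(a_reps[0])
    rng = np.random.default_rng(seed)
    k_sub = max(int(round(subsample_frac * n)), 50)
    orig_a = intersect_replicates(a_reps)
    orig_b = intersect_replicates(b_reps)
    candidates = np.where(orig_a | orig_b)[0]
    fixed_masks = {
        "A": _region_masks(cg_units, unique_a, reference_pmds),
        "B": _region_masks(cg_units, unique_b, reference_pmds),
    }

    means = {"A": [], "B": []}
    sds = {"A": [], "B": []}
    for i, f in enumerate(f_grid):
        a2, b2 = swap_mixture(a_reps, b_reps, float(f), seed=seed + 1000 + i)
        ca = intersect_replicates(a2)
        cb = intersect_replicates(b2)
        if recompute_pmds:
            kw = pmd_kwargs or {}
            wa = compute_window_fractions(ca, cg_units, layout)
            wb = compute_window_fractions(cb, cg_units, layout)
            pa = call_pmds(wa, layout, **kw)
            pb = call_pmds(wb, layout, **kw)
            ua, ub = unique_pmds_2cell(pa, pb, wa, wb)
            masks = {
                "A": _region_masks(cg_units, ua, reference_pmds),
                "B": _region_masks(cg_units, ub, reference_pmds),
            }
        else:
            masks = fixed_masks
        for name, calls in (("A", ca), ("B", cb)):
            in_u, in_ref = masks[name]
            vals = np.empty(n_resample)
            for r in range(n_resample):
                mask = np.zeros(n, dtype=bool)
                if len(candidates):
                    take = rng.choice(candidates, size=min(k_sub, len(candidates)), replace=False)
                    mask[take] = True
                vals[r] = _concentration_from_masks(calls, in_u, in_ref, mask)
            vals = vals[np.isfinite(vals)]
            means[name].append(float(vals.mean()) if len(vals) else np.nan)
            sds[name].append(float(vals.std(ddof=1)) if len(vals) > 1 else np.nan)

    out = {}
    for name in ("A", "B"):
        m = np.asarray(means[name])
        s = np.asarray(sds[name])
        interp = ~np.isfinite(m)
        if interp.any() and np.isfinite(m).sum() >= 2:
            ok = np.isfinite(m)
            m = np.interp(f_grid, f_grid[ok], m[ok])
        out[name] = CalibrationCurve(daughter=name, f=f_grid.copy(), mean=m, sd=s,
                                     interpolated=interp)
    return out


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def estimate_fraction(parent_calls, cg_units: pd.DataFrame, unique_pmds: pd.DataFrame,
                      motherline_pmds: pd.DataFrame, curve: CalibrationCurve) -> dict:
    """Invert the parent sample's uCG concentration through a calibration curve.

    The parent statistic is the fraction of its replicate-consistent uCG sites
    inside the motherline PMD set that fall within the daughterline's unique
    2-cell-PMDs.  Inversion is piecewise-linear; observations outside the
    curve range clamp to the nearest endpoint (flagged), and non-monotone
    segments yield every crossing with an ``ambiguous`` flag.  The returned
    ``fraction`` is the estimated share of the curve's daughterline
    (``1 - f``), with an uncertainty propagated from the resampling SD through
    the local slope.
    """
    parent = intersect_replicates(_as_rep_list(parent_calls))
    observed = ucg_concentration(parent, cg_units, unique_pmds, motherline_pmds)
    f, m = curve.f, curve.mean
    flags = []
    crossings = []
    for i in range(len(f) - 1):
        lo, hi = sorted((m[i], m[i + 1]))
        if lo <= observed <= hi and m[i] != m[i + 1]:
            t = (observed - m[i]) / (m[i + 1] - m[i])
            crossings.append(f[i] + t * (f[i + 1] - f[i]))
    if not crossings:
        f_hat = f[0] if abs(observed - m[0]) < abs(observed - m[-1]) else f[-1]
        flags.append("out_of_range")
    else:
        f_hat = float(np.mean(crossings))
        if len(crossings) > 1:
            flags.append("ambiguous")
    i_near = int(np.argmin(np.abs(f - f_hat)))
    slope = np.gradient(m, f)[i_near]
    sd = curve.sd[i_near] if np.isfinite(curve.sd[i_near]) else np.nan
    uncertainty = float(abs(sd / slope)) if slope != 0 and np.isfinite(sd) else float("nan")
    return {
        "observed": float(observed),
        "f_hat": float(f_hat),
        "fraction": float(1.0 - f_hat),
        "uncertainty": uncertainty,
        "crossings": [float(c) for c in crossings],
        "flags": flags,
    }
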