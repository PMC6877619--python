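"""Interaction-frequency decay with genomic distance.

Per chromosome, the decay curve is the median normalized Hi-C value at
each diagonal (distance in bins), with structurally absent sparse cells
counted as zeros so sparse and dense inputs agree. The decay slope is an
ordinary least-squares fit of log10(median) on log10(distance in bp) over
a short-range window where the decay is close to linear. Pairwise slope
differences (deltas), normalized cumulative decay curves (CDFs), the
Kuiper statistic between CDFs, and the chrX-vs-autosome rank-sum
comparison complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix


@dataclass
class DecayCurve:
    chromosome: str
    distances: np.ndarray  # bins
    medians: np.ndarray
    bin_size: int
    scale: str  # "signal" or "frequency"


@dataclass
class SlopeFit:
    chromosome: str
    slope: float
    intercept: float
    fit_range: tuple[int, int]  # bins


@dataclass
class DecayCDF:
    chromosome: str
    distances: np.ndarray
    cdf: np.ndarray


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    x_deltas: np.ndarray
    autosome_deltas: np.ndarray


def decay_curve(m: ContactMatrix, min_dist: int = 2, max_dist: int = 100) -> dict[str, DecayCurve]:
    """Per-distance median of cis values for every chromosome.

    The median at distance ``d`` is taken over the full diagonal of the
    chromosome (absent sparse cells count as 0; non-finite stored values
    are set to 0). Chromosomes shorter than ``max_dist + 1`` bins get a
    truncated distance range with a warning.
    """
    if m.kind not in ("balanced", "frequency"):
        raise ValueError("decay_curve expects a balanced or frequency matrix")
    scale = "frequency" if m.kind == "frequency" else "signal"
    out: dict[str, DecayCurve] = {}
    for c in m.genome.chrom_names:
        n = m.genome.n_bins_of(c)
        hi = max_dist
        if n - 1 < max_dist:
            hi = n - 1
            warnings.warn(
                f"chromosome {c!r}: only {n} bins; decay range truncated to {hi}",
                stacklevel=2,
            )
        dense = m.cis_dense(c)
        dists = np.arange(min_dist, hi + 1)
        meds = np.array([float(np.median(np.diagonal(dense, d))) for d in dists])
        out[c] = DecayCurve(c, dists, meds, m.genome.bin_size, scale)
    return out


def fit_decay_slope(curve: DecayCurve, fit_min: int = 2, fit_max: int = 15) -> SlopeFit:
    """OLS of log10(median) on log10(distance in bp) over the fit range.

    Zero medians are dropped from the fit (with a warning); fewer than 3
    usable points is an error.
    """
    sel = (curve.distances >= fit_min) & (curve.distances <= fit_max)
    d = curve.distances[sel].astype(float) * curve.bin_size
    y = curve.medians[sel]
    pos = y > 0
    if (~pos).any():
        warnings.warn(
            f"chromosome {curve.chromosome!r}: {int((~pos).sum())} zero medians dropped from slope fit",
            stacklevel=2,
        )
    if pos.sum() < 3:
        raise ValueError(
            f"chromosome {curve.chromosome!r}: only {int(pos.sum())} positive medians in fit range"
        )
    slope, intercept = np.polyfit(np.log10(d[pos]), np.log10(y[pos]), 1)
    return SlopeFit(curve.chromosome, float(slope), float(intercept), (fit_min, fit_max))


def slope_deltas(fits: list[SlopeFit] | dict[str, SlopeFit]) -> pd.DataFrame:
    """Antisymmetric table of pairwise slope differences, Δ(a, b) = slope_a − slope_b."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    names = [f.chromosome for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in slope fits")
    if len(names) < 2:
        raise ValueError("need at least 2 chromosomes")
    s = np.array([f.slope for f in fits])
    table = s[:, None] - s[None, :]
    return pd.DataFrame(table, index=names, columns=names)


def decay_cdf(curve: DecayCurve) -> DecayCDF:
    """Normalized cumulative sum of median contact frequencies over the distance grid."""
    if curve.scale != "frequency":
        raise ValueError("decay_cdf expects a frequency-scale curve")
    total = curve.medians.sum()
    if total <= 0:
        raise ValueError(f"chromosome {curve.chromosome!r}: all-zero decay curve")
    cs = np.cumsum(curve.medians)
    return DecayCDF(curve.chromosome, curve.distances.copy(), cs / cs[-1])


def kuiper_statistic(a: DecayCDF, b: DecayCDF) -> float:
    """Kuiper's V: max positive plus max negative CDF deviation (each floored at 0)."""
    if len(a.distances) != len(b.distances) or not np.array_equal(a.distances, b.distances):
        raise ValueError("CDF distance grids differ")
    up = max(float(np.max(a.cdf - b.cdf)), 0.0)
    dn = max(float(np.max(b.cdf - a.cdf)), 0.0)
    return up + dn


def compare_x_vs_autosomes(deltas: pd.DataFrame, chrx_name: str) -> RankSumResult:
    """Rank-sum test of chrX-vs-autosome slope deltas against autosome-pair deltas.

    Group one holds Δ(chrX, autosome) for every autosome; group two holds
    Δ(a, b) over unordered autosome pairs in table order. The two-sided
    p-value uses the exact distribution for small tie-free samples.
    """
    if chrx_name not in deltas.index:
        raise ValueError(f"{chrx_name!r} not in delta table")
    autosomes = [c for c in deltas.index if c != chrx_name]
    x_vals = np.array([deltas.loc[chrx_name, a] for a in autosomes])
    auto_vals = np.array(
        [deltas.loc[a, b] for k, a in enumerate(autosomes) for b in autosomes[k + 1 :]]
    )
    if len(x_vals) < 2 or len(auto_vals) < 2:
        raise ValueError(
            f"need >= 2 deltas per group (chrX group {len(x_vals)}, autosome group {len(auto_vals)})"
        )
    res = stats.mannwhitneyu(x_vals, auto_vals, alternative="two-sided")
    return RankSumResult(float(res.statistic), float(res.pvalue), x_vals, auto_vals)
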