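"""Feature tracks around domain boundaries: enrichment, insulator classes,
aggregate pairwise pile-ups, 4C enrichment, and TSS-boundary association.

Point features (binding-site midpoints, TSSs) are assigned to the genomic
bin containing their midpoint. Enrichment around boundary classes uses a
uniform null: the expected number of sites per bin is the chromosome total
divided by the chromosome length in bins, and the observed density is
counted inside boundary-flank windows that are split at the midpoint
between neighbouring boundaries so no bin is counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

# imported lazily at call sites would be circular-safe, but lsd does not
# import features, so a direct import is fine
from .lsd import BoundarySet


@dataclass
class FeatureTrack:
    """Point features (chrom, pos[, extra columns]) or scaled signal
    intervals (chrom, start, end, value)."""

    name: str
    data: pd.DataFrame
    kind: str = "point"  # "point" or "signal"
    scaling: str | None = None  # e.g. "99th-percentile"

    @classmethod
    def read_points(cls, path, name: str = "sites") -> "FeatureTrack":
        """Read point features from BED: midpoint of (start, end) is the site."""
        df = pd.read_csv(path, sep="\t", header=None)
        out = pd.DataFrame({"chrom": df[0], "pos": (df[1] + df[2]) // 2})
        if df.shape[1] > 3:
            out["name"] = df[3]
        return cls(name=name, data=out, kind="point")

    @classmethod
    def read_signal(cls, path, name: str = "signal") -> "FeatureTrack":
        """Read a bedGraph (chrom, start, end, value) signal track."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
        return cls(name=name, data=df, kind="signal")

    def scale_99th(self) -> "FeatureTrack":
        """Divide signal values by their 99th percentile (cross-sample scaling)."""
        if self.kind != "signal":
            raise ValueError("99th-percentile scaling applies to signal tracks")
        q = np.percentile(self.data["value"], 99)
        if q <= 0:
            raise ValueError("99th percentile of the signal is not positive")
        df = self.data.copy()
        df["value"] = df["value"] / q
        return FeatureTrack(self.name, df, "signal", scaling="99th-percentile")


def boundary_windows(b: BoundarySet, half: int = 15) -> pd.DataFrame:
    """Flanking windows of up to ``half`` bins per side around each boundary.

    Windows are centred on the boundary junction coordinate; where the
    windows of neighbouring boundaries would overlap, the intervening
    region is split equally between the two, so the returned windows are
    pairwise disjoint. Coordinates are bp, clipped to the chromosome.
    """
    bs = b.bin_size
    juncs = b.junctions
    jc = (juncs + 1) * bs  # junction coordinates
    length = b.n_bins * bs
    rows = []
    for k, e in enumerate(juncs):
        lo = jc[k] - half * bs
        hi = jc[k] + half * bs
        if k > 0:
            lo = max(lo, (jc[k - 1] + jc[k]) // 2)
        if k < len(juncs) - 1:
            hi = min(hi, (jc[k] + jc[k + 1]) // 2)
        rows.append(
            {"junction": int(e), "start": int(max(lo, 0)), "end": int(min(hi, length))}
        )
    return pd.DataFrame(rows, columns=["junction", "start", "end"])


def feature_enrichment(
    windows: pd.DataFrame, track: FeatureTrack, g: GenomeModel, chrom: str
) -> float:
    """log2 observed/expected site density inside boundary windows.

    Expected density is the uniform null: total sites on the chromosome
    divided by the chromosome length in bins. Observed density is sites
    falling inside the windows divided by the total window length in bins.
    """
    if track.kind != "point":
        raise ValueError("feature_enrichment expects a point track")
    total_len_bins = float((windows["end"] - windows["start"]).sum()) / g.bin_size
    if total_len_bins == 0:
        raise ValueError("zero total window length")
    sites = track.data.loc[track.data["chrom"] == chrom, "pos"].to_numpy()
    n_total = len(sites)
    if n_total == 0:
        raise ValueError(f"no sites on chromosome {chrom!r}")
    exp_per_bin = n_total / g.n_bins_of(chrom)
    inside = 0
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, sites, side="right") - 1
    ok = (idx >= 0) & (sites < ends[np.clip(idx, 0, len(ends) - 1)])
    inside = int(ok.sum())
    obs_per_bin = inside / total_len_bins
    with np.errstate(divide="ignore"):
        return float(np.log2(obs_per_bin / exp_per_bin))


def feature_enrichment_by_class(
    b: BoundarySet,
    classes: dict[str, np.ndarray],
    track: FeatureTrack,
    g: GenomeModel,
    chrom: str,
    half: int = 15,
) -> dict[str, float]:
    """Per-class log2 observed/expected density around boundary junctions.

    Windows are built over the full boundary set (so the equal-split rule
    sees every neighbour) and then grouped by the class of their junction.
    """
    win = boundary_windows(b, half)
    out = {}
    for cls_name, juncs in classes.items():
        sub = win[win["junction"].isin(np.asarray(juncs))]
        if len(sub) == 0:
            raise ValueError(f"class {cls_name!r} has no boundaries with windows")
        out[cls_name] = feature_enrichment(sub, track, g, chrom)
    return out


def _summits(regions: pd.DataFrame, track: FeatureTrack, chrom: str) -> np.ndarray:
    """Max scaled signal within each boundary region (0 where uncovered)."""
    df = track.data[track.data["chrom"] == chrom]
    s = df["start"].to_numpy()
    e = df["end"].to_numpy()
    v = df["value"].to_numpy()
    out = np.zeros(len(regions))
    for k, row in enumerate(regions.itertuples(index=False)):
        hit = (s < row.end) & (e > row.start)
        if hit.any():
            out[k] = v[hit].max()
    return out


BEAF_AND_CPCH = "BEAF+ and CP/CH+"
BEAF_OR_CPCH = "BEAF+ or CP/CH+"
BEAF_NOR_CPCH = "BEAF- and CP/CH-"


def classify_insulator_boundaries(
    regions: pd.DataFrame,
    beaf: FeatureTrack,
    cp190: FeatureTrack,
    chromator: FeatureTrack,
    chrom: str,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Combinatorial insulator class per boundary from scaled ChIP summits.

    The summit of each factor is the maximum 99th-percentile-scaled signal
    inside the boundary region (callers comparing two sexes should pass
    tracks holding the per-interval maximum of the two). Classes: (i)
    BEAF-32 high and at least one of CP190/Chromator high; (ii) exactly
    one side high (BEAF-32 alone, or CP190-or-Chromator without BEAF-32);
    (iii) everything low.
    """
    for nm, tr in (("beaf", beaf), ("cp190", cp190), ("chromator", chromator)):
        if tr is None:
            raise ValueError(f"missing insulator track: {nm}")
        if tr.kind != "signal":
            raise ValueError(f"insulator track {nm} must be a signal track")
    b = _summits(regions, beaf, chrom)
    cp = _summits(regions, cp190, chrom)
    ch = _summits(regions, chromator, chrom)
    beaf_hi = b > cutoff
    cpch_hi = (cp > cutoff) | (ch > cutoff)
    cls = np.where(
        beaf_hi & cpch_hi,
        BEAF_AND_CPCH,
        np.where(beaf_hi | cpch_hi, BEAF_OR_CPCH, BEAF_NOR_CPCH),
    )
    out = regions.copy()
    out["beaf_summit"] = b
    out["cp190_summit"] = cp
    out["chromator_summit"] = ch
    out["insulator_class"] = cls
    return out


def aggregate_pairwise_profile(
    dense: np.ndarray, anchors: np.ndarray, n: int = 20
) -> tuple[np.ndarray, int]:
    """Mean log2 background-normalized pile-up over anchor pairs.

    ``dense`` is one chromosome's symmetric cis matrix (non-finite values
    treated as 0); anchors are local bin indices. Retained pairs (i, j)
    satisfy n <= i <= D-1-n and i + 2n < j <= D-1-n (0-based), which keeps
    the (2n+1)^2 window inside the matrix and off the diagonal. Each
    window is divided by the mean of its (2(n+1)+1)^2 background window,
    log2-transformed (non-finite cells set to 0), and averaged over pairs.
    Returns the profile and the number of pairs used.
    """
    dense = np.where(np.isfinite(dense), dense, 0.0)
    d = dense.shape[0]
    anchors = np.sort(np.unique(np.asarray(anchors, dtype=np.int64)))
    # background window needs n+1 bins of clearance
    valid = anchors[(anchors >= n + 1) & (anchors <= d - n - 2)]
    acc = np.zeros((2 * n + 1, 2 * n + 1))
    used = 0
    total_pairs = 0
    for ai, i in enumerate(valid):
        for j in valid[ai + 1 :]:
            total_pairs += 1
            if not (j > i + 2 * n):
                continue
            win = dense[i - n : i + n + 1, j - n : j + n + 1]
            bg = dense[i - n - 1 : i + n + 2, j - n - 1 : j + n + 2]
            bg_mean = bg.mean()
            if bg_mean == 0:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                logw = np.log2(win / bg_mean)
            logw = np.where(np.isfinite(logw), logw, 0.0)
            acc += logw
            used += 1
    if used == 0:
        raise ValueError(
            f"no anchor pair survived the filters ({len(anchors)} anchors, "
            f"{total_pairs} candidate pairs)"
        )
    return acc / used, used


# ---------------------------------------------------------------------------
# 4C enrichment
# ---------------------------------------------------------------------------


@dataclass
class FourCTrack:
    """Binarized, replicate-merged 4C fragment values and their enrichment.

    ``data`` columns: chrom, midpoint, v (0/1); after
    :func:`fourc_enrichment`, also ``enrichment`` (NaN where undefined).
    """

    data: pd.DataFrame
    w_small: int | None = None
    w_big: int | None = None


def binarize_fragments(counts: pd.DataFrame, replicate_cols: list[str]) -> pd.DataFrame:
    """Merge replicate read counts per fragment into a 0/1 value.

    A fragment scores 1 when any replicate has at least one read.
    """
    out = counts[["chrom", "midpoint"]].copy()
    out["v"] = (counts[replicate_cols].to_numpy() > 0).any(axis=1).astype(np.int64)
    return out


def filter_probes(
    manifest: pd.DataFrame, max_replicate_fold: float = 2.0, max_cross_fold: float = 1.5
) -> list[str]:
    """Probe-level QC on a read-count manifest (probe, sample, replicate, reads).

    A probe is discarded when its two replicates differ by at least
    ``max_replicate_fold`` in total reads within any sample, or when its
    per-sample totals differ by more than ``max_cross_fold`` across the
    compared samples. Returns the list of retained probe names.
    """
    keep = []
    for probe, grp in manifest.groupby("probe"):
        ok = True
        totals = []
        for _, sg in grp.groupby("sample"):
            reads = sg["reads"].to_numpy(dtype=float)
            if len(reads) >= 2 and reads.max() / max(reads.min(), 1) >= max_replicate_fold:
                ok = False
            totals.append(reads.sum())
        if ok and len(totals) >= 2:
            if max(totals) / max(min(totals), 1) > max_cross_fold:
                ok = False
        if ok:
            keep.append(probe)
    return keep


def fourc_enrichment(
    track: FourCTrack,
    chrom_lengths: dict[str, int],
    w_small: int = 20000,
    w_big: int = 600000,
) -> FourCTrack:
    """Windowed 4C enrichment per fragment midpoint.

    E_m = log10( sum of v in +/- w_small / sum of v in +/- w_big + 1 ),
    defined for w_big <= m <= l_chr - w_big. A zero big-window sum leaves
    E_m undefined (NaN) and flagged.
    """
    parts = []
    for chrom, grp in track.data.groupby("chrom", sort=False):
        grp = grp.sort_values("midpoint").reset_index(drop=True)
        m = grp["midpoint"].to_numpy()
        v = grp["v"].to_numpy(dtype=float)
        cs = np.concatenate([[0.0], np.cumsum(v)])

        def winsum(w):
            lo = np.searchsorted(m, m - w, side="left")
            hi = np.searchsorted(m, m + w, side="right")
            return cs[hi] - cs[lo]

        small = winsum(w_small)
        big = winsum(w_big)
        l_chr = chrom_lengths[chrom]
        in_domain = (m >= w_big) & (m <= l_chr - w_big)
        e = np.full(len(m), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = small / big
        defined = in_domain & (big > 0)
        e[defined] = np.log10(ratio[defined] + 1.0)
        grp = grp.copy()
        grp["enrichment"] = e
        grp["undefined_bg"] = in_domain & (big == 0)
        parts.append(grp)
    return FourCTrack(pd.concat(parts, ignore_index=True), w_small, w_big)


def fourc_boundary_summary(
    track: FourCTrack,
    b: BoundarySet,
    classes: dict[str, np.ndarray],
    chrom: str,
    half: int = 35000,
) -> dict[str, tuple[np.ndarray, np.ndarray, float]]:
    """Mean 4C enrichment around boundary junctions, per class.

    Fragments are mapped to contact-map bins (bin value = mean enrichment
    over its fragments); bins are re-indexed by offset from the bin
    containing each boundary junction, and the metaprofile is the mean
    across the class's boundaries per offset. Returns, per class,
    ``(offsets_bins, metaprofile, scalar)`` where the scalar is the mean
    over offsets within +/- ``half`` bp. Classes with no covered boundary
    are dropped with a warning.
    """
    bs = b.bin_size
    df = track.data[track.data["chrom"] == chrom]
    if "enrichment" not in df:
        raise ValueError("run fourc_enrichment first")
    bins = (df["midpoint"].to_numpy() // bs).astype(np.int64)
    e_b = pd.Series(df["enrichment"].to_numpy()).groupby(bins).mean()
    bin_val = np.full(b.n_bins, np.nan)
    idx = e_b.index.to_numpy()
    ok = (idx >= 0) & (idx < b.n_bins)
    bin_val[idx[ok]] = e_b.to_numpy()[ok]
    k = half // bs
    offsets = np.arange(-k, k + 1)
    out = {}
    for cls_name, juncs in classes.items():
        rows = []
        for e in np.asarray(juncs, dtype=np.int64):
            centre = e + 1  # bin containing the junction coordinate
            prof = np.full(len(offsets), np.nan)
            for oi, o in enumerate(offsets):
                p = centre + o
                if 0 <= p < b.n_bins:
                    prof[oi] = bin_val[p]
            if np.isfinite(prof).any():
                rows.append(prof)
        if not rows:
            warnings.warn(f"class {cls_name!r}: no boundary covered by 4C data", stacklevel=2)
            continue
        meta = np.nanmean(np.vstack(rows), axis=0)
        out[cls_name] = (offsets, meta, float(np.nanmean(meta)))
    return out


def assign_tss_to_boundaries(
    tss: FeatureTrack, b: BoundarySet, chrom: str, max_dist: int = 10000
) -> pd.DataFrame:
    """Unique (boundary, gene) pairs by nearest-boundary competition.

    Every gene (active or not) is mapped to its nearest boundary junction;
    pairs at distance >= ``max_dist`` are dropped; per boundary only the
    closest gene survives; finally low/no-expression genes are removed.
    Inactive genes take part in the competition first, as a guard against
    spurious active-gene/boundary associations.
    """
    if tss.kind != "point":
        raise ValueError("assign_tss_to_boundaries expects a point track")
    df = tss.data[tss.data["chrom"] == chrom].copy()
    juncs = b.junctions
    if len(juncs) == 0 or len(df) == 0:
        return pd.DataFrame(columns=["junction", "gene", "distance", "active"])
    jc = (juncs + 1) * b.bin_size
    pos = df["pos"].to_numpy()
    right = np.searchsorted(jc, pos)
    left = np.clip(right - 1, 0, len(jc) - 1)
    right = np.clip(right, 0, len(jc) - 1)
    d_left = np.abs(pos - jc[left])
    d_right = np.abs(pos - jc[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    df["junction"] = juncs[nearest]
    df["distance"] = dist
    df = df[df["distance"] < max_dist]
    df = df.sort_values(["junction", "distance"], kind="stable").groupby("junction").head(1)
    if "active" in df:
        df = df[df["active"].astype(bool)]
    gene_col = "gene" if "gene" in df else ("name" if "name" in df else None)
    out = pd.DataFrame(
        {
            "junction": df["junction"].to_numpy(),
            "gene": df[gene_col].to_numpy() if gene_col else df["pos"].to_numpy(),
            "distance": df["distance"].to_numpy(),
            "active": df["active"].to_numpy() if "active" in df else True,
        }
    )
    return out.reset_index(drop=True)
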