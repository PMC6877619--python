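"""Boundary windows, enrichment, insulator classes, pile-ups, 4C, TSS pairing."""

import numpy as np
import pandas as pd
import pytest

from hicarch import (
    BoundarySet,
    FeatureTrack,
    FourCTrack,
    GenomeModel,
    aggregate_pairwise_profile,
    assign_tss_to_boundaries,
    boundary_windows,
    classify_insulator_boundaries,
    feature_enrichment,
    fourc_boundary_summary,
    fourc_enrichment,
)
from hicarch.features import BEAF_AND_CPCH, BEAF_NOR_CPCH, BEAF_OR_CPCH, binarize_fragments

BS = 3500


def bset(junctions, n_bins=400):
    return BoundarySet("X", BS, n_bins, np.array([], dtype=int), np.asarray(junctions, dtype=np.int64))


def test_isolated_boundary_gets_full_window():
    w = boundary_windows(bset([100]), half=15)
    jc = 101 * BS
    assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (jc - 15 * BS, jc + 15 * BS)


def test_neighbouring_windows_split_equally_and_are_disjoint():
    w = boundary_windows(bset([100, 110]), half=15)
    jc0, jc1 = 101 * BS, 111 * BS
    mid = (jc0 + jc1) // 2
    assert w.iloc[0]["end"] == mid
    assert w.iloc[1]["start"] == mid
    # each boundary keeps 5 of the 10 intervening bins
    assert (w.iloc[0]["end"] - jc0) == 5 * BS
    # disjoint cover
    assert w.iloc[0]["end"] <= w.iloc[1]["start"]


def test_window_clipped_at_chromosome_start():
    w = boundary_windows(bset([3]), half=15)
    assert w.iloc[0]["start"] == 0


def test_feature_enrichment_arithmetic():
    g = GenomeModel([("X", 1000 * BS, 2)], BS)
    # windows covering 100 bins; 20 of 100 sites inside -> obs 0.2/bin, exp 0.1/bin
    windows = pd.DataFrame({"junction": [50], "start": [0], "end": [100 * BS]})
    rng = np.random.default_rng(0)
    inside = rng.integers(0, 100 * BS, 20)
    outside = rng.integers(100 * BS, 1000 * BS, 80)
    track = FeatureTrack("t", pd.DataFrame({"chrom": "X", "pos": np.concatenate([inside, outside])}))
    lr = feature_enrichment(windows, track, g, "X")
    assert lr == pytest.approx(1.0)
    with pytest.raises(ValueError, match="zero total window"):
        feature_enrichment(pd.DataFrame({"junction": [], "start": [], "end": []}), track, g, "X")


def signal(chrom, start, end, value):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end], "value": [value]})


def make_track(value):
    return FeatureTrack("s", signal("X", 0, 10 * BS, value), kind="signal")


@pytest.mark.parametrize(
    "beaf,cp,ch,expect",
    [
        (0.9, 0.7, 0.1, BEAF_AND_CPCH),
        (0.9, 0.2, 0.2, BEAF_OR_CPCH),
        (0.2, 0.9, 0.9, BEAF_OR_CPCH),
        (0.2, 0.2, 0.2, BEAF_NOR_CPCH),
    ],
)
def test_insulator_classification_rules(beaf, cp, ch, expect):
    regions = pd.DataFrame({"junction": [2], "start": [BS], "end": [2 * BS]})
    out = classify_insulator_boundaries(
        regions, make_track(beaf), make_track(cp), make_track(ch), "X"
    )
    assert out["insulator_class"].iloc[0] == expect


def test_missing_insulator_track_is_named():
    regions = pd.DataFrame({"junction": [2], "start": [BS], "end": [2 * BS]})
    with pytest.raises(ValueError, match="cp190"):
        classify_insulator_boundaries(regions, make_track(1), None, make_track(1), "X")


def test_profile_constant_matrix_is_zero():
    d = np.full((60, 60), 4.0)
    prof, used = aggregate_pairwise_profile(d, np.array([10, 50]), n=5)
    assert used == 1
    assert np.allclose(prof, 0.0)


def test_profile_pair_filter():
    d = np.full((120, 120), 1.0)
    # j = 65 <= i + 2n = 70 -> the only candidate pair excluded
    with pytest.raises(ValueError, match="no anchor pair"):
        aggregate_pairwise_profile(d, np.array([30, 65]), n=20)


def test_profile_matches_dense_brute_force_with_planted_pixel():
    n = 3
    rng = np.random.default_rng(5)
    d = rng.random((40, 40)) + 1.0
    d = (d + d.T) / 2
    anchors = np.array([10, 25])
    d[10, 25] = d[25, 10] = 25.0
    prof, used = aggregate_pairwise_profile(d, anchors, n=n)
    assert used == 1
    i, j = anchors
    win = d[i - n:i + n + 1, j - n:j + n + 1]
    bg = d[i - n - 1:i + n + 2, j - n - 1:j + n + 2]
    expect = np.log2(win / bg.mean())
    assert np.allclose(prof, expect, atol=1e-9)
    assert prof[n, n] == prof.max() > 0


def test_fourc_enrichment_window_sums():
    # fragments every 1 kb, all v = 1: E = log10(1 + 41/1201)
    pos = np.arange(0, 1_300_001, 1000)
    frags = FourCTrack(pd.DataFrame({"chrom": "X", "midpoint": pos, "v": 1}))
    out = fourc_enrichment(frags, {"X": 1_300_000}, w_small=20_000, w_big=600_000)
    df = out.data
    mid = df[df["midpoint"] == 650_000]
    assert mid["enrichment"].iloc[0] == pytest.approx(np.log10(1 + 41 / 1201), abs=1e-12)
    # positions closer than w_big to an edge are excluded
    assert np.isnan(df.loc[df["midpoint"] == 10_000, "enrichment"]).all()
    # brute-force check at an arbitrary interior midpoint
    m = 700_000
    v = df.set_index("midpoint")["v"]
    small = v[(v.index >= m - 20_000) & (v.index <= m + 20_000)].sum()
    big = v[(v.index >= m - 600_000) & (v.index <= m + 600_000)].sum()
    assert df.loc[df["midpoint"] == m, "enrichment"].iloc[0] == pytest.approx(
        np.log10(small / big + 1), abs=1e-12
    )


def test_fourc_zero_small_window_gives_zero_enrichment():
    pos = np.arange(0, 1_300_001, 1000)
    v = np.ones(len(pos), dtype=int)
    centre = 650_000
    v[np.abs(pos - centre) <= 20_000] = 0
    frags = FourCTrack(pd.DataFrame({"chrom": "X", "midpoint": pos, "v": v}))
    out = fourc_enrichment(frags, {"X": 1_300_000})
    got = out.data.loc[out.data["midpoint"] == centre, "enrichment"].iloc[0]
    assert got == pytest.approx(0.0)


def test_fourc_monotone_in_small_window_sum():
    rng = np.random.default_rng(3)
    pos = np.arange(0, 2_000_001, 2000)
    base = (rng.random(len(pos)) < 0.5).astype(int)
    richer = base.copy()
    centre = 1_000_000
    richer[np.abs(pos - centre) <= 20_000] = 1
    e0 = fourc_enrichment(FourCTrack(pd.DataFrame({"chrom": "X", "midpoint": pos, "v": base})), {"X": 2_000_000})
    e1 = fourc_enrichment(FourCTrack(pd.DataFrame({"chrom": "X", "midpoint": pos, "v": richer})), {"X": 2_000_000})
    a = e0.data.loc[e0.data["midpoint"] == centre, "enrichment"].iloc[0]
    b = e1.data.loc[e1.data["midpoint"] == centre, "enrichment"].iloc[0]
    assert b >= a


def test_binarize_merges_replicates():
    df = pd.DataFrame({"chrom": ["X"] * 3, "midpoint": [0, 1000, 2000],
                       "r1": [0, 2, 0], "r2": [0, 0, 1]})
    out = binarize_fragments(df, ["r1", "r2"])
    assert out["v"].tolist() == [0, 1, 1]


def test_fourc_boundary_summary_flat_and_single():
    n_bins = 600
    pos = np.arange(0, n_bins * BS, 1000)
    frags = FourCTrack(pd.DataFrame({"chrom": "X", "midpoint": pos, "v": 1}))
    tr = fourc_enrichment(frags, {"X": n_bins * BS})
    b = bset([300], n_bins=n_bins)
    out = fourc_boundary_summary(tr, b, {"cls": np.array([300])}, "X", half=35_000)
    offsets, meta, scalar = out["cls"]
    const = np.log10(1 + 41 / 1201)
    assert np.allclose(meta, const, atol=1e-6)
    assert scalar == pytest.approx(const, abs=1e-6)


def test_tss_assignment_rules():
    b = bset([100, 200])
    jc0 = 101 * BS  # 353500
    tss = FeatureTrack("tss", pd.DataFrame({
        "chrom": ["X"] * 4,
        "pos": [jc0 - 5000, jc0 + 6000, jc0 + 12_000, 201 * BS + 2000],
        "gene": ["g5k", "g6k", "g12k", "gB"],
        "active": [True, True, True, False],
    }))
    out = assign_tss_to_boundaries(tss, b, "X", max_dist=10_000)
    # nearest gene per boundary wins; >=10 kb dropped; inactive dropped last
    assert out["gene"].tolist() == ["g5k"]
    assert (out["distance"] < 10_000).all()
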