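"""Directionality index, LSD boundary calling, comparison, insulation."""

import numpy as np
import pandas as pd
import pytest

from hicarch import (
    BoundarySet,
    GenomeModel,
    SimSpec,
    call_domains,
    compare_boundary_sets,
    delta_di,
    directionality_index,
    ice_balance,
    insulation_score,
    make_boundary_regions,
    simulate_contact_map,
)
from hicarch.lsd import DITrack, _fences

from conftest import dense_to_matrix


BS = 3500


def genome(n):
    return GenomeModel([("A", n * BS, 2)], BS)


def test_di_zero_when_symmetric_and_hand_value():
    n = 9
    w = np.zeros((n, n))
    i = 4
    w[i, i - 1] = w[i - 1, i] = 10.0
    w[i, i + 1] = w[i + 1, i] = 20.0
    m = dense_to_matrix(genome(n), "A", w)
    di = directionality_index(m, window_n=1)["A"]
    # A=10, B=20, E=15: DI = +((10-15)^2 + (20-15)^2)/15 = 10/3
    assert di.di[i] == pytest.approx(10 / 3)
    w[i, i + 1] = w[i + 1, i] = 10.0
    di2 = directionality_index(dense_to_matrix(genome(n), "A", w), 1)["A"]
    assert di2.di[i] == 0.0


def test_di_antisymmetric_under_reflection():
    n = 30
    rng = np.random.default_rng(2)
    w = np.triu(rng.random((n, n)), 2)
    w = w + w.T
    m = directionality_index(dense_to_matrix(genome(n), "A", w), 5)["A"]
    r = directionality_index(dense_to_matrix(genome(n), "A", w[::-1, ::-1]), 5)["A"]
    fin = np.isfinite(m.di) & np.isfinite(r.di[::-1])
    assert np.allclose(m.di[fin], -r.di[::-1][fin])


def test_delta_di_identities():
    di = DITrack("A", np.array([0.0, 5.0, 0.0, 2.0]), 1)
    dd = delta_di(di)
    assert dd.forward[1] == 5.0
    assert dd.backward[1] == 5.0
    # forward_i = -(backward_{i+1})
    fin = np.isfinite(dd.forward[:-1])
    assert np.allclose(dd.forward[:-1][fin], -dd.backward[1:][fin])
    const = delta_di(DITrack("A", np.full(6, 2.5), 1))
    assert np.all(const.forward[np.isfinite(const.forward)] == 0)


def two_block_matrix(n, k, high=5.0, low=0.5):
    """Two domains separated after bin k, power-law decay inside."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 2, n):
            base = (j - i) ** -1.0
            w[i, j] = base * (high if (j <= k or i > k) else low)
    return w + w.T


def test_two_block_matrix_boundary_called_near_junction():
    n, k = 60, 29
    m = dense_to_matrix(genome(n), "A", two_block_matrix(n, k))
    b = call_domains(m, window_n=5, local_m=10)["A"]
    ends = b.ends
    starts = b.starts
    assert any(abs(e - k) <= 1 for e in ends)
    assert any(k <= s <= k + 2 for s in starts)


def test_uniform_matrix_calls_no_boundaries():
    n = 40
    w = np.full((n, n), 2.0)
    for d in range(2):
        idx = np.arange(n - d)
        w[idx, idx + d] = 0
        w[idx + d, idx] = 0
    b = call_domains(dense_to_matrix(genome(n), "A", w), window_n=5, local_m=10)["A"]
    assert len(b.starts) == 0 and len(b.ends) == 0


def test_calls_match_per_bin_brute_force_oracle():
    n = 80
    rng = np.random.default_rng(9)
    w = np.triu(rng.random((n, n)) ** 3, 2)
    w = w + w.T
    m = dense_to_matrix(genome(n), "A", w)
    window_n, local_m = 5, 10
    got = call_domains(m, window_n=window_n, local_m=local_m)["A"]

    # independent per-bin re-implementation of the fence conditions
    di = directionality_index(m, window_n)["A"].di
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    fwd[:-1] = di[:-1] - di[1:]
    bwd[1:] = di[1:] - di[:-1]
    starts, ends = [], []
    for i in range(n):
        if not np.isfinite(di[i]):
            continue
        win = slice(max(0, i - local_m), min(n, i + local_m + 1))
        fv = fwd[win]
        fv = fv[np.isfinite(fv)]
        if np.isfinite(fwd[i]) and fv.size:
            q25, q75 = np.percentile(fv, [25, 75])
            fence = q25 - 1.5 * (q75 - q25)
            cond = fwd[i] <= fence and fwd[i] <= di[i]
            if q75 - q25 == 0:
                cond = cond and fwd[i] < 0
            if cond:
                starts.append(i)
        bv = bwd[win]
        bv = bv[np.isfinite(bv)]
        if np.isfinite(bwd[i]) and bv.size:
            q25, q75 = np.percentile(bv, [25, 75])
            fence = q75 + 1.5 * (q75 - q25)
            cond = bwd[i] >= fence and bwd[i] >= di[i]
            if q75 - q25 == 0:
                cond = cond and bwd[i] > 0
            if cond:
                ends.append(i)
    assert got.starts.tolist() == starts
    assert got.ends.tolist() == ends


def test_calls_invariant_to_global_rescaling():
    n = 60
    rng = np.random.default_rng(4)
    w = np.triu(rng.random((n, n)), 2)
    w = w + w.T
    a = call_domains(dense_to_matrix(genome(n), "A", w), 5, 10)["A"]
    b = call_domains(dense_to_matrix(genome(n), "A", 271.8 * w), 5, 10)["A"]
    assert np.array_equal(a.starts, b.starts)
    assert np.array_equal(a.ends, b.ends)


def test_strict_gating():
    n = 60
    rng = np.random.default_rng(4)
    w = np.triu(rng.random((n, n)), 2)
    w = w + w.T
    m = dense_to_matrix(genome(n), "A", w)
    loose = call_domains(m, 5, 10, strict=False)["A"]
    strict = call_domains(m, 5, 10, strict=True)["A"]
    di = directionality_index(m, 5)["A"].di
    assert set(strict.starts) <= set(loose.starts)
    assert all(di[s] <= 0 for s in strict.starts)
    assert all(di[e] >= 0 for e in strict.ends)


def test_boundary_regions_coordinates():
    b = BoundarySet("A", BS, 100, np.array([], dtype=int), np.array([40, 40, 70]))
    reg = make_boundary_regions(b)
    assert len(reg) == 2  # duplicates collapse
    first = reg.iloc[0]
    centre = 41 * BS
    assert (first["start"], first["end"]) == (centre - BS // 2, centre + BS - BS // 2)
    empty = make_boundary_regions(BoundarySet("A", BS, 100, np.array([], dtype=int), np.array([], dtype=int)))
    assert len(empty) == 0


def test_compare_boundary_sets_classes_partition_union():
    f = BoundarySet("A", BS, 200, np.array([], dtype=int), np.array([10, 50, 90]))
    m = BoundarySet("A", BS, 200, np.array([], dtype=int), np.array([10, 90, 120]))
    r = compare_boundary_sets(f, m)
    assert r.same.tolist() == [10, 90]
    assert r.disappearing.tolist() == [50]
    assert r.appearing.tolist() == [120]
    assert r.non_matching_fraction == pytest.approx(0.5)
    union = set(f.junctions) | set(m.junctions)
    parts = set(r.same) | set(r.appearing) | set(r.disappearing)
    assert parts == union
    assert len(r.same) + len(r.appearing) + len(r.disappearing) == len(union)
    ident = compare_boundary_sets(f, f)
    assert ident.non_matching_fraction == 0.0
    disjoint = compare_boundary_sets(
        f, BoundarySet("A", BS, 200, np.array([], dtype=int), np.array([20, 60]))
    )
    assert disjoint.non_matching_fraction == 1.0
    with pytest.raises(ValueError, match="bin size"):
        compare_boundary_sets(f, BoundarySet("A", 7000, 200, np.array([], dtype=int), np.array([10])))


def test_insulation_uniform_matrix_is_one():
    n = 50
    w = np.full((n, n), 3.0)
    per_bin, _ = insulation_score(dense_to_matrix(genome(n), "A", w), window=10)
    scored = np.isfinite(per_bin["A"])
    assert scored.sum() == n - 20
    assert np.allclose(per_bin["A"][scored], 1.0)


def test_insulation_matches_dense_brute_force():
    n = 50
    rng = np.random.default_rng(6)
    w = np.triu(rng.random((n, n)), 1)
    w = w + w.T
    m = dense_to_matrix(genome(n), "A", w)
    window = 10
    per_bin, _ = insulation_score(m, window=window)
    dense = m.cis_dense("A")
    raw = np.full(n, np.nan)
    for i in range(window, n - window):
        raw[i] = dense[i - window:i, i + 1:i + window + 1].mean()
    norm = raw / np.nanmean(raw)
    fin = np.isfinite(norm)
    assert np.allclose(per_bin["A"][fin], norm[fin], atol=1e-9, rtol=0)


def test_insulation_minimum_at_planted_boundary():
    g = genome(80)
    spec = SimSpec(genome=g, decay_exponent=-1.0,
                   tad_boundaries={"A": [(39, 0.8)]}, intra_tad_boost=2.0,
                   coverage=80 * 300, seed=2)
    m, _ = simulate_contact_map(spec)
    bal = ice_balance(m)
    per_bin, per_boundary = insulation_score(
        bal, window=10,
        boundaries={"A": BoundarySet("A", BS, 80, np.array([], dtype=int), np.array([39]))},
    )
    s = per_bin["A"]
    centre = np.nanargmin(s)
    assert abs(centre - 39.5) <= 2
    assert per_boundary["A"][0] < np.nanmean(s)


def test_weakened_boundary_is_classified_disappearing():
    import hicarch as h

    bs = 3500
    n = 140
    g = GenomeModel([("X", n * bs, 2)], bs)
    juncs = [12, 25, 38, 51, 64, 77, 90, 103, 116, 127]
    spec = h.SimSpec(genome=g, decay_exponent=-1.0,
                     tad_boundaries={"X": [(j, 0.8) for j in juncs]},
                     intra_tad_boost=2.0, coverage=600 * n, seed=3)
    weakened_idx = 4  # junction 64
    (fm, _), (mm, _) = h.simulate_sex_pair(spec, weakened=[weakened_idx],
                                           delta_exponent=0.0, seed=3, chrx="X")
    female = call_domains(ice_balance(fm))["X"]
    male = call_domains(ice_balance(mm))["X"]
    r = compare_boundary_sets(female, male)
    gone = juncs[weakened_idx]
    assert any(abs(d - gone) <= 1 for d in r.disappearing)
    assert not any(abs(s - gone) <= 1 for s in r.same)
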