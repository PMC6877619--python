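"""Iterative-correction balancing, contact-frequency rescaling, downsampling.

Balancing equalizes per-bin marginals under a factorizable-bias model
(``balanced = raw / (bias_i * bias_j)``). It is run either per chromosome on
cis blocks only, or genome-wide on the full matrix including trans blocks.
Before balancing the first ``ignore_diags`` cis diagonals are zeroed and
bins whose marginal falls below ``min_marginal`` are masked out entirely.
Convergence is declared when the relative spread ``(max - min) / mean`` of
unmasked marginals drops to ``tol`` (checked before each update, so an
already-balanced matrix is a fixed point).
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import ContactMatrix

DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    pass


def _marginal_spread(marg: np.ndarray, unmasked: np.ndarray) -> float:
    m = marg[unmasked]
    if m.size == 0 or m.mean() == 0:
        return 0.0
    return float((m.max() - m.min()) / m.mean())


def _ice_dense(
    w: np.ndarray,
    min_marginal: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance one dense symmetric block (excluded diagonals already zeroed).

    Returns (balanced, bias, masked). Masked rows/columns are zeroed and
    their bias is NaN.
    """
    w = w.astype(float).copy()
    marg0 = w.sum(axis=1)
    masked = marg0 < min_marginal
    w[masked, :] = 0.0
    w[:, masked] = 0.0
    n = w.shape[0]
    bias = np.ones(n)
    unmasked = ~masked
    if not unmasked.any():
        warnings.warn("all bins masked; empty balanced block", stacklevel=3)
        bias[:] = np.nan
        return w, bias, masked

    spread = np.inf
    for _ in range(max_iter):
        marg = w.sum(axis=1)
        spread = _marginal_spread(marg, unmasked)
        if spread <= tol:
            break
        s = marg.copy()
        s[unmasked] = s[unmasked] / s[unmasked].mean()
        s[masked | (s == 0)] = 1.0
        w /= s[:, None]
        w /= s[None, :]
        bias *= s
    else:
        raise ConvergenceError(
            f"iterative correction did not converge in {max_iter} iterations "
            f"(last spread {spread:.3g} > tol {tol:g})"
        )
    bias[masked] = np.nan
    return w, bias, masked


def _zero_cis_diags(w: np.ndarray, rows: slice, ignore_diags: int) -> None:
    """Zero cis diagonals 0..ignore_diags-1 of a square sub-block in place."""
    n = rows.stop - rows.start
    sub = w[rows, rows]
    for d in range(ignore_diags):
        idx = np.arange(n - d)
        sub[idx, idx + d] = 0.0
        sub[idx + d, idx] = 0.0
    w[rows, rows] = sub


def ice_balance(
    m: ContactMatrix,
    scope: str = "chromosome",
    min_marginal: float = 40,
    ignore_diags: int = 2,
    tol: float = 1e-2,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ContactMatrix:
    """Iterative correction of a raw-count matrix.

    ``scope="chromosome"`` balances each chromosome's cis block separately
    (trans entries are dropped from the output); ``scope="genome"`` balances
    the full genome-wide matrix including trans blocks. The first
    ``ignore_diags`` cis diagonals are excluded before balancing in both
    scopes.
    """
    if m.kind != "raw":
        raise ValueError("ice_balance expects a raw-count matrix")
    if scope not in ("chromosome", "genome"):
        raise ValueError("scope must be 'chromosome' or 'genome'")
    g = m.genome
    bias = np.full(g.n_bins, np.nan)
    masked = np.zeros(g.n_bins, dtype=bool)
    b1_parts, b2_parts, v_parts = [], [], []

    if scope == "chromosome":
        for c in g.chrom_names:
            lo, _ = g.bin_range(c)
            w = m.cis_dense(c)
            n = w.shape[0]
            for d in range(ignore_diags):
                idx = np.arange(n - d)
                w[idx, idx + d] = 0.0
                w[idx + d, idx] = 0.0
            bal, bi, mk = _ice_dense(w, min_marginal, tol, max_iter)
            bias[lo : lo + n] = bi
            masked[lo : lo + n] = mk
            iu, ju = np.triu_indices(n)
            nz = bal[iu, ju] != 0
            b1_parts.append(iu[nz] + lo)
            b2_parts.append(ju[nz] + lo)
            v_parts.append(bal[iu, ju][nz])
    else:
        n = g.n_bins
        w = np.zeros((n, n))
        vv = np.where(np.isfinite(m.value), m.value, 0.0)
        w[m.bin1, m.bin2] = vv
        w[m.bin2, m.bin1] = vv
        for c in g.chrom_names:
            lo, hi = g.bin_range(c)
            _zero_cis_diags(w, slice(lo, hi), ignore_diags)
        bal, bias, masked = _ice_dense(w, min_marginal, tol, max_iter)
        iu, ju = np.triu_indices(n)
        nz = bal[iu, ju] != 0
        b1_parts.append(iu[nz])
        b2_parts.append(ju[nz])
        v_parts.append(bal[iu, ju][nz])

    return ContactMatrix(
        g,
        np.concatenate(b1_parts) if b1_parts else [],
        np.concatenate(b2_parts) if b2_parts else [],
        np.concatenate(v_parts) if v_parts else [],
        kind="balanced",
        bias=bias,
        masked=masked,
    )


def to_contact_frequency(m: ContactMatrix) -> ContactMatrix:
    """Rescale a balanced matrix to contact frequencies.

    Every cis entry is divided by the median balanced value at distance
    exactly 2 bins of its own chromosome (computed over the full diagonal,
    structurally absent cells counted as 0), anchoring the contact
    probability scale at the first informative diagonal.
    """
    if m.kind != "balanced":
        raise ValueError("to_contact_frequency expects a balanced matrix")
    g = m.genome
    value = m.value.copy()
    c1 = g.chrom_of_bins(m.bin1)
    c2 = g.chrom_of_bins(m.bin2)
    for ci, c in enumerate(g.chrom_names):
        n = g.n_bins_of(c)
        if n < 3:
            raise ValueError(f"chromosome {c!r}: no distance-2 diagonal")
        med = float(np.median(np.diagonal(m.cis_dense(c), 2)))
        if not np.isfinite(med) or med <= 0:
            raise ValueError(f"chromosome {c!r}: distance-2 median is zero or undefined")
        sel = (c1 == ci) & (c2 == ci)
        value[sel] = value[sel] / med
    return m._replace(value=value, kind="frequency")


def downsample_binomial(m: ContactMatrix, p: float = 0.5, seed: int = 0) -> ContactMatrix:
    """Binomially thin every count with probability ``p`` (reproducible by seed)."""
    if m.kind != "raw":
        raise ValueError("downsample_binomial expects a raw-count matrix")
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    new = rng.binomial(m.value.astype(np.int64), p).astype(np.float64)
    return m._replace(value=new)


def downsample_matched_cis(target: ContactMatrix, reference: ContactMatrix, seed: int = 0) -> ContactMatrix:
    """Thin each chromosome's cis counts to match the reference cis totals.

    Per chromosome, target cis entries are binomially thinned with
    ``p = reference_cis_total / target_cis_total``; chromosomes where the
    ratio is >= 1 are left unchanged. Trans entries are untouched.
    """
    if target.kind != "raw" or reference.kind != "raw":
        raise ValueError("downsample_matched_cis expects raw-count matrices")
    t_names = target.genome.chrom_names
    for c in t_names:
        if c not in reference.genome.chrom_names:
            raise ValueError(f"chromosome {c!r} missing from reference")
    rng = np.random.default_rng(seed)
    value = target.value.copy()
    c1 = target.genome.chrom_of_bins(target.bin1)
    c2 = target.genome.chrom_of_bins(target.bin2)
    for ci, c in enumerate(t_names):
        t_tot = target.cis_total(c)
        if t_tot == 0:
            continue
        ratio = reference.cis_total(c) / t_tot
        if ratio >= 1:
            continue
        sel = (c1 == ci) & (c2 == ci)
        value[sel] = rng.binomial(value[sel].astype(np.int64), ratio)
    return target._replace(value=value)
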