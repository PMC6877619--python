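"""Cis/trans contact accounting and the trans-propensity null model.

The null model distributes the trans contacts originating from any
chromosome uniformly over the other (target) chromosomes in proportion to
the target's length times its copy number:

    E(a, b) = (c_b * l_b) / sum_{b' != a} (c_b' * l_b') * T_a

where ``T_a`` is the observed total of trans pairs involving chromosome
``a``. The propensity table is the log2 ratio of observed over expected;
it is not expected to be symmetric because the normalization differs per
origin. Each read pair is counted once per involved chromosome, so the
observed count table is symmetric while the expectations are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .matrix import ContactMatrix


@dataclass
class TransTable:
    counts: pd.DataFrame  # symmetric chromosome x chromosome trans counts, NaN diagonal
    cis_totals: pd.Series

    @classmethod
    def from_matrix(cls, m: ContactMatrix) -> "TransTable":
        g = m.genome
        names = g.chrom_names
        k = len(names)
        c1 = g.chrom_of_bins(m.bin1)
        c2 = g.chrom_of_bins(m.bin2)
        counts = np.zeros((k, k))
        np.add.at(counts, (c1, c2), m.value)
        counts = counts + counts.T - np.diag(np.diag(counts))
        cis = pd.Series(np.diag(counts).copy(), index=names, dtype=float)
        np.fill_diagonal(counts, np.nan)
        return cls(pd.DataFrame(counts, index=names, columns=names), cis)

    def trans_totals(self) -> pd.Series:
        """Total trans pairs involving each chromosome (T_a of the null model)."""
        return self.counts.sum(axis=1, skipna=True)


@dataclass
class TransPropensity:
    log2_obs_exp: pd.DataFrame
    zero_observed: pd.DataFrame  # True where observed was 0 (-inf sentinel in the table)


def trans_cis_ratio(t: TransTable) -> pd.Series:
    """Per chromosome, trans pairs involving it divided by its cis total."""
    if (t.cis_totals <= 0).any():
        bad = t.cis_totals.index[t.cis_totals <= 0].tolist()
        raise ValueError(f"zero cis total for chromosome(s) {bad}")
    return t.trans_totals() / t.cis_totals


def expected_trans(t: TransTable, g: GenomeModel) -> pd.DataFrame:
    """Expected origin x target trans counts under the length/copy-number null."""
    names = list(t.counts.index)
    if len(names) < 2:
        raise ValueError("expected_trans needs at least 2 chromosomes")
    w = np.array([g.chromosome(c).copy_number * g.chromosome(c).length for c in names], dtype=float)
    T = t.trans_totals().to_numpy()
    exp = np.full((len(names), len(names)), np.nan)
    for ai in range(len(names)):
        denom = w.sum() - w[ai]
        for bi in range(len(names)):
            if bi != ai:
                exp[ai, bi] = w[bi] / denom * T[ai]
    return pd.DataFrame(exp, index=names, columns=names)


def trans_propensity(t: TransTable, g: GenomeModel) -> TransPropensity:
    """log2 observed/expected trans contacts per origin-target pair.

    Cells with zero observed counts are reported as -inf with a flag in
    ``zero_observed`` rather than dropped.
    """
    exp = expected_trans(t, g)
    off = ~np.eye(len(exp), dtype=bool)
    if (exp.to_numpy()[off] <= 0).any():
        raise ValueError("expected counts must be positive for all off-diagonal cells")
    obs = t.counts.to_numpy()
    with np.errstate(divide="ignore"):
        ratio = np.log2(obs / exp.to_numpy())
    zero = pd.DataFrame((obs == 0) & off, index=exp.index, columns=exp.columns)
    return TransPropensity(pd.DataFrame(ratio, index=exp.index, columns=exp.columns), zero)
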