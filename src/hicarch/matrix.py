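"""Sparse symmetric contact matrices and their text interchange formats.

A :class:`ContactMatrix` stores the upper triangle of a genome-wide
symmetric matrix as triplets ``(bin_i, bin_j, value)`` with
``bin_i <= bin_j``; queries are symmetric. ``kind`` tracks the processing
stage: ``"raw"`` (integer counts), ``"balanced"`` (after iterative
correction) or ``"frequency"`` (balanced values rescaled so the median at
2-bin distance is 1 per chromosome).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel

KINDS = ("raw", "balanced", "frequency")


class ContactMatrix:
    def __init__(
        self,
        genome: GenomeModel,
        bin1,
        bin2,
        value,
        kind: str = "raw",
        bias: np.ndarray | None = None,
        masked: np.ndarray | None = None,
    ):
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        value = np.asarray(value, dtype=np.float64)
        if not (bin1.shape == bin2.shape == value.shape):
            raise ValueError("bin1, bin2, value must have equal length")
        bad = (bin1 < 0) | (bin1 >= genome.n_bins) | (bin2 < 0) | (bin2 >= genome.n_bins)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {k}: bin id ({bin1[k]}, {bin2[k]}) outside the "
                f"{genome.n_bins}-bin table"
            )
        if kind == "raw":
            if (value < 0).any():
                k = int(np.flatnonzero(value < 0)[0])
                raise ValueError(f"record {k}: negative count {value[k]}")
        # mirror into the upper triangle and sum duplicates
        lo = np.minimum(bin1, bin2)
        hi = np.maximum(bin1, bin2)
        key = lo * genome.n_bins + hi
        order = np.argsort(key, kind="stable")
        key, lo, hi, value = key[order], lo[order], hi[order], value[order]
        uniq, start = np.unique(key, return_index=True)
        sums = np.add.reduceat(value, start) if len(value) else value
        self.genome = genome
        self.bin1 = lo[start] if len(lo) else lo
        self.bin2 = hi[start] if len(hi) else hi
        self.value = sums
        self.kind = kind
        self.bias = None if bias is None else np.asarray(bias, dtype=np.float64)
        self.masked = (
            np.zeros(genome.n_bins, dtype=bool) if masked is None else np.asarray(masked, dtype=bool)
        )

    # -- construction ------------------------------------------------------
    def _replace(self, value=None, kind=None, bias=None, masked=None) -> "ContactMatrix":
        return ContactMatrix(
            self.genome,
            self.bin1,
            self.bin2,
            self.value if value is None else value,
            kind=self.kind if kind is None else kind,
            bias=self.bias if bias is None else bias,
            masked=self.masked if masked is None else masked,
        )

    # -- accessors ---------------------------------------------------------
    def cis_mask(self) -> np.ndarray:
        c1 = self.genome.chrom_of_bins(self.bin1)
        c2 = self.genome.chrom_of_bins(self.bin2)
        return c1 == c2

    def cis_entries(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cis triplets of one chromosome in local (chromosome) bin indices."""
        lo, hi = self.genome.bin_range(chrom)
        m = (self.bin1 >= lo) & (self.bin1 < hi) & (self.bin2 >= lo) & (self.bin2 < hi)
        return self.bin1[m] - lo, self.bin2[m] - lo, self.value[m]

    def cis_dense(self, chrom: str) -> np.ndarray:
        """Dense symmetric cis block; non-finite values are set to 0."""
        n = self.genome.n_bins_of(chrom)
        i, j, v = self.cis_entries(chrom)
        d = np.zeros((n, n))
        v = np.where(np.isfinite(v), v, 0.0)
        d[i, j] = v
        d[j, i] = v
        return d

    def cis_total(self, chrom: str) -> float:
        """Total cis value of a chromosome (each unordered pair counted once)."""
        _, _, v = self.cis_entries(chrom)
        return float(np.nansum(v))

    def total(self) -> float:
        return float(np.nansum(self.value))

    def value_at(self, i: int, j: int) -> float:
        lo, hi = min(i, j), max(i, j)
        m = (self.bin1 == lo) & (self.bin2 == hi)
        return float(self.value[m].sum()) if m.any() else 0.0

    # -- I/O ---------------------------------------------------------------
    def write_triplets(self, path) -> None:
        pd.DataFrame({"bin1_id": self.bin1, "bin2_id": self.bin2, "value": self.value}).to_csv(
            path, sep="\t", header=False, index=False
        )

    def write_bias(self, path) -> None:
        if self.bias is None:
            raise ValueError("matrix has no bias vector")
        pd.DataFrame({"bin_id": np.arange(self.genome.n_bins), "bias": self.bias}).to_csv(
            path, sep="\t", header=False, index=False
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ContactMatrix(kind={self.kind!r}, nnz={len(self.value)}, n_bins={self.genome.n_bins})"


def read_contacts(path, bins_path, copy_numbers: dict[str, int] | None = None, kind: str = "raw") -> ContactMatrix:
    """Read a triplet TSV (bin1_id, bin2_id, value) against a BED4 bin table.

    Lower-triangle records are mirrored into the upper triangle and summed
    with duplicates. Non-finite values of balanced/frequency inputs are set
    to 0; a negative raw count or an out-of-table bin id is an error.
    """
    genome = GenomeModel.read_bins(bins_path, copy_numbers)
    try:
        trip = pd.read_csv(path, sep="\t", header=None, names=["bin1", "bin2", "value"])
    except pd.errors.EmptyDataError:
        trip = pd.DataFrame({"bin1": [], "bin2": [], "value": []})
    v = trip["value"].to_numpy(dtype=np.float64)
    if kind != "raw":
        v = np.where(np.isfinite(v), v, 0.0)
    return ContactMatrix(genome, trip["bin1"].to_numpy(), trip["bin2"].to_numpy(), v, kind=kind)
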