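"""Genome model: chromosomes, copy numbers, and the dense bin table.

All coordinates are 0-based half-open (BED convention). Bins tile each
chromosome left to right; the last bin of a chromosome may be shorter than
``bin_size``. Bin ids are dense and global across the genome, in chromosome
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Chromosome:
    """One chromosome (or chromosome arm) with its expected copy number."""

    name: str
    length: int
    copy_number: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be positive")
        if self.copy_number < 1:
            raise ValueError(f"chromosome {self.name!r}: copy_number must be >= 1")


class GenomeModel:
    """Ordered chromosomes plus a dense genome-wide bin table.

    Parameters
    ----------
    chromosomes
        Iterable of ``Chromosome`` or ``(name, length_bp, copy_number)``
        tuples (copy number defaults to 2 when omitted).
    bin_size
        Bin width in bp.
    """

    def __init__(self, chromosomes, bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        chroms: list[Chromosome] = []
        for c in chromosomes:
            if isinstance(c, Chromosome):
                chroms.append(c)
            else:
                chroms.append(Chromosome(*c))
        if not chroms:
            raise ValueError("genome needs at least one chromosome")
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes: tuple[Chromosome, ...] = tuple(chroms)
        self.bin_size = int(bin_size)

        self._offset: dict[str, int] = {}
        self._nbins: dict[str, int] = {}
        rows = []
        bid = 0
        for c in self.chromosomes:
            n = -(-c.length // self.bin_size)  # ceil division
            self._offset[c.name] = bid
            self._nbins[c.name] = n
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, c.length)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c.name,
                        "start": starts,
                        "end": ends,
                        "bin_id": np.arange(bid, bid + n, dtype=np.int64),
                    }
                )
            )
            bid += n
        self.bins: pd.DataFrame = pd.concat(rows, ignore_index=True)
        self.n_bins = bid

    # -- lookups -----------------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def offset(self, name: str) -> int:
        """First global bin id of a chromosome."""
        return self._offset[name]

    def n_bins_of(self, name: str) -> int:
        return self._nbins[name]

    def bin_range(self, name: str) -> tuple[int, int]:
        """Half-open global bin-id range [lo, hi) of a chromosome."""
        lo = self._offset[name]
        return lo, lo + self._nbins[name]

    def chrom_of_bins(self, bin_ids: np.ndarray) -> np.ndarray:
        """Chromosome index (position in ``chromosomes``) per global bin id."""
        edges = np.array([self._offset[c.name] for c in self.chromosomes[1:]])
        return np.searchsorted(edges, np.asarray(bin_ids), side="right")

    # -- I/O ---------------------------------------------------------------
    def write_bins(self, path) -> None:
        """Write the BED4 bin table (chrom, start, end, bin_id)."""
        self.bins.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bins_table(cls, bins: pd.DataFrame, copy_numbers: dict[str, int] | None = None) -> "GenomeModel":
        """Reconstruct a genome from a BED4 bin table.

        Chromosome lengths are taken from the last bin end; the bin size
        from the modal bin width. Copy numbers default to 2 unless given.
        """
        copy_numbers = copy_numbers or {}
        widths = (bins["end"] - bins["start"]).to_numpy()
        bin_size = int(np.bincount(widths).argmax())
        chroms = []
        for name, grp in bins.groupby("chrom", sort=False):
            chroms.append(Chromosome(str(name), int(grp["end"].max()), copy_numbers.get(str(name), 2)))
        g = cls(chroms, bin_size)
        if g.n_bins != len(bins):
            raise ValueError("bin table does not tile the inferred genome")
        return g

    @classmethod
    def read_bins(cls, path, copy_numbers: dict[str, int] | None = None) -> "GenomeModel":
        bins = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "bin_id"])
        return cls.from_bins_table(bins, copy_numbers)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeModel({len(self.chromosomes)} chromosomes, bin_size={self.bin_size}, n_bins={self.n_bins})"
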