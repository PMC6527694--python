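"""Array-backed container for sequenced fragments.

A sample easily carries 10^5–10^8 fragments; per-object intervals are too
slow for that, so fragments are held as parallel numpy arrays with a small
chromosome-name table. Conversion to/from :class:`~atacatlas.io.GenomicInterval`
lists and BED text is provided at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

from .io import GenomicInterval, ValidationError


@dataclass
class FragmentSet:
    """Fragments as parallel arrays: ``chrom_names[chrom_codes[i]]`` spans
    ``[starts[i], ends[i])`` in 0-based half-open coordinates."""

    chrom_names: tuple[str, ...]
    chrom_codes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chrom_codes)
        if not (len(self.starts) == len(self.ends) == n):
            raise ValidationError("fragment arrays must have equal length")
        if n and (self.starts >= self.ends).any():
            raise ValidationError("fragments require start < end")
        if n and ((self.chrom_codes < 0) | (self.chrom_codes >= len(self.chrom_names))).any():
            raise ValidationError("chromosome code out of range")

    def __len__(self) -> int:
        return len(self.starts)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def sorted(self) -> "FragmentSet":
        order = np.lexsort((self.ends, self.starts, self.chrom_codes))
        return FragmentSet(
            self.chrom_names,
            self.chrom_codes[order],
            self.starts[order],
            self.ends[order],
        )

    def per_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield ``(chrom, starts, ends)`` per chromosome, in name-table order."""
        for code, name in enumerate(self.chrom_names):
            mask = self.chrom_codes == code
            if mask.any():
                yield name, self.starts[mask], self.ends[mask]

    def to_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom_names[c], int(s), int(e))
            for c, s, e in zip(self.chrom_codes, self.starts, self.ends)
        ]

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "FragmentSet":
        intervals = list(intervals)
        names: list[str] = []
        index: dict[str, int] = {}
        codes = np.empty(len(intervals), dtype=np.int32)
        starts = np.empty(len(intervals), dtype=np.int64)
        ends = np.empty(len(intervals), dtype=np.int64)
        for i, iv in enumerate(intervals):
            if iv.chrom not in index:
                index[iv.chrom] = len(names)
                names.append(iv.chrom)
            codes[i] = index[iv.chrom]
            starts[i] = iv.start
            ends[i] = iv.end
        return cls(tuple(names), codes, starts, ends)

    @classmethod
    def read_bed(cls, path: str | Path) -> "FragmentSet":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        names = tuple(dict.fromkeys(df["chrom"]))
        index = {n: i for i, n in enumerate(names)}
        codes = df["chrom"].map(index).to_numpy(dtype=np.int32)
        return cls(names, codes, df["start"].to_numpy(), df["end"].to_numpy())

    def write_bed(self, path: str | Path) -> None:
        chroms = np.asarray(self.chrom_names, dtype=object)[self.chrom_codes]
        pd.DataFrame({"chrom": chroms, "start": self.starts, "end": self.ends}).to_csv(
            path, sep="\t", header=False, index=False
        )


Fragments = Union[FragmentSet, Sequence[GenomicInterval]]


def as_fragment_set(fragments: Fragments) -> FragmentSet:
    if isinstance(fragments, FragmentSet):
        return fragments
    return FragmentSet.from_intervals(fragments)
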