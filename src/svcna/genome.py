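"""Genome layout, interval arithmetic, 1-Mb binning and callability masks.

All internal coordinates are 0-based half-open. BED-style inputs are read
natively; 1-based inclusive segment tables are converted at the I/O layer.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 1_000_000


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals; output sorted by (chrom, start)."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


@dataclass
class GenomeLayout:
    """Chromosome names/lengths, arm boundaries and an uncallable-region mask."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    arm_boundaries: dict[str, int] = field(default_factory=dict)
    mask: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chrom_names:
            raise ValueError("empty genome layout")
        for c in self.chrom_names:
            if self.chrom_lengths.get(c, 0) <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        for c, b in self.arm_boundaries.items():
            if not (0 < b < self.chrom_lengths[c]):
                raise ValueError(f"arm boundary of {c} outside (0, length)")
        for iv in self.mask:
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"mask interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(f"mask interval {iv} beyond chromosome end")
        self.mask = merge_intervals(self.mask) if self.mask else []
        self._mask_by_chrom: dict[str, np.ndarray] = {}
        for iv in self.mask:
            arr = self._mask_by_chrom.setdefault(iv.chrom, np.empty((0, 2), int))
            self._mask_by_chrom[iv.chrom] = np.vstack([arr, [iv.start, iv.end]])

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def chrom_index(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)

    def in_mask(self, chrom: str, pos: int) -> bool:
        ivs = self._mask_by_chrom.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        return i >= 0 and pos < ivs[i, 1]

    def positions_in_mask(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized mask membership for arrays of chromosome names/positions."""
        out = np.zeros(len(positions), dtype=bool)
        for chrom, ivs in self._mask_by_chrom.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            pos = positions[sel]
            i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
            hit = (i >= 0) & (pos < ivs[np.clip(i, 0, None), 1])
            out[sel] = hit
        return out

    def arms(self) -> list[tuple[str, str, Interval]]:
        """(chrom, arm_name, interval) for every defined arm."""
        out = []
        for c in self.chrom_names:
            length = self.chrom_lengths[c]
            b = self.arm_boundaries.get(c)
            if b is None:
                out.append((c, "", Interval(c, 0, length)))
            else:
                out.append((c, "p", Interval(c, 0, b)))
                out.append((c, "q", Interval(c, b, length)))
        return out

    @classmethod
    def from_chrom_sizes(
        cls,
        path: str,
        arm_boundaries: dict[str, int] | None = None,
        mask_bed: str | None = None,
    ) -> "GenomeLayout":
        """Build a layout from a two-column chrom/length TSV (FASTA-index-like)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        names = list(df["chrom"])
        lengths = dict(zip(df["chrom"], df["length"].astype(int)))
        mask = read_bed_intervals(mask_bed) if mask_bed else []
        return cls(names, lengths, arm_boundaries or {}, mask)


def read_bed_intervals(path: str) -> list[Interval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return [Interval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


@dataclass
class GenomeBin:
    """One bin of the grid: interval, covariates, callability, expected count."""

    interval: Interval
    covariates: dict[str, float] = field(default_factory=dict)
    callable: bool = True
    b_j: float | None = None


class BinGrid:
    """Ordered non-overlapping bins tiling every chromosome of a layout.

    Exposes bulk numpy views (``starts``, ``ends``, ``chrom_codes`` …) used
    by the simulation and enrichment stages; per-bin :class:`GenomeBin`
    objects remain the authoritative store.
    """

    def __init__(self, bins: list[GenomeBin], s_bin: int, layout: GenomeLayout):
        if s_bin <= 0:
            raise ValueError("s_bin must be positive")
        self.bins = bins
        self.s_bin = s_bin
        self.layout = layout
        self.chroms = np.array([b.interval.chrom for b in bins], dtype=object)
        self.chrom_codes = np.array(
            [layout.chrom_index(c) for c in self.chroms], dtype=np.int64
        )
        self.starts = np.array([b.interval.start for b in bins], dtype=np.int64)
        self.ends = np.array([b.interval.end for b in bins], dtype=np.int64)
        # first bin index of each chromosome, for O(1) position->bin lookup
        self._chrom_offset = {}
        self._chrom_nbins = {}
        for i, c in enumerate(self.chroms):
            if c not in self._chrom_offset:
                self._chrom_offset[c] = i
            self._chrom_nbins[c] = self._chrom_nbins.get(c, 0) + 1

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def callable_flags(self) -> np.ndarray:
        return np.array([b.callable for b in self.bins], dtype=bool)

    @property
    def b(self) -> np.ndarray:
        return np.array(
            [0.0 if b.b_j is None else b.b_j for b in self.bins], dtype=float
        )

    def set_b(self, values: np.ndarray) -> None:
        if len(values) != len(self.bins):
            raise ValueError("b_j vector length mismatch")
        if np.any(values < 0):
            raise ValueError("b_j must be non-negative")
        for bin_, v in zip(self.bins, values):
            bin_.b_j = float(v)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing (chrom, pos)."""
        off = self._chrom_offset[chrom]
        n = self._chrom_nbins[chrom]
        return off + min(int(pos) // self.s_bin, n - 1)

    def bin_indices(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        offs = np.array([self._chrom_offset[c] for c in chroms], dtype=np.int64)
        nb = np.array([self._chrom_nbins[c] for c in chroms], dtype=np.int64)
        return offs + np.minimum(positions // self.s_bin, nb - 1)

    def bin_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open range of bin indices overlapping [start, end)."""
        return self.bin_index(chrom, start), self.bin_index(chrom, end - 1) + 1

    def covariate_frame(self) -> pd.DataFrame:
        return pd.DataFrame([b.covariates for b in self.bins])

    def set_covariates(self, frame: pd.DataFrame) -> None:
        for bin_, (_, row) in zip(self.bins, frame.iterrows()):
            bin_.covariates = dict(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "callable": self.callable_flags,
                "b_j": self.b,
            }
        )


def build_bins(
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    mask_callable_threshold: float = 0.5,
) -> BinGrid:
    """Tile each chromosome with non-overlapping bins of ``bin_size``.

    The final bin of a chromosome may be shorter. A bin whose overlap with
    the layout mask exceeds ``mask_callable_threshold`` (fraction of bin
    width) is flagged not callable.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[GenomeBin] = []
    for chrom in layout.chrom_names:
        length = layout.chrom_lengths[chrom]
        mask_ivs = [iv for iv in layout.mask if iv.chrom == chrom]
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            iv = Interval(chrom, start, end)
            masked = sum(iv.overlap_length(m) for m in mask_ivs)
            callable_ = masked <= mask_callable_threshold * iv.length
            bins.append(GenomeBin(interval=iv, callable=callable_))
    return BinGrid(bins, bin_size, layout)


def apply_mask(grid: BinGrid, mask: list[Interval],
               mask_callable_threshold: float = 0.5) -> BinGrid:
    """Re-evaluate callability of an existing grid against ``mask``.

    Idempotent: applying the same mask twice leaves the grid unchanged.
    """
    merged = merge_intervals(list(mask))
    for b in grid.bins:
        masked = sum(b.interval.overlap_length(m) for m in merged
                     if m.chrom == b.interval.chrom)
        if masked > mask_callable_threshold * b.interval.length:
            b.callable = False
    return grid
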