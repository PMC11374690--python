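"""Count- and length-preserving null simulation of SV catalogues.

Each observed SV is re-placed by sampling a bin with probability
proportional to the expected breakend surface b_j, placing the first
breakend uniformly within the bin, and then placing the partner at the
observed distance (direction by fair coin) for intrachromosomal SVs, or
in a b_j-weighted bin on another chromosome for interchromosomal SVs.
SVs whose breakends land in the mask or off-chromosome are redrawn whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import Breakend, Rearrangement
from .genome import BinGrid, GenomeLayout

MAX_REJECTIONS = 10_000


@dataclass
class SimulatedCatalog:
    replicate_id: int
    seed: int
    svs: list[Rearrangement]


@dataclass
class SimulatedPositions:
    """Array representation of one simulated replicate (fast path)."""

    replicate_id: int
    chrom1: np.ndarray  # object array of chromosome names
    pos1: np.ndarray
    chrom2: np.ndarray
    pos2: np.ndarray
    is_intra: np.ndarray

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted breakend positions per chromosome."""
        chroms = np.concatenate([self.chrom1, self.chrom2])
        pos = np.concatenate([self.pos1, self.pos2])
        out: dict[str, np.ndarray] = {}
        for c in np.unique(chroms.astype(str)):
            out[c] = np.sort(pos[chroms.astype(str) == c])
        return out


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    )


def observed_arrays(observed: list[Rearrangement]):
    """Extract the conserved attributes of an observed catalogue."""
    is_intra = np.array([r.is_intrachromosomal for r in observed], dtype=bool)
    lengths = np.array(
        [r.length if r.is_intrachromosomal else 0 for r in observed], dtype=np.int64
    )
    return is_intra, lengths


def simulate_positions(
    is_intra: np.ndarray,
    lengths: np.ndarray,
    grid: BinGrid,
    layout: GenomeLayout,
    rng: np.random.Generator,
    replicate_id: int = 0,
) -> SimulatedPositions:
    """Simulate breakend placements for SVs described by arrays."""
    b = grid.b
    total_b = b.sum()
    if total_b <= 0:
        raise ValueError("sum of b_j must be positive")
    p = b / total_b
    n_bins = len(grid)
    chrom_names = np.array(layout.chrom_names, dtype=object)
    chrom_len = np.array(
        [layout.chrom_lengths[c] for c in layout.chrom_names], dtype=np.int64
    )
    bin_chrom_code = grid.chrom_codes
    bin_start = grid.starts
    bin_width = grid.ends - grid.starts

    # per-chromosome renormalized probabilities for interchromosomal partners
    chrom_total_b = np.zeros(len(chrom_names))
    np.add.at(chrom_total_b, bin_chrom_code, b)

    n = len(is_intra)
    if lengths[is_intra].max(initial=0) >= chrom_len.max():
        raise ValueError("an SV length exceeds every chromosome")
    out_c1 = np.empty(n, dtype=np.int64)
    out_p1 = np.empty(n, dtype=np.int64)
    out_c2 = np.empty(n, dtype=np.int64)
    out_p2 = np.empty(n, dtype=np.int64)

    pending = np.arange(n)
    attempts = 0
    while len(pending):
        attempts += 1
        if attempts > MAX_REJECTIONS:
            raise RuntimeError(
                f"{len(pending)} SVs still rejected after {MAX_REJECTIONS} rounds"
            )
        m = len(pending)
        bins1 = rng.choice(n_bins, size=m, p=p)
        c1 = bin_chrom_code[bins1]
        p1 = bin_start[bins1] + (rng.random(m) * bin_width[bins1]).astype(np.int64)
        intra = is_intra[pending]

        c2 = np.empty(m, dtype=np.int64)
        p2 = np.empty(m, dtype=np.int64)
        # intrachromosomal: partner at observed distance, fair-coin direction
        if intra.any():
            direction = np.where(rng.random(intra.sum()) < 0.5, 1, -1)
            p2[intra] = p1[intra] + direction * lengths[pending][intra]
            c2[intra] = c1[intra]
        # interchromosomal: b_j-weighted bin on another chromosome
        inter_idx = np.where(~intra)[0]
        for code in np.unique(c1[inter_idx]):
            sel = inter_idx[c1[inter_idx] == code]
            w = np.where(bin_chrom_code == code, 0.0, b)
            wsum = w.sum()
            if wsum <= 0:
                raise ValueError(
                    "no expected breakends outside chromosome "
                    f"{chrom_names[code]} for interchromosomal partner"
                )
            bins2 = rng.choice(n_bins, size=len(sel), p=w / wsum)
            c2[sel] = bin_chrom_code[bins2]
            p2[sel] = bin_start[bins2] + (
                rng.random(len(sel)) * bin_width[bins2]
            ).astype(np.int64)

        ok = (p2 >= 0) & (p2 < chrom_len[c2]) & (p1 >= 0) & (p1 < chrom_len[c1])
        if ok.any():
            masked = layout.positions_in_mask(
                np.concatenate([chrom_names[c1[ok]], chrom_names[c2[ok]]]),
                np.concatenate([p1[ok], p2[ok]]),
            )
            k = ok.sum()
            good = ~(masked[:k] | masked[k:])
            acc = np.where(ok)[0][good]
        else:
            acc = np.empty(0, dtype=np.int64)
        tgt = pending[acc]
        out_c1[tgt], out_p1[tgt] = c1[acc], p1[acc]
        out_c2[tgt], out_p2[tgt] = c2[acc], p2[acc]
        keep = np.ones(m, dtype=bool)
        keep[acc] = False
        pending = pending[keep]

    return SimulatedPositions(
        replicate_id=replicate_id,
        chrom1=chrom_names[out_c1],
        pos1=out_p1,
        chrom2=chrom_names[out_c2],
        pos2=out_p2,
        is_intra=is_intra.copy(),
    )


def simulate_catalog(
    observed: list[Rearrangement],
    grid: BinGrid,
    layout: GenomeLayout,
    seed: int,
    replicate_id: int = 0,
) -> SimulatedCatalog:
    """Simulate one replicate catalogue preserving per-SV class and length."""
    rng = _replicate_rng(seed, replicate_id)
    is_intra, lengths = observed_arrays(observed)
    pos = simulate_positions(is_intra, lengths, grid, layout, rng, replicate_id)
    svs = []
    for i, r in enumerate(observed):
        svs.append(
            Rearrangement(
                id=f"sim{replicate_id}_{i}",
                sample_id=r.sample_id,
                bnd1=Breakend(str(pos.chrom1[i]), int(pos.pos1[i]), r.bnd1.orientation),
                bnd2=Breakend(str(pos.chrom2[i]), int(pos.pos2[i]), r.bnd2.orientation),
                callers=r.callers,
            )
        )
    return SimulatedCatalog(replicate_id=replicate_id, seed=seed, svs=svs)


def run_replicates(
    observed: list[Rearrangement],
    grid: BinGrid,
    layout: GenomeLayout,
    n_reps: int = 1000,
    seed: int = 0,
) -> list[SimulatedCatalog]:
    """Independent replicates; replicate r is reproducible from (seed, r)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [
        simulate_catalog(observed, grid, layout, seed, replicate_id=r)
        for r in range(n_reps)
    ]


def run_replicate_positions(
    is_intra: np.ndarray,
    lengths: np.ndarray,
    grid: BinGrid,
    layout: GenomeLayout,
    n_reps: int,
    seed: int,
) -> list[SimulatedPositions]:
    """Fast-path replicates returning position arrays only."""
    out = []
    for r in range(n_reps):
        rng = _replicate_rng(seed, r)
        out.append(simulate_positions(is_intra, lengths, grid, layout, rng, r))
    return out
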