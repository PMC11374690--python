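"""Chromothripsis/chromoplexy calling and complex-SV enrichment.

A complex cluster (>= 3 rearrangements) is chromothripsis when it shows an
oscillating copy-number run, at least six interleaved intrachromosomal
rearrangements, and no evidence (FDR > 0.2) that its intrachromosomal join
orientations diverge from an equal-probability multinomial. It is
chromoplexy when a breakpoint chain spans >= 3 chromosomes, >= 50% of its
footprints look like balanced translocations, and it holds 3-30
rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chisquare

from .catalog import (
    DELETION_BRIDGE_TOL,
    FOOTPRINT_GAP,
    OrientationCounts,
    SvCluster,
    orientation_counts,
)
from .genome import BinGrid, GenomeBin, GenomeLayout

CHROMOPLEXY_EDGE_DIST = 1_000_000
ORIENTATION_FDR_MIN = 0.2
MIN_INTERLEAVED = 6
CHROMOPLEXY_SIZE_RANGE = (3, 30)
EXACT_MULTINOMIAL_MAX_N = 60


@dataclass
class ClusterCall:
    cluster_id: str
    call: str  # chromothripsis | chromoplexy | complex_unclassified
    oscillation_found: bool = False
    oscillation_run_length: int = 0
    oscillation_n_states: int = 0
    interleaved_count: int = 0
    orientation_fdr: float = float("nan")
    chain_chromosomes: int = 0
    balanced_footprint_fraction: float = float("nan")
    n_rearrangements: int = 0


@dataclass
class ComplexBinStat:
    bin: GenomeBin
    g_obs: int
    g_exp: float
    beta_complex: float
    fdr: float


# ---------------------------------------------------------------------------
# Chromothripsis criteria
# ---------------------------------------------------------------------------

def detect_oscillation(cn_values: list[int | float]) -> tuple[bool, int, int]:
    """Search for a copy-number oscillation run.

    Found when a contiguous run of adjacent-differing values exists with
    >= 4 segments over <= 2 distinct states, or >= 5 segments over <= 3
    distinct states. Returns (found, best run length, distinct states in
    that run).
    """
    if len(cn_values) == 0:
        raise ValueError("need at least one copy-number value")
    vals = list(cn_values)
    n = len(vals)
    best = (False, 0, 0)
    for i in range(n):
        distinct = {vals[i]}
        for j in range(i + 1, n):
            if vals[j] == vals[j - 1]:
                break
            distinct.add(vals[j])
            length = j - i + 1
            k = len(distinct)
            if (length >= 4 and k <= 2) or (length >= 5 and k <= 3):
                if length > best[1]:
                    best = (True, length, k)
    return best


def count_interleaved(cluster: SvCluster) -> int:
    """Intrachromosomal rearrangements crossing at least one other.

    Spans (a1, a2) and (b1, b2) on the same chromosome interleave when
    a1 < b1 < a2 < b2 (crossing; nested or disjoint pairs do not count).
    """
    spans_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, r in enumerate(cluster.rearrangements):
        if r.is_intrachromosomal:
            spans_by_chrom.setdefault(r.bnd1.chrom, []).append(
                (r.bnd1.pos, r.bnd2.pos, idx)
            )
    interleaved: set[int] = set()
    for spans in spans_by_chrom.values():
        for i, (a1, a2, ia) in enumerate(spans):
            for b1, b2, ib in spans[i + 1:]:
                if (a1 < b1 < a2 < b2) or (b1 < a1 < b2 < a2):
                    interleaved.add(ia)
                    interleaved.add(ib)
    return len(interleaved)


def exact_multinomial_p(counts: tuple[int, ...], k: int = 4) -> float:
    """Exact equal-probability multinomial goodness-of-fit p-value.

    p is the total probability, under cell probabilities 1/k, of outcomes
    no more probable than the observed one. Enumerates all compositions of
    n into k cells.
    """
    counts = tuple(int(c) for c in counts)
    n = sum(counts)
    if n == 0:
        return 1.0

    def logpmf(cs: tuple[int, ...]) -> float:
        return (
            gammaln(n + 1)
            - sum(gammaln(c + 1) for c in cs)
            - n * np.log(k)
        )

    lp_obs = logpmf(counts)
    tol = 1e-9
    total = 0.0

    def rec(prefix: list[int], remaining: int, depth: int) -> None:
        nonlocal total
        if depth == k - 1:
            cs = tuple(prefix + [remaining])
            lp = logpmf(cs)
            if lp <= lp_obs + tol:
                total += float(np.exp(lp))
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c, depth + 1)

    rec([], n, 0)
    return min(1.0, total)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def orientation_multinomial_fdr(
    cluster_counts: list[OrientationCounts],
) -> list[tuple[float, float]]:
    """Per-cluster multinomial p against equal orientation probabilities, with BH FDR.

    Exact enumeration for totals <= 60, chi-square approximation beyond.
    All-zero counts give p = 1.
    """
    if not cluster_counts:
        raise ValueError("need at least one cluster")
    pvals = []
    for oc in cluster_counts:
        n = oc.total
        if n == 0:
            pvals.append(1.0)
        elif n <= EXACT_MULTINOMIAL_MAX_N:
            pvals.append(exact_multinomial_p(oc.as_tuple()))
        else:
            stat = chisquare(np.array(oc.as_tuple(), dtype=float))
            pvals.append(float(stat.pvalue))
    fdr = benjamini_hochberg(np.array(pvals))
    return list(zip(pvals, fdr.tolist()))


def _cluster_cn_values(cluster: SvCluster, cn_segments) -> list[int]:
    """Total-CN series of segments within the cluster span on each chromosome."""
    values: list[int] = []
    for chrom in sorted(cluster.chromosomes()):
        pos = [b.pos for r in cluster.rearrangements for b in r.breakends
               if b.chrom == chrom]
        if not pos:
            continue
        lo, hi = min(pos), max(pos)
        segs = [s for s in cn_segments
                if s.interval.chrom == chrom
                and s.interval.start <= hi and s.interval.end >= lo]
        segs.sort(key=lambda s: s.interval.start)
        values.extend(s.t_cn for s in segs)
    return values


def call_chromothripsis(
    cluster: SvCluster,
    cn_segments,
    orientation_fdr: float,
    cluster_id: str = "",
) -> ClusterCall:
    """Apply the three chromothripsis criteria to a complex cluster."""
    if cluster.size < 3:
        raise ValueError("chromothripsis requires a complex cluster (size >= 3)")
    cn_values = _cluster_cn_values(cluster, cn_segments)
    if cn_values:
        found, run_len, n_states = detect_oscillation(cn_values)
    else:
        found, run_len, n_states = False, 0, 0
    inter = count_interleaved(cluster)
    is_ct = found and inter >= MIN_INTERLEAVED and orientation_fdr > ORIENTATION_FDR_MIN
    return ClusterCall(
        cluster_id=cluster_id,
        call="chromothripsis" if is_ct else "complex_unclassified",
        oscillation_found=found,
        oscillation_run_length=run_len,
        oscillation_n_states=n_states,
        interleaved_count=inter,
        orientation_fdr=orientation_fdr,
        n_rearrangements=cluster.size,
    )


# ---------------------------------------------------------------------------
# Chromoplexy criteria
# ---------------------------------------------------------------------------

def _chain_chromosome_count(cluster: SvCluster, edge_dist: int) -> int:
    """Max chromosomes touched by one breakpoint-graph component.

    Nodes are breakends; an edge joins breakends of *different*
    rearrangements within ``edge_dist`` on the same chromosome. Breakends
    of the same rearrangement are implicitly chained through their
    junction, so components are taken over rearrangements.
    """
    nodes: list[tuple[str, int, int]] = []  # (chrom, pos, rearrangement idx)
    for i, r in enumerate(cluster.rearrangements):
        nodes.append((r.bnd1.chrom, r.bnd1.pos, i))
        nodes.append((r.bnd2.chrom, r.bnd2.pos, i))
    nodes.sort(key=lambda t: (t[0], t[1]))
    parent = list(range(cluster.size))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (c1, p1, i1), (c2, p2, i2) in zip(nodes, nodes[1:]):
        if c1 == c2 and p2 - p1 <= edge_dist and i1 != i2:
            ri, rj = find(i1), find(i2)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    comp_chroms: dict[int, set[str]] = {}
    for i, r in enumerate(cluster.rearrangements):
        s = comp_chroms.setdefault(find(i), set())
        s.add(r.bnd1.chrom)
        s.add(r.bnd2.chrom)
    return max(len(s) for s in comp_chroms.values())


def balanced_footprint_fraction(
    cluster: SvCluster, bridge_tol: int = DELETION_BRIDGE_TOL
) -> float:
    """Fraction of cluster footprints consistent with balanced translocations.

    A footprint qualifies when it holds breakends from two different
    interchromosomal rearrangements with opposite orientations within the
    deletion-bridge tolerance (reciprocal junction geometry: no copy-number
    change, or only a short deletion bridge).
    """
    if not cluster.footprints:
        return 0.0
    n_bal = 0
    for fp in cluster.footprints:
        inter = [(b, r) for b, r in fp.breakends if not r.is_intrachromosomal]
        ok = False
        for i, (b1, r1) in enumerate(inter):
            for b2, r2 in inter[i + 1:]:
                if (
                    r1 is not r2
                    and b1.orientation != b2.orientation
                    and abs(b1.pos - b2.pos) <= bridge_tol
                ):
                    ok = True
        if ok:
            n_bal += 1
    return n_bal / len(cluster.footprints)


def call_chromoplexy(
    cluster: SvCluster,
    cluster_id: str = "",
    edge_dist: int = CHROMOPLEXY_EDGE_DIST,
    bridge_tol: int = DELETION_BRIDGE_TOL,
) -> ClusterCall:
    """Apply the three chromoplexy criteria to a complex cluster."""
    if cluster.size < 3:
        raise ValueError("chromoplexy requires a complex cluster (size >= 3)")
    chain = _chain_chromosome_count(cluster, edge_dist)
    frac = balanced_footprint_fraction(cluster, bridge_tol)
    lo, hi = CHROMOPLEXY_SIZE_RANGE
    is_cp = chain >= 3 and frac >= 0.5 and lo <= cluster.size <= hi
    return ClusterCall(
        cluster_id=cluster_id,
        call="chromoplexy" if is_cp else "complex_unclassified",
        chain_chromosomes=chain,
        balanced_footprint_fraction=frac,
        n_rearrangements=cluster.size,
    )


def classify_complex(
    cluster: SvCluster,
    cn_segments,
    orientation_fdr: float,
    cluster_id: str = "",
) -> ClusterCall:
    """Chromothripsis first, then chromoplexy, else complex_unclassified."""
    ct = call_chromothripsis(cluster, cn_segments, orientation_fdr, cluster_id)
    if ct.call == "chromothripsis":
        return ct
    cp = call_chromoplexy(cluster, cluster_id)
    if cp.call == "chromoplexy":
        cp.oscillation_found = ct.oscillation_found
        cp.interleaved_count = ct.interleaved_count
        cp.orientation_fdr = orientation_fdr
        return cp
    ct.chain_chromosomes = cp.chain_chromosomes
    ct.balanced_footprint_fraction = cp.balanced_footprint_fraction
    return ct


# ---------------------------------------------------------------------------
# Complex-SV enrichment
# ---------------------------------------------------------------------------

def _tumour_bin_counts(
    placements: list[tuple[int, np.ndarray, np.ndarray]], grid: BinGrid
) -> np.ndarray:
    """Number of tumours with >= 1 footprint overlapping each bin.

    ``placements`` holds (tumour_index, chrom_codes, starts/ends arrays)
    per tumour; see callers for layout.
    """
    n_bins = len(grid)
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, first_bin, last_bin in placements:
        touched: set[int] = set()
        for b0, b1 in zip(first_bin, last_bin):
            touched.update(range(int(b0), int(b1) + 1))
        if touched:
            counts[list(touched)] += 1
    return counts


def _footprint_bins(
    grid: BinGrid, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    first = grid.bin_indices(chroms, starts)
    last = grid.bin_indices(chroms, np.maximum(ends - 1, starts))
    return first, last


def complex_enrichment(
    footprints_by_tumour: dict[str, list],
    layout: GenomeLayout,
    grid: BinGrid,
    n_perm: int = 100_000,
    seed: int = 0,
) -> list[ComplexBinStat]:
    """Permutation-based per-bin complex-SV enrichment with empirical FDR.

    g_obs counts tumours with >= 1 complex footprint overlapping each bin.
    Footprints are re-placed uniformly on the genome (length-preserving;
    placements crossing a chromosome end are redrawn) ``n_perm`` times;
    g_exp is the per-bin mean of the permuted counts. beta = g_obs / g_exp.
    The FDR at each observed beta is the mean number of permuted bins with
    beta at least as great divided by the number of observed bins with beta
    at least as great, capped at 1, with zeros promoted to the smallest
    non-zero value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    chrom_lengths = np.array(
        [layout.chrom_lengths[c] for c in layout.chrom_names], dtype=np.int64
    )
    tumours = sorted(footprints_by_tumour)
    obs_placements = []
    lengths_per_tumour = []
    for ti, t in enumerate(tumours):
        fps = footprints_by_tumour[t]
        if not fps:
            lengths_per_tumour.append(np.empty(0, dtype=np.int64))
            obs_placements.append((ti, np.empty(0, np.int64), np.empty(0, np.int64)))
            continue
        lens = np.array([fp.interval.length for fp in fps], dtype=np.int64)
        for fp in fps:
            if fp.interval.length > layout.chrom_lengths[fp.interval.chrom]:
                raise ValueError("footprint longer than its chromosome")
        if lens.max(initial=0) > chrom_lengths.max():
            raise ValueError("footprint longer than every chromosome")
        lengths_per_tumour.append(lens)
        chroms = np.array([fp.interval.chrom for fp in fps], dtype=object)
        starts = np.array([fp.interval.start for fp in fps], dtype=np.int64)
        ends = np.array([fp.interval.end for fp in fps], dtype=np.int64)
        first, last = _footprint_bins(grid, chroms, starts, ends)
        obs_placements.append((ti, first, last))

    g_obs = _tumour_bin_counts(obs_placements, grid)

    def permute_once(rng: np.random.Generator) -> np.ndarray:
        placements = []
        for ti, lens in enumerate(lengths_per_tumour):
            if len(lens) == 0:
                placements.append((ti, np.empty(0, np.int64), np.empty(0, np.int64)))
                continue
            chroms = np.empty(len(lens), dtype=object)
            starts = np.empty(len(lens), dtype=np.int64)
            pending = np.arange(len(lens))
            while len(pending):
                ci = rng.integers(0, len(chrom_lengths), size=len(pending))
                room = chrom_lengths[ci] - lens[pending]
                ok = room >= 0
                if ok.any():
                    pos = (rng.random(len(pending)) * (room + 1)).astype(np.int64)
                    sel = pending[ok]
                    chroms[sel] = np.array(layout.chrom_names, dtype=object)[ci[ok]]
                    starts[sel] = pos[ok]
                pending = pending[~ok]
            first, last = _footprint_bins(grid, chroms, starts, starts + lens)
            placements.append((ti, first, last))
        return _tumour_bin_counts(placements, grid)

    g_sum = np.zeros(len(grid), dtype=np.float64)
    for r in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        g_sum += permute_once(rng)
    g_exp = g_sum / n_perm

    callable_ = grid.callable_flags
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_obs = np.where(g_exp > 0, g_obs / g_exp, np.where(g_obs > 0, np.inf, 0.0))

    # second pass with the same substreams: exceedance counts of permuted beta
    idx = np.where(callable_ & (g_exp > 0))[0]
    obs_beta = beta_obs[idx]
    order = np.sort(obs_beta)
    exceed = np.zeros(len(idx), dtype=np.float64)
    for r in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        g_perm = permute_once(rng)
        beta_perm = np.where(g_exp[idx] > 0, g_perm[idx] / g_exp[idx], 0.0)
        sorted_perm = np.sort(beta_perm)
        # permuted bins with beta >= v, for each observed v
        exceed += len(sorted_perm) - np.searchsorted(sorted_perm, obs_beta, side="left")
    mean_exceed = exceed / n_perm
    n_obs_ge = len(order) - np.searchsorted(order, obs_beta, side="left")
    fdr = np.minimum(mean_exceed / n_obs_ge, 1.0)
    nonzero = fdr[fdr > 0]
    floor = nonzero.min() if len(nonzero) else 1.0 / n_perm
    fdr = np.where(fdr == 0, floor, fdr)

    out = []
    for k, i in enumerate(idx):
        out.append(
            ComplexBinStat(
                bin=grid.bins[i],
                g_obs=int(g_obs[i]),
                g_exp=float(g_exp[i]),
                beta_complex=float(beta_obs[i]),
                fdr=float(fdr[k]),
            )
        )
    return out
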