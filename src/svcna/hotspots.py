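"""SV hotspot detection.

Per chromosome, sorted breakend positions are converted to log10
inter-mutational distances (IMDs) and segmented by exact penalized
least-squares piecewise-constant fitting (PCF). Each segment i gets an
observed breakend density d_obs = a_i / s_i, an expected density
d_exp = (sum of b_j over overlapping bins) / (n * s_bin), and an
enrichment factor beta = d_obs / d_exp. Empirical FDRs compare observed
beta exceedance counts against PCF segments of simulated null catalogues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid, Interval

DEFAULT_GAMMA = 10.0
DEFAULT_KMIN = 10
DEFAULT_FDR_THRESHOLD = 0.05
FOCAL_SV_MAX_LENGTH = 3_000_000
CNA_SUPPORT_TOL = 3_000


@dataclass(frozen=True)
class PcfParams:
    gamma: float = DEFAULT_GAMMA
    kmin: int = DEFAULT_KMIN

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kmin < 2:
            raise ValueError("kmin must be >= 2")


@dataclass
class PcfSegment:
    chrom: str
    first_index: int  # first breakend index in the chromosome's sorted array
    last_index: int  # last breakend index (inclusive)
    start: int  # first breakend position
    end: int  # last breakend position
    a_i: int
    s_i: int
    d_obs: float
    d_exp: float
    beta_simple: float
    fdr: float = float("nan")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end + 1)


@dataclass
class Hotspot:
    interval: Interval
    sv_class: str
    beta_simple: float
    fdr: float
    n_breakends: int
    n_samples: int = 0
    cna_supported: bool = True
    fragile: bool = False
    fragile_criteria: tuple[bool, ...] = ()
    candidate_genes: list[str] = field(default_factory=list)
    n_focal_samples: int = 0


@dataclass
class FragileAnnotation:
    mean_replication_timing: float | None = None
    genes_per_mb: float | None = None
    largest_gene_length: float | None = None
    in_gene_flank_density_ratio: float | None = None
    overlaps_known_fragile_list_1: bool = False
    overlaps_known_fragile_list_2: bool = False


# ---------------------------------------------------------------------------
# IMD series and PCF
# ---------------------------------------------------------------------------

def imd_series(positions: np.ndarray) -> np.ndarray:
    """log10 inter-mutational distances of sorted positions (floor 1 bp)."""
    positions = np.asarray(positions)
    if len(positions) < 2:
        return np.empty(0, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    return np.log10(np.maximum(np.diff(positions), 1).astype(float))


def _pcf_suffix_dp_py(s1, s2, n, gamma, kmin):
    g_cost = np.full(n + 1, np.inf)
    g_nseg = np.full(n + 1, 2**31, dtype=np.int64)
    g_cost[n] = 0.0
    g_nseg[n] = 0
    for s in range(n - 1, -1, -1):
        best_cost = np.inf
        best_nseg = 2**31
        for e in range(s + kmin, n + 1):
            if e != n and n - e < kmin:
                continue
            if g_cost[e] == np.inf:
                continue
            w = e - s
            sm = s1[e] - s1[s]
            cost = (s2[e] - s2[s]) - sm * sm / w + gamma + g_cost[e]
            nseg = g_nseg[e] + 1
            if cost < best_cost or (cost == best_cost and nseg < best_nseg):
                best_cost = cost
                best_nseg = nseg
        g_cost[s] = best_cost
        g_nseg[s] = best_nseg
    return g_cost, g_nseg


try:  # optional numba acceleration for the O(n^2) inner loop
    from numba import njit

    _pcf_suffix_dp = njit(cache=False)(_pcf_suffix_dp_py)
except Exception:  # pragma: no cover - numba always present in CI image
    _pcf_suffix_dp = _pcf_suffix_dp_py


def pcf(values: np.ndarray, params: PcfParams) -> list[tuple[int, int, float]]:
    """Exact penalized least-squares segmentation.

    Minimizes sum of within-segment squared deviations plus gamma per
    segment, each segment holding >= kmin points, by dynamic programming.
    Ties break toward fewer segments, then lexicographically earliest
    boundaries. Returns (start, end_exclusive, mean) per segment.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return []
    if n < params.kmin:
        warnings.warn("series shorter than kmin; returning a single segment")
        return [(0, n, float(values.mean()))]
    gamma = float(params.gamma)
    kmin = params.kmin

    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    g_cost, g_nseg = _pcf_suffix_dp(s1, s2, n, gamma, kmin)

    # front-greedy reconstruction: earliest boundary achieving the optimum
    segments: list[tuple[int, int, float]] = []
    s = 0
    while s < n:
        ends = np.arange(s + kmin, n + 1)
        ends = ends[(ends == n) | (n - ends >= kmin)]
        w = ends - s
        sm = s1[ends] - s1[s]
        cost = (s2[ends] - s2[s]) - sm * sm / w + gamma + g_cost[ends]
        nseg = g_nseg[ends] + 1
        match = np.where((cost == g_cost[s]) & (nseg == g_nseg[s]))[0]
        if len(match) == 0:  # numerical guard; fall back to argmin
            match = [int(np.argmin(cost))]
        e = int(ends[match[0]])
        segments.append((s, e, float((s1[e] - s1[s]) / (e - s))))
        s = e
    return segments


def pcf_cost(values: np.ndarray, segments: list[tuple[int, int, float]],
             gamma: float) -> float:
    """Objective value of a segmentation (for oracle comparison)."""
    values = np.asarray(values, dtype=float)
    total = gamma * len(segments)
    for a, b, _ in segments:
        seg = values[a:b]
        total += float(np.sum((seg - seg.mean()) ** 2))
    return total


# ---------------------------------------------------------------------------
# Segment statistics
# ---------------------------------------------------------------------------

def segment_stats(
    chrom: str,
    imd_range: tuple[int, int],
    positions: np.ndarray,
    grid: BinGrid,
) -> PcfSegment:
    """Enrichment statistics for one PCF segment of an IMD series.

    IMD indices [j, k) cover breakends j..k (inclusive), hence
    a_i = k - j + 1 breakends and span s_i = pos[k] - pos[j] + 1.
    """
    j, k_excl = imd_range
    k = k_excl  # IMD index range [j, k_excl) maps to breakends [j, k_excl]
    first_pos = int(positions[j])
    last_pos = int(positions[k])
    a_i = k - j + 1
    s_i = last_pos - first_pos + 1
    b0, b1 = grid.bin_range(chrom, first_pos, last_pos + 1)
    n_bins = b1 - b0
    sum_b = float(grid.b[b0:b1].sum())
    d_obs = a_i / s_i
    d_exp = sum_b / (n_bins * grid.s_bin)
    beta = d_obs / d_exp if d_exp > 0 else float("inf")
    return PcfSegment(
        chrom=chrom,
        first_index=j,
        last_index=k,
        start=first_pos,
        end=last_pos,
        a_i=a_i,
        s_i=s_i,
        d_obs=d_obs,
        d_exp=d_exp,
        beta_simple=beta,
    )


def segment_catalog(
    positions_by_chrom: dict[str, np.ndarray],
    grid: BinGrid,
    params: PcfParams,
) -> list[PcfSegment]:
    """PCF-segment every chromosome of a breakend catalogue."""
    out: list[PcfSegment] = []
    for chrom in sorted(positions_by_chrom):
        pos = np.sort(np.asarray(positions_by_chrom[chrom]))
        y = imd_series(pos)
        if len(y) < 1:
            continue
        if len(y) < params.kmin:
            continue
        for a, b, _ in pcf(y, params):
            out.append(segment_stats(chrom, (a, b), pos, grid))
    return out


# ---------------------------------------------------------------------------
# Empirical FDR
# ---------------------------------------------------------------------------

def empirical_fdr(
    observed: list[PcfSegment],
    simulated: list[list[PcfSegment]],
) -> list[PcfSegment]:
    """Fill segment FDRs from simulated null segmentations.

    FDR(v) = (mean over replicates of simulated segments with beta >= v)
    / (observed segments with beta >= v); capped at 1, zeros promoted to
    the smallest non-zero FDR.
    """
    if not simulated:
        raise ValueError("need at least one simulated replicate")
    if not observed:
        return []
    n_reps = len(simulated)
    obs_beta = np.array([s.beta_simple for s in observed])
    sim_beta = np.sort(
        np.concatenate(
            [np.array([s.beta_simple for s in reps]) for reps in simulated]
            or [np.empty(0)]
        )
    )
    order = np.sort(obs_beta)
    n_obs_ge = len(order) - np.searchsorted(order, obs_beta, side="left")
    n_sim_ge = len(sim_beta) - np.searchsorted(sim_beta, obs_beta, side="left")
    fdr = np.minimum((n_sim_ge / n_reps) / n_obs_ge, 1.0)
    nonzero = fdr[fdr > 0]
    floor = float(nonzero.min()) if len(nonzero) else 1.0 / (n_reps * len(observed))
    fdr = np.where(fdr == 0, floor, fdr)
    for seg, f in zip(observed, fdr):
        seg.fdr = float(f)
    return observed


def scan(
    positions_by_chrom: dict[str, np.ndarray],
    simulated_positions: list[dict[str, np.ndarray]],
    grid: BinGrid,
    params: PcfParams,
) -> list[PcfSegment]:
    """Segment observed and simulated catalogues and fill observed FDRs."""
    obs = segment_catalog(positions_by_chrom, grid, params)
    sims = [segment_catalog(s, grid, params) for s in simulated_positions]
    return empirical_fdr(obs, sims)


def select_parameters(
    positions_by_chrom: dict[str, np.ndarray],
    simulated_positions: list[dict[str, np.ndarray]],
    grid: BinGrid,
    gamma_grid: list[float] | None = None,
    kmin_grid: list[int] | None = None,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> PcfParams:
    """Grid-search (gamma, kmin) maximizing FDR-significant segment count.

    Ties break toward lower median FDR, then lower gamma, then lower kmin.
    """
    gamma_grid = gamma_grid or list(range(1, 21))
    kmin_grid = kmin_grid or list(range(2, 21))
    best: tuple | None = None
    best_params: PcfParams | None = None
    for gamma in gamma_grid:
        for kmin in kmin_grid:
            params = PcfParams(gamma=float(gamma), kmin=int(kmin))
            segs = scan(positions_by_chrom, simulated_positions, grid, params)
            n_hot = sum(1 for s in segs if s.fdr < fdr_threshold)
            med = float(np.median([s.fdr for s in segs])) if segs else 1.0
            key = (-n_hot, med, gamma, kmin)
            if best is None or key < best:
                best = key
                best_params = params
    return best_params


# ---------------------------------------------------------------------------
# Filtering, collapsing, annotation
# ---------------------------------------------------------------------------

def _sv_breakends_in(sv, interval: Interval):
    return [b for b in sv.breakends
            if b.chrom == interval.chrom and interval.contains(b.pos)]


def _has_cna_support(sv, boundaries: dict[str, np.ndarray], tol: int) -> bool:
    for b in sv.breakends:
        pos = boundaries.get(b.chrom)
        if pos is None or len(pos) == 0:
            continue
        i = np.searchsorted(pos, b.pos)
        for j in (i - 1, i):
            if 0 <= j < len(pos) and abs(int(pos[j]) - b.pos) <= tol:
                return True
    return False


def filter_and_collapse(
    segments: list[PcfSegment],
    sv_class: str = "",
    svs: list | None = None,
    cn_boundaries_by_sample: dict[str, dict[str, np.ndarray]] | None = None,
    genes: list | None = None,
    drivers: set[str] | None = None,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    cna_tol: int = CNA_SUPPORT_TOL,
    focal_max_length: int = FOCAL_SV_MAX_LENGTH,
) -> list[Hotspot]:
    """Turn FDR-significant PCF segments into collapsed, annotated hotspots.

    Segments at FDR >= threshold are dropped. When per-sample CN boundary
    positions are supplied, hotspots whose contributing SVs all lack a
    breakend within ``cna_tol`` of a CN segment boundary are removed as
    potential artefacts. Overlapping kept segments are merged (union span,
    min FDR, max beta). Candidate genes are overlapping drivers or the sole
    expressed overlapping gene; focal sample counts consider only SVs
    shorter than ``focal_max_length``.
    """
    kept = [s for s in segments if s.fdr < fdr_threshold]
    if not kept:
        return []
    kept.sort(key=lambda s: (s.chrom, s.start))
    merged: list[list[PcfSegment]] = [[kept[0]]]
    for s in kept[1:]:
        last = merged[-1][-1]
        if s.chrom == last.chrom and s.start <= max(x.end for x in merged[-1]):
            merged[-1].append(s)
        else:
            merged.append([s])

    hotspots: list[Hotspot] = []
    for group in merged:
        chrom = group[0].chrom
        start = min(s.start for s in group)
        end = max(s.end for s in group) + 1
        iv = Interval(chrom, start, end)
        contributing = []
        samples = set()
        if svs is not None:
            for sv in svs:
                if _sv_breakends_in(sv, iv):
                    contributing.append(sv)
                    samples.add(sv.sample_id)
        cna_ok = True
        if cn_boundaries_by_sample is not None and svs is not None:
            cna_ok = any(
                _has_cna_support(
                    sv, cn_boundaries_by_sample.get(sv.sample_id, {}), cna_tol
                )
                for sv in contributing
            )
            if not cna_ok:
                continue
        candidate_genes: list[str] = []
        if genes is not None:
            overlapping = [g for g in genes if g.interval.overlaps(iv)]
            expressed = [g for g in overlapping if getattr(g, "expressed", True)]
            for g in overlapping:
                if drivers and g.name in drivers:
                    candidate_genes.append(g.name)
            if len(expressed) == 1 and expressed[0].name not in candidate_genes:
                candidate_genes.append(expressed[0].name)
        n_focal_samples = 0
        if genes is not None and svs is not None and candidate_genes:
            gene_ivs = [g.interval for g in genes if g.name in candidate_genes]
            focal_samples = set()
            for sv in contributing:
                if sv.is_intrachromosomal and (sv.length or 0) < focal_max_length:
                    span = Interval(sv.bnd1.chrom, sv.bnd1.pos,
                                    max(sv.bnd2.pos, sv.bnd1.pos + 1))
                    if any(span.overlaps(gi) for gi in gene_ivs):
                        focal_samples.add(sv.sample_id)
            n_focal_samples = len(focal_samples)
        hotspots.append(
            Hotspot(
                interval=iv,
                sv_class=sv_class,
                beta_simple=max(s.beta_simple for s in group),
                fdr=min(s.fdr for s in group),
                n_breakends=sum(s.a_i for s in group),
                n_samples=len(samples) if svs is not None else 0,
                cna_supported=cna_ok,
                candidate_genes=candidate_genes,
                n_focal_samples=n_focal_samples,
            )
        )
    return hotspots


# ---------------------------------------------------------------------------
# Fragile-site triage
# ---------------------------------------------------------------------------

LATE_REPLICATION_MAX = 0.0
GENE_DENSITY_MAX = 5.0
LARGE_GENE_MIN = 300_000
DENSITY_RATIO_MIN = 5.0
FRAGILE_MIN_CRITERIA = 3


def classify_fragile(
    hotspot: Hotspot,
    ann: FragileAnnotation,
    drivers_contained: set[str] | None = None,
) -> tuple[bool, tuple[bool, ...]]:
    """Six-criteria fragile-site call; fragile iff >= 3 met and no driver inside.

    Criteria: (1) late replication (mean timing <= 0); (2) gene density
    < 5 per Mb; (3) overlaps a gene > 300 kb; (4) largest-gene vs 1-Mb-flank
    breakpoint density ratio > 5; (5) and (6) overlap with the two known
    fragile-site lists. Missing annotations leave a criterion unmet.
    """
    criteria = (
        ann.mean_replication_timing is not None
        and ann.mean_replication_timing <= LATE_REPLICATION_MAX,
        ann.genes_per_mb is not None and ann.genes_per_mb < GENE_DENSITY_MAX,
        ann.largest_gene_length is not None
        and ann.largest_gene_length > LARGE_GENE_MIN,
        ann.in_gene_flank_density_ratio is not None
        and ann.in_gene_flank_density_ratio > DENSITY_RATIO_MIN,
        bool(ann.overlaps_known_fragile_list_1),
        bool(ann.overlaps_known_fragile_list_2),
    )
    has_driver = bool(drivers_contained)
    fragile = sum(criteria) >= FRAGILE_MIN_CRITERIA and not has_driver
    hotspot.fragile = fragile
    hotspot.fragile_criteria = criteria
    return fragile, criteria


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = []
    for h in hotspots:
        rows.append(
            {
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "class": h.sv_class,
                "n_breakends": h.n_breakends,
                "beta": h.beta_simple,
                "fdr": h.fdr,
                "n_samples": h.n_samples,
                "cna_supported": h.cna_supported,
                "fragile": h.fragile,
                "criteria_bitmap": "".join(
                    "1" if c else "0" for c in h.fragile_criteria
                ),
                "candidate_genes": ",".join(h.candidate_genes),
            }
        )
    return pd.DataFrame(rows)
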