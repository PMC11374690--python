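"""Synthetic-cohort generation.

Produces genomes with covariate-driven NB breakend rates, SV catalogues
with optional injected hotspot bins and planted complex-event clusters,
and WGD/non-WGD allele-specific copy-number profiles — everything the
pipeline consumes, with truth tables for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fixtures
from .catalog import Breakend, Rearrangement
from .cna import CnSegment
from .genome import BinGrid, GenomeLayout, Interval, build_bins

DEFAULT_COVARIATES = [
    ("replication_timing", "normal"),
    ("gc", "normal"),
    ("dnase", "normal"),
    ("h3k36me3", "normal"),
    ("h3k9me3", "normal"),
    ("alu", "normal"),
    ("segdup", "binary"),
    ("fragile_site", "binary"),
    ("high_expression", "binary"),
]


@dataclass
class SynthConfig:
    n_chroms: int = 20
    chrom_length: int = 150_000_000
    bin_size: int = 1_000_000
    centromere_halfwidth: int = 600_000
    covariates: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COVARIATES)
    )
    true_beta: dict[str, float] = field(
        default_factory=lambda: {
            "replication_timing": -0.5,
            "gc": 0.3,
            "dnase": 0.2,
            "h3k36me3": -0.2,
            "h3k9me3": 0.1,
            "alu": 0.4,
            "segdup": 0.3,
            "fragile_site": 0.8,
            "high_expression": -0.1,
        }
    )
    dispersion: float = 1.0
    n_svs: int = 2_000
    n_tumours: int = 100
    hotspot_bins: list[int] = field(default_factory=list)
    hotspot_multiplier: float = 15.0
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "deletion": 0.45,
            "tandem_duplication": 0.25,
            "inversion": 0.2,
            "translocation": 0.1,
        }
    )
    length_log10_mean: float = 4.7
    length_log10_sd: float = 0.6
    wgd_fraction: float = 0.3
    purity_range: tuple[float, float] = (0.3, 0.95)
    n_chromothripsis: int = 0
    n_chromoplexy: int = 0
    seed: int = 0


def generate_genome(config: SynthConfig) -> tuple[GenomeLayout, BinGrid]:
    """Layout with centromeric masks, 1-Mb grid, random covariates."""
    if config.n_chroms < 2 or config.chrom_length <= 2 * config.bin_size:
        raise ValueError("invalid genome spec")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    )
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    lengths = {c: config.chrom_length for c in names}
    mid = config.chrom_length // 2
    arm_boundaries = {c: mid for c in names}
    mask = []
    if config.centromere_halfwidth > 0:
        mask = [
            Interval(c, mid - config.centromere_halfwidth,
                     mid + config.centromere_halfwidth)
            for c in names
        ]
    layout = GenomeLayout(names, lengths, arm_boundaries, mask)
    grid = build_bins(layout, config.bin_size)
    n = len(grid)
    cols = {}
    for name, kind in config.covariates:
        if kind == "normal":
            cols[name] = rng.normal(0.0, 1.0, size=n)
        elif kind == "binary":
            cols[name] = rng.binomial(1, 0.25, size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    grid.set_covariates(pd.DataFrame(cols))
    return layout, grid


def bin_rates(config: SynthConfig, grid: BinGrid) -> np.ndarray:
    """Per-bin relative first-breakend rates (0 on uncallable bins)."""
    X = grid.covariate_frame()
    eta = np.zeros(len(grid))
    for name, beta in config.true_beta.items():
        if name in X.columns:
            eta += beta * X[name].to_numpy()
    lam = np.exp(eta)
    lam[~grid.callable_flags] = 0.0
    for b in config.hotspot_bins:
        lam[b] *= config.hotspot_multiplier
    return lam


def pick_hotspot_bins(
    config: SynthConfig,
    grid: BinGrid,
    n: int,
    rate_band: tuple[float, float] = (0.8, 1.25),
) -> list[int]:
    """Choose ``n`` injection bins with near-median covariate-driven rate.

    PCF segments absolute breakend density, so a multiplicative excess on a
    bin whose baseline rate is far below the genome average is structurally
    hard to segment; rate-matched injection keeps the recovery benchmark
    about the detection machinery rather than placement luck. Deterministic
    given the config seed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(3,))
    )
    lam = bin_rates(config, grid)
    callable_ = grid.callable_flags
    med = np.median(lam[callable_ & (lam > 0)])
    in_band = (lam >= rate_band[0] * med) & (lam <= rate_band[1] * med)
    # flanking neighbourhood must be typical too, else the segmentation
    # cannot isolate the injected bin from a locally dense background
    flank_ok = np.ones(len(lam), dtype=bool)
    for off in (-2, -1, 1, 2):
        rolled = np.roll(lam, off)
        flank_ok &= rolled <= 1.6 * med
    ok = np.where(callable_ & in_band & flank_ok)[0]
    if len(ok) < n:
        raise ValueError("not enough rate-matched callable bins")
    # keep picks on distinct chromosomes where possible
    picks: list[int] = []
    used_chroms: set[int] = set()
    for idx in rng.permutation(ok):
        code = int(grid.chrom_codes[idx])
        if code in used_chroms and len(ok) - len(picks) > n - len(picks):
            continue
        picks.append(int(idx))
        used_chroms.add(code)
        if len(picks) == n:
            break
    return sorted(picks)


def generate_cohort_svs(
    config: SynthConfig, grid: BinGrid, layout: GenomeLayout | None = None
) -> tuple[dict[str, list[Rearrangement]], pd.DataFrame,
           dict[str, list[CnSegment]]]:
    """Per-tumour SV lists, a truth table, and planted CN segments.

    First breakends land in bins with NB-distributed counts whose means
    follow exp(X beta_true), multiplied in injected hotspot bins; lengths
    are log-normal; orientations follow the class convention. Planted
    chromothripsis/chromoplexy clusters are appended with truth labels;
    the oscillating copy-number segments accompanying planted
    chromothripsis events are returned per tumour so downstream CN-aware
    classification sees them.
    """
    layout = layout or grid.layout
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    lam = bin_rates(config, grid)
    mean = config.n_svs * lam / lam.sum()
    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        counts = rng.negative_binomial(size, size / (size + mean), size=len(mean))
        counts[mean == 0] = 0
    else:
        counts = rng.poisson(mean)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    probs = probs / probs.sum()

    chrom_len = {c: layout.chrom_lengths[c] for c in layout.chrom_names}
    svs: dict[str, list[Rearrangement]] = {
        f"T{t:04d}": [] for t in range(config.n_tumours)
    }
    truth_rows = []
    sv_i = 0
    bin_order = np.repeat(np.arange(len(grid)), counts)
    for bidx in bin_order:
        b = grid.bins[bidx]
        chrom = b.interval.chrom
        pos = int(rng.integers(b.interval.start, b.interval.end))
        cls = classes[rng.choice(len(classes), p=probs)]
        tumour = f"T{int(rng.integers(0, config.n_tumours)):04d}"
        if cls == "translocation":
            others = [c for c in layout.chrom_names if c != chrom]
            c2 = others[int(rng.integers(0, len(others)))]
            p2 = int(rng.integers(0, chrom_len[c2]))
            o1, o2 = ("+", "-") if rng.random() < 0.5 else ("-", "+")
            r = Rearrangement(
                f"sv{sv_i}", tumour, Breakend(chrom, pos, o1), Breakend(c2, p2, o2)
            )
        else:
            length = int(10 ** rng.normal(config.length_log10_mean,
                                          config.length_log10_sd))
            length = max(50, length)
            direction = 1 if rng.random() < 0.5 else -1
            p2 = pos + direction * length
            if p2 < 0 or p2 >= chrom_len[chrom]:
                p2 = pos - direction * length
            if p2 < 0 or p2 >= chrom_len[chrom]:
                continue
            lo, hi = min(pos, p2), max(pos, p2)
            # orientations attach to the position-ordered breakends
            if cls == "deletion":
                o_lo, o_hi = "+", "-"
            elif cls == "tandem_duplication":
                o_lo, o_hi = "-", "+"
            else:  # inversion junction
                o_lo = o_hi = "+" if rng.random() < 0.5 else "-"
            r = Rearrangement(
                f"sv{sv_i}", tumour, Breakend(chrom, lo, o_lo),
                Breakend(chrom, hi, o_hi)
            )
        svs[tumour].append(r)
        sv_i += 1

    for b in config.hotspot_bins:
        truth_rows.append(
            {
                "kind": "hotspot_bin",
                "chrom": grid.bins[b].interval.chrom,
                "start": grid.bins[b].interval.start,
                "end": grid.bins[b].interval.end,
                "bin_index": b,
                "multiplier": config.hotspot_multiplier,
                "label": "",
            }
        )
    from dataclasses import replace

    planted_cn: dict[str, list[CnSegment]] = {}
    for i in range(config.n_chromothripsis):
        cluster, ct_segs = fixtures.make_chromothripsis_cluster(seed=config.seed + i)
        tumour = f"T{i % config.n_tumours:04d}"
        for r in cluster.rearrangements:
            svs[tumour].append(replace(r, sample_id=tumour))
        planted_cn.setdefault(tumour, []).extend(ct_segs)
        truth_rows.append(
            {"kind": "planted_cluster", "chrom": "chr1", "start": 0, "end": 0,
             "bin_index": -1, "multiplier": 1.0, "label": "chromothripsis"}
        )
    for i in range(config.n_chromoplexy):
        cluster = fixtures.make_chromoplexy_cluster(seed=config.seed + i)
        tumour = f"T{(i + 7) % config.n_tumours:04d}"
        for r in cluster.rearrangements:
            svs[tumour].append(replace(r, sample_id=tumour))
        truth_rows.append(
            {"kind": "planted_cluster", "chrom": "chr1", "start": 0, "end": 0,
             "bin_index": -1, "multiplier": 1.0, "label": "chromoplexy"}
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "chrom", "start", "end", "bin_index", "multiplier",
                 "label"],
    )
    return svs, truth, planted_cn


def generate_cn_profiles(
    config: SynthConfig, layout: GenomeLayout
) -> tuple[dict[str, list[CnSegment]], pd.DataFrame]:
    """Per-tumour CN segment lists with truth WGD flags and purities.

    WGD tumours sit on a 2+2 baseline, non-WGD on 1+1; each tumour gets a
    few category-labelled arm-scale deviations kept small enough that the
    WGD inequality holds by construction.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
    )
    out: dict[str, list[CnSegment]] = {}
    rows = []
    arms = layout.arms()
    for t in range(config.n_tumours):
        name = f"T{t:04d}"
        is_wgd = bool(rng.random() < config.wgd_fraction)
        base = (2, 2) if is_wgd else (1, 1)
        deviated = {}
        n_dev = int(rng.integers(1, 4))
        arm_idx = rng.choice(len(arms), size=min(n_dev, len(arms)), replace=False)
        for ai in arm_idx:
            chrom, arm, iv = arms[ai]
            frac = 0.55 + 0.35 * rng.random()
            width = int(frac * iv.length)
            start = iv.start if rng.random() < 0.5 else iv.end - width
            if is_wgd:
                state = [(4, 2), (2, 1), (2, 0), (5, 2)][int(rng.integers(0, 4))]
            else:
                state = [(2, 1), (1, 0), (3, 1)][int(rng.integers(0, 3))]
            deviated[(chrom, arm)] = (Interval(chrom, start, start + width), state)
        segs: list[CnSegment] = []
        for chrom, arm, iv in arms:
            dev = deviated.get((chrom, arm))
            if dev is None:
                segs.append(CnSegment(iv, *base))
                continue
            div, state = dev
            if div.start > iv.start:
                segs.append(CnSegment(Interval(chrom, iv.start, div.start), *base))
            segs.append(CnSegment(div, *state))
            if div.end < iv.end:
                segs.append(CnSegment(Interval(chrom, div.end, iv.end), *base))
        out[name] = segs
        purity = config.purity_range[0] + (
            config.purity_range[1] - config.purity_range[0]
        ) * rng.random()
        rows.append({"sample": name, "is_wgd": is_wgd, "purity": purity})
    return out, pd.DataFrame(rows)
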