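"""End-to-end orchestration: bins -> background -> simulate -> PCF -> FDR
-> filter/collapse -> reports.

`run_cohort_scan` is the core per-class scan used by both the CLI and the
test-suite; `run_pipeline` drives a full synthetic demo run and writes the
output bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import background, cna, hotspots, simulate, synthetic
from .catalog import Rearrangement, group_clusters, orientation_counts, classify_simple
from .complex_events import classify_complex, orientation_multinomial_fdr
from .genome import BinGrid, GenomeLayout

logger = logging.getLogger("svcna")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_reps: int = 100
    gamma: float = hotspots.DEFAULT_GAMMA
    kmin: int = hotspots.DEFAULT_KMIN
    fdr_threshold: float = hotspots.DEFAULT_FDR_THRESHOLD
    cohort: str = "synthetic"
    sv_classes: list[str] = field(
        default_factory=lambda: ["deletion", "tandem_duplication"]
    )
    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)


def breakend_positions_by_chrom(svs: list[Rearrangement]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for r in svs:
        for b in r.breakends:
            by_chrom.setdefault(b.chrom, []).append(b.pos)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}


def breakend_counts_per_bin(svs: list[Rearrangement], grid: BinGrid) -> np.ndarray:
    counts = np.zeros(len(grid), dtype=np.int64)
    for r in svs:
        for b in r.breakends:
            counts[grid.bin_index(b.chrom, b.pos)] += 1
    return counts


def fit_background(
    svs: list[Rearrangement], grid: BinGrid
) -> tuple[background.NbModel, background.CovariateMatrix]:
    """Fit the NB surface for one SV class and fill b_j on the grid."""
    counts = breakend_counts_per_bin(svs, grid)
    cov = background.normalize_covariates(grid)
    model = background.fit_nb(counts[cov.bin_index], cov)
    background.expected_breakends(
        model, cov, grid, observed_total=float(counts[cov.bin_index].sum())
    )
    return model, cov


def run_cohort_scan(
    svs: list[Rearrangement],
    grid: BinGrid,
    layout: GenomeLayout,
    n_reps: int,
    seed: int,
    params: hotspots.PcfParams,
) -> list[hotspots.PcfSegment]:
    """Background fit + null replicates + PCF/FDR for one SV class."""
    fit_background(svs, grid)
    is_intra, lengths = simulate.observed_arrays(svs)
    reps = simulate.run_replicate_positions(
        is_intra, lengths, grid, layout, n_reps, seed
    )
    obs_pos = breakend_positions_by_chrom(svs)
    sim_pos = [r.positions_by_chrom() for r in reps]
    return hotspots.scan(obs_pos, sim_pos, grid, params)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Synthetic end-to-end run; returns the paths of the written outputs.

    All outputs are deterministic functions of the config (no timestamps in
    data files); the log carries timing and is excluded from reproducibility
    comparisons.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    layout, grid = synthetic.generate_genome(config.synth)
    svs_by_tumour, truth, planted_cn = synthetic.generate_cohort_svs(
        config.synth, grid, layout
    )
    all_svs = [r for t in sorted(svs_by_tumour) for r in svs_by_tumour[t]]
    logger.info("generated %d SVs across %d tumours", len(all_svs),
                len(svs_by_tumour))

    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["grid"] = out / "bins.tsv"

    # cluster and classify per tumour (clusters are per-sample events)
    clusters = [
        cl
        for t in sorted(svs_by_tumour)
        for cl in group_clusters(svs_by_tumour[t])
    ]
    cn_profiles, cn_truth = synthetic.generate_cn_profiles(config.synth, layout)
    complex_clusters = [c for c in clusters if c.is_complex]
    cluster_rows = []
    if complex_clusters:
        ocs = [orientation_counts(c) for c in complex_clusters]
        fdrs = orientation_multinomial_fdr(ocs)
        for i, (cl, (p, fdr)) in enumerate(zip(complex_clusters, fdrs)):
            sample = cl.rearrangements[0].sample_id
            # planted oscillation segments shadow the baseline profile
            cn_segs = planted_cn.get(sample, []) + cn_profiles.get(sample, [])
            call = classify_complex(cl, cn_segs, fdr, cluster_id=f"C{i}")
            cluster_rows.append(
                {
                    "cluster_id": call.cluster_id,
                    "call": call.call,
                    "n_rearrangements": call.n_rearrangements,
                    "oscillation": call.oscillation_found,
                    "interleaved": call.interleaved_count,
                    "orientation_fdr": call.orientation_fdr,
                    "chain_chromosomes": call.chain_chromosomes,
                    "balanced_footprint_fraction":
                        call.balanced_footprint_fraction,
                }
            )
    for i, cl in enumerate(c for c in clusters if not c.is_complex):
        sample = cl.rearrangements[0].sample_id
        label = classify_simple(cl)
        cluster_rows.append(
            {
                "cluster_id": f"S{i}", "call": label,
                "n_rearrangements": cl.size, "oscillation": False,
                "interleaved": 0, "orientation_fdr": float("nan"),
                "chain_chromosomes": 0,
                "balanced_footprint_fraction": float("nan"),
            }
        )
    paths["clusters"] = out / "cluster_calls.tsv"
    pd.DataFrame(cluster_rows).to_csv(paths["clusters"], sep="\t", index=False)

    # per-class hotspot scans over simple SVs only
    simple_svs = [r for c in clusters if not c.is_complex for r in c.rearrangements]
    params = hotspots.PcfParams(gamma=config.gamma, kmin=config.kmin)
    hotspot_frames = []
    for sv_class in config.sv_classes:
        class_svs = [
            r
            for r in simple_svs
            if r.is_intrachromosomal
            and (
                (sv_class == "deletion" and r.orientation_class == "del_like")
                or (
                    sv_class == "tandem_duplication"
                    and r.orientation_class == "dup_like"
                )
                or (
                    sv_class == "inversion"
                    and r.orientation_class in ("hh_inv", "tt_inv")
                )
            )
            or (sv_class == "translocation" and not r.is_intrachromosomal)
        ]
        if len(class_svs) < 2 * params.kmin:
            logger.info("class %s: too few SVs (%d), skipped", sv_class,
                        len(class_svs))
            continue
        segs = run_cohort_scan(
            class_svs, grid, layout, config.n_reps, config.seed, params
        )
        found = hotspots.filter_and_collapse(
            segs, sv_class=sv_class, svs=class_svs,
            fdr_threshold=config.fdr_threshold,
        )
        hotspot_frames.append(hotspots.hotspots_to_frame(found))
        logger.info("class %s: %d segments, %d hotspots", sv_class, len(segs),
                    len(found))
    paths["hotspots"] = out / "hotspots.tsv"
    if hotspot_frames:
        pd.concat(hotspot_frames, ignore_index=True).to_csv(
            paths["hotspots"], sep="\t", index=False
        )
    else:
        hotspots.hotspots_to_frame([]).to_csv(
            paths["hotspots"], sep="\t", index=False
        )

    # grid written after scans so b_j of the last class is recorded
    grid.to_frame().to_csv(paths["grid"], sep="\t", index=False)

    # CNA layer summary
    cna_rows = []
    for sample in sorted(cn_profiles):
        segs = cn_profiles[sample]
        call = cna.call_wgd(segs)
        cna_rows.append(
            {
                "sample": sample,
                "psi_ave": call.psi_ave,
                "h_frac": call.h_frac,
                "is_wgd": call.is_wgd,
                "fraction_loh": cna.fraction_loh(segs),
            }
        )
    paths["cna"] = out / "cna_summary.tsv"
    pd.DataFrame(cna_rows).to_csv(paths["cna"], sep="\t", index=False)
    truth_path = out / "cna_truth.tsv"
    cn_truth.to_csv(truth_path, sep="\t", index=False)
    paths["cna_truth"] = truth_path

    # resolved config, serialized for provenance / re-runs
    paths["config"] = out / "resolved_config.yaml"
    import yaml

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(serialize_config(config), fh, sort_keys=True)
    return paths


def serialize_config(config: RunConfig) -> dict:
    synth = config.synth
    return {
        "out_dir": str(config.out_dir),
        "seed": config.seed,
        "n_reps": config.n_reps,
        "gamma": config.gamma,
        "kmin": config.kmin,
        "fdr_threshold": config.fdr_threshold,
        "cohort": config.cohort,
        "sv_classes": list(config.sv_classes),
        "synth": {
            "n_chroms": synth.n_chroms,
            "chrom_length": synth.chrom_length,
            "bin_size": synth.bin_size,
            "n_svs": synth.n_svs,
            "n_tumours": synth.n_tumours,
            "dispersion": synth.dispersion,
            "hotspot_bins": list(synth.hotspot_bins),
            "hotspot_multiplier": synth.hotspot_multiplier,
            "wgd_fraction": synth.wgd_fraction,
            "n_chromothripsis": synth.n_chromothripsis,
            "n_chromoplexy": synth.n_chromoplexy,
            "seed": synth.seed,
        },
    }


def config_from_dict(d: dict) -> RunConfig:
    synth_d = d.get("synth", {}) or {}
    synth = synthetic.SynthConfig(
        **{k: v for k, v in synth_d.items()
           if k in synthetic.SynthConfig.__dataclass_fields__}
    )
    kwargs = {
        k: v for k, v in d.items()
        if k in RunConfig.__dataclass_fields__ and k != "synth"
    }
    return RunConfig(synth=synth, **kwargs)
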