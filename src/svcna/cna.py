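"""Allele-specific copy-number state layer.

WGD classification from mean genome copy number and LOH fraction,
six-category CNA classification, ploidy-normalized SegCN records for
recurrence analysis, sample pass/fail logic and purity/ploidy
re-estimation, arm-level event calls and fraction-LOH.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GenomeLayout, Interval

CATEGORIES = ("HD", "LOH", "OLOSS", "NOC", "Gain", "AMP")

#: WGD inequality offset: is_wgd iff 2.9 - 2*H < psi_ave (strict).
WGD_INTERCEPT = 2.9

#: Clonal-cluster CCF window and purity concordance threshold for sample QC.
CLONAL_CCF_WINDOW = (0.95, 1.05)
PURITY_DISCORDANCE_MAX = 0.05
MIN_CLUSTER_SNV_FRACTION = 0.01


@dataclass
class CnSegment:
    """Allele-specific copy-number segment.

    ``c_maj``/``c_min`` expose the state of the largest clonal fraction;
    any further subclonal states are carried in ``subclonal_states`` as
    (c_maj, c_min, fraction) tuples.
    """

    interval: Interval
    c_maj: int
    c_min: int
    clonal_fraction: float = 1.0
    subclonal_states: list[tuple[int, int, float]] | None = None

    def __post_init__(self) -> None:
        if self.c_min < 0 or self.c_maj < self.c_min:
            raise ValueError("require c_maj >= c_min >= 0")
        if not (0.0 < self.clonal_fraction <= 1.0):
            raise ValueError("clonal_fraction must be in (0, 1]")

    @classmethod
    def from_states(
        cls, interval: Interval, states: list[tuple[int, int, float]]
    ) -> "CnSegment":
        """Build a segment from one or more (c_maj, c_min, fraction) states.

        The exposed state is the one with the largest fraction.
        """
        if not states:
            raise ValueError("no states supplied")
        top = max(states, key=lambda s: s[2])
        rest = [s for s in states if s is not top] or None
        return cls(interval, top[0], top[1], top[2], rest)

    @property
    def t_cn(self) -> int:
        return self.c_maj + self.c_min

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class WgdCall:
    psi_ave: float
    h_frac: float
    is_wgd: bool


@dataclass(frozen=True)
class PurityPloidyState:
    rho: float
    psi: float
    ccf_top: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if self.psi <= 0:
            raise ValueError("psi must be positive")


@dataclass(frozen=True)
class GisticRecord:
    interval: Interval
    seg_cn: float


@dataclass(frozen=True)
class SnvCluster:
    ccf: float
    n_snvs: int


def compute_psi_ave(segments: list[CnSegment]) -> tuple[float, float]:
    """Length-weighted mean total copy number and fraction with c_min == 0."""
    if not segments:
        raise ValueError("empty segment list")
    total = sum(s.length for s in segments)
    if total <= 0:
        raise ValueError("total segment length must be positive")
    psi_ave = sum(s.length * s.t_cn for s in segments) / total
    h_frac = sum(s.length for s in segments if s.c_min == 0) / total
    return psi_ave, h_frac


def call_wgd(segments: list[CnSegment]) -> WgdCall:
    """WGD iff 2.9 - 2H < psi_ave (strict; boundary equality is non-WGD)."""
    psi_ave, h = compute_psi_ave(segments)
    return WgdCall(psi_ave=psi_ave, h_frac=h, is_wgd=(WGD_INTERCEPT - 2.0 * h) < psi_ave)


def classify_segment(seg: CnSegment, is_wgd: bool) -> str:
    """Six-category CNA state with precedence HD > LOH > NOC > Gain > AMP > OLOSS.

    Thresholds double under WGD: LOH requires c_min == 0 with total copy
    number <= 2 (non-WGD) or <= 4 (WGD); NOC is 1+1 / 2+2; Gain is
    2 < t <= 5 / 4 < t <= 10; AMP is t > 5 / t > 10. OLOSS (WGD only)
    covers the remaining sub-baseline states with retained heterozygosity.
    """
    t = seg.t_cn
    if t == 0:
        return "HD"
    loh_max = 4 if is_wgd else 2
    if seg.c_min == 0 and t <= loh_max:
        return "LOH"
    noc = (2, 2) if is_wgd else (1, 1)
    if (seg.c_maj, seg.c_min) == noc:
        return "NOC"
    gain_lo, gain_hi = (4, 10) if is_wgd else (2, 5)
    if gain_lo < t <= gain_hi:
        return "Gain"
    if t > gain_hi:
        return "AMP"
    if not is_wgd:  # pragma: no cover - unreachable: cases above are exhaustive
        raise AssertionError(f"unclassifiable non-WGD state {seg.c_maj}+{seg.c_min}")
    return "OLOSS"


def seg_cn(seg: CnSegment, is_wgd: bool, male_x: bool = False) -> GisticRecord:
    """Ploidy-normalized per-segment copy number, clipped to [-2, 2].

    Non-WGD: t - 2 (t - 1 on male X). WGD: (t - 4) / 2 (t - 2 on male X).
    """
    t = seg.t_cn
    if is_wgd:
        value = float(t - 2) if male_x else (t - 4) / 2.0
    else:
        value = float(t - 1) if male_x else float(t - 2)
    return GisticRecord(seg.interval, min(2.0, max(-2.0, value)))


def update_purity_ploidy(state: PurityPloidyState) -> tuple[float, float]:
    """Re-estimate (rho, psi) from the top-CCF SNV cluster.

    rho_new = rho * ccf_top;
    psi_new = (rho * psi + 2 * (rho_new - rho)) / rho_new.
    """
    rho_new = state.rho * state.ccf_top
    if rho_new <= 0:
        raise ValueError("updated purity must be positive")
    psi_new = (state.rho * state.psi + 2.0 * (rho_new - state.rho)) / rho_new
    return rho_new, psi_new


def evaluate_cna_pass(
    clusters: list[SnvCluster], purity_a: float, purity_b: float
) -> tuple[bool, list[str]]:
    """Sample-level copy-number QC decision.

    Pass requires (1) a cluster with CCF in [0.95, 1.05] that has either the
    highest CCF or the most SNVs (clusters holding <1% of SNVs are dropped
    first), and (2) purity estimates agreeing to within 0.05.
    """
    reasons: list[str] = []
    total = sum(c.n_snvs for c in clusters)
    kept = [c for c in clusters if total == 0 or c.n_snvs >= MIN_CLUSTER_SNV_FRACTION * total]
    lo, hi = CLONAL_CCF_WINDOW
    clonal_ok = False
    if kept:
        max_ccf = max(c.ccf for c in kept)
        max_n = max(c.n_snvs for c in kept)
        clonal_ok = any(
            lo <= c.ccf <= hi and (c.ccf == max_ccf or c.n_snvs == max_n)
            for c in kept
        )
    if not clonal_ok:
        reasons.append("no clonal cluster")
    if not abs(purity_a - purity_b) < PURITY_DISCORDANCE_MAX:
        reasons.append("purity discordance")
    return not reasons, reasons


def arm_level_events(
    segments: list[CnSegment], layout: GenomeLayout, is_wgd: bool,
    min_fraction: float = 0.5,
) -> dict[tuple[str, str], list[str]]:
    """Per-arm category calls: summed segment length per category > 50% of arm.

    NOC spans are not events and are never reported. Returns a mapping
    (chrom, arm) -> list of categories called on the arm.
    """
    calls: dict[tuple[str, str], list[str]] = {}
    for chrom, arm, arm_iv in layout.arms():
        totals: dict[str, int] = {}
        for seg in segments:
            ov = seg.interval.overlap_length(arm_iv)
            if ov > 0:
                cat = classify_segment(seg, is_wgd)
                totals[cat] = totals.get(cat, 0) + ov
        hit = [c for c in CATEGORIES if c != "NOC"
               and totals.get(c, 0) > min_fraction * arm_iv.length]
        if hit:
            calls[(chrom, arm)] = hit
    return calls


def fraction_loh(segments: list[CnSegment]) -> float:
    """Length-weighted genome fraction with c_min == 0 and t_CN >= 1."""
    if not segments:
        raise ValueError("empty segment list")
    total = sum(s.length for s in segments)
    if total <= 0:
        raise ValueError("total segment length must be positive")
    loh = sum(s.length for s in segments if s.c_min == 0 and s.t_cn >= 1)
    return loh / total


# ---------------------------------------------------------------------------
# I/O: Battenberg-like 1-based inclusive segment tables
# ---------------------------------------------------------------------------

def read_segments_tsv(path: str) -> dict[str, list[CnSegment]]:
    """Read per-sample segments from a 1-based inclusive TSV.

    Expected columns: sample, chr, startpos, endpos, nMaj1_A, nMin1_A,
    frac1_A and optionally nMaj2_A, nMin2_A, frac2_A for a second
    subclonal state.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str, "sample": str})
    out: dict[str, list[CnSegment]] = {}
    has2 = {"nMaj2_A", "nMin2_A", "frac2_A"}.issubset(df.columns)
    for row in df.itertuples():
        iv = Interval(row.chr, int(row.startpos) - 1, int(row.endpos))
        states = [(int(row.nMaj1_A), int(row.nMin1_A), float(row.frac1_A))]
        if has2 and pd.notna(getattr(row, "nMaj2_A")):
            states.append(
                (int(row.nMaj2_A), int(row.nMin2_A), float(row.frac2_A))
            )
        out.setdefault(row.sample, []).append(CnSegment.from_states(iv, states))
    return out


def write_gistic_tsv(
    records: dict[str, list[GisticRecord]], path: str, n_markers_per_mb: int = 100
) -> None:
    """Write SegCN records as a GISTIC-style segmentation table (1-based)."""
    rows = []
    for sample, recs in records.items():
        for r in recs:
            rows.append(
                {
                    "sample": sample,
                    "chrom": r.interval.chrom,
                    "start": r.interval.start + 1,
                    "end": r.interval.end,
                    "n_markers": max(
                        1, int(r.interval.length * n_markers_per_mb / 1e6)
                    ),
                    "seg_cn": r.seg_cn,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
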