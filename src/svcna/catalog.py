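"""SV catalogue: breakends, consensus merging, clustering and simple classes.

Orientation convention (BEDPE strand columns, records ordered bnd1 <= bnd2):
``(+,-)`` deletion-like, ``(-,+)`` tandem-duplication-like, ``(+,+)``
head-to-head inversion, ``(-,-)`` tail-to-tail inversion. ``+`` means the
retained fragment extends toward lower coordinates (the junction continues
on the higher side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Interval

MERGE_TOL = 400
CN_BOUNDARY_TOL = 3_000
MIN_TUMOUR_SUPPORT = 0.02
FOOTPRINT_GAP = 10_000
CLUSTER_GAP = 1_000_000
DELETION_BRIDGE_TOL = 10_000

ORIENTATION_CLASSES = {
    ("+", "-"): "del_like",
    ("-", "+"): "dup_like",
    ("+", "+"): "hh_inv",
    ("-", "-"): "tt_inv",
}

SIMPLE_CLASS_BY_ORIENTATION = {
    "del_like": "deletion",
    "dup_like": "tandem_duplication",
}


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    pos: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


@dataclass(frozen=True)
class Rearrangement:
    """One SV junction joining two oriented breakends (bnd1 <= bnd2)."""

    id: str
    sample_id: str
    bnd1: Breakend
    bnd2: Breakend
    callers: frozenset[str] = frozenset()
    tumour_support_frac: float = 1.0
    normal_support: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumour_support_frac <= 1.0):
            raise ValueError("tumour_support_frac must be in [0, 1]")
        if (self.bnd2.chrom, self.bnd2.pos) < (self.bnd1.chrom, self.bnd1.pos):
            b1, b2 = self.bnd1, self.bnd2
            object.__setattr__(self, "bnd1", b2)
            object.__setattr__(self, "bnd2", b1)

    @property
    def is_intrachromosomal(self) -> bool:
        return self.bnd1.chrom == self.bnd2.chrom

    @property
    def length(self) -> int | None:
        if not self.is_intrachromosomal:
            return None
        return self.bnd2.pos - self.bnd1.pos

    @property
    def orientation_pair(self) -> tuple[str, str]:
        return (self.bnd1.orientation, self.bnd2.orientation)

    @property
    def orientation_class(self) -> str | None:
        if not self.is_intrachromosomal:
            return None
        return ORIENTATION_CLASSES[self.orientation_pair]

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.bnd1, self.bnd2)


@dataclass
class Footprint:
    interval: Interval
    breakends: list[tuple[Breakend, Rearrangement]] = field(default_factory=list)


@dataclass
class SvCluster:
    rearrangements: list[Rearrangement]
    footprints: list[Footprint] = field(default_factory=list)
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.rearrangements)

    @property
    def is_complex(self) -> bool:
        return self.size >= 3

    def chromosomes(self) -> set[str]:
        out = set()
        for r in self.rearrangements:
            out.add(r.bnd1.chrom)
            out.add(r.bnd2.chrom)
        return out


@dataclass(frozen=True)
class OrientationCounts:
    del_like: int = 0
    dup_like: int = 0
    hh_inv: int = 0
    tt_inv: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.del_like, self.dup_like, self.hh_inv, self.tt_inv)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


# ---------------------------------------------------------------------------
# Consensus merging
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _near_boundary(bnd: Breakend, boundaries: dict[str, np.ndarray], tol: int) -> bool:
    pos = boundaries.get(bnd.chrom)
    if pos is None or len(pos) == 0:
        return False
    i = np.searchsorted(pos, bnd.pos)
    for j in (i - 1, i):
        if 0 <= j < len(pos) and abs(int(pos[j]) - bnd.pos) <= tol:
            return True
    return False


def cn_boundaries_from_segments(segments) -> dict[str, np.ndarray]:
    """Sorted CN segment boundary positions per chromosome."""
    by_chrom: dict[str, set[int]] = {}
    for seg in segments:
        s = by_chrom.setdefault(seg.interval.chrom, set())
        s.add(seg.interval.start)
        s.add(seg.interval.end)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}


def merge_consensus(
    callsets: dict[str, list[Rearrangement]],
    cn_boundaries: dict[str, np.ndarray] | None = None,
    layout: GenomeLayout | None = None,
    tol: int = MERGE_TOL,
    boundary_tol: int = CN_BOUNDARY_TOL,
    known_callers: set[str] | None = None,
) -> list[Rearrangement]:
    """Graph-based multi-caller consensus merge.

    Pre-filters calls with normal-sample support, tumour support below 2%,
    or a breakend in the mask / on a chromosome absent from the layout.
    Calls from different callers are joined when both breakends agree within
    ``tol`` bp and orientations match; merged variants are retained when
    supported by >= 2 callers, or by one caller with a breakend within
    ``boundary_tol`` of a copy-number segment boundary.
    """
    if known_callers is not None:
        unknown = set(callsets) - set(known_callers)
        if unknown:
            raise ValueError(f"unknown caller(s) in config: {sorted(unknown)}")
    calls: list[Rearrangement] = []
    for caller in sorted(callsets):
        for r in callsets[caller]:
            r = r if r.callers else replace(r, callers=frozenset({caller}))
            if r.normal_support > 0 or r.tumour_support_frac < MIN_TUMOUR_SUPPORT:
                continue
            if layout is not None:
                if (r.bnd1.chrom not in layout.chrom_lengths
                        or r.bnd2.chrom not in layout.chrom_lengths):
                    continue
                if (layout.in_mask(r.bnd1.chrom, r.bnd1.pos)
                        or layout.in_mask(r.bnd2.chrom, r.bnd2.pos)):
                    continue
            calls.append(r)

    calls.sort(key=lambda r: (r.bnd1.chrom, r.bnd1.pos, r.bnd2.chrom, r.bnd2.pos))
    uf = _UnionFind(len(calls))
    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if b.bnd1.chrom != a.bnd1.chrom or b.bnd1.pos - a.bnd1.pos > tol:
                break
            if (
                a.sample_id == b.sample_id
                and a.bnd2.chrom == b.bnd2.chrom
                and abs(a.bnd2.pos - b.bnd2.pos) <= tol
                and a.orientation_pair == b.orientation_pair
            ):
                uf.union(i, j)

    groups: dict[int, list[Rearrangement]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(calls[i])

    merged: list[Rearrangement] = []
    for members in groups.values():
        members.sort(key=lambda r: (sorted(r.callers), r.bnd1.pos, r.bnd2.pos))
        rep = members[0]
        callers = frozenset().union(*(m.callers for m in members))
        rec = replace(rep, callers=callers)
        if len(callers) >= 2:
            merged.append(rec)
        elif cn_boundaries is not None and (
            _near_boundary(rec.bnd1, cn_boundaries, boundary_tol)
            or _near_boundary(rec.bnd2, cn_boundaries, boundary_tol)
        ):
            merged.append(rec)
    merged.sort(key=lambda r: (r.bnd1.chrom, r.bnd1.pos, r.bnd2.chrom, r.bnd2.pos))
    return merged


# ---------------------------------------------------------------------------
# Footprint / cluster grouping
# ---------------------------------------------------------------------------

def _build_footprints(
    svs: list[Rearrangement], d_fp: int
) -> list[Footprint]:
    entries: list[tuple[str, int, Breakend, Rearrangement]] = []
    for r in svs:
        for b in r.breakends:
            entries.append((b.chrom, b.pos, b, r))
    entries.sort(key=lambda e: (e[0], e[1]))
    footprints: list[Footprint] = []
    run: list[tuple[str, int, Breakend, Rearrangement]] = []
    for e in entries:
        if run and (e[0] != run[-1][0] or e[1] - run[-1][1] > d_fp):
            footprints.append(_close_footprint(run))
            run = []
        run.append(e)
    if run:
        footprints.append(_close_footprint(run))
    return footprints


def _close_footprint(run) -> Footprint:
    chrom = run[0][0]
    lo = run[0][1]
    hi = run[-1][1]
    iv = Interval(chrom, lo, hi + 1)
    return Footprint(iv, [(b, r) for _, _, b, r in run])


def group_clusters(
    svs: list[Rearrangement],
    d_fp: int = FOOTPRINT_GAP,
    d_cl: int = CLUSTER_GAP,
) -> list[SvCluster]:
    """Partition rearrangements into clusters by breakend proximity.

    Rearrangements are linked when any two of their breakends lie within
    ``d_cl`` on the same chromosome; clusters are the connected components.
    Footprints (maximal breakend runs with successive gaps <= ``d_fp``) are
    computed per cluster. Every SV ends up in exactly one cluster.
    """
    if d_fp > d_cl:
        raise ValueError("require d_fp <= d_cl")
    if not svs:
        return []
    uf = _UnionFind(len(svs))
    entries: list[tuple[str, int, int]] = []
    for i, r in enumerate(svs):
        entries.append((r.bnd1.chrom, r.bnd1.pos, i))
        entries.append((r.bnd2.chrom, r.bnd2.pos, i))
    entries.sort(key=lambda e: (e[0], e[1]))
    for (c1, p1, i1), (c2, p2, i2) in zip(entries, entries[1:]):
        if c1 == c2 and p2 - p1 <= d_cl:
            uf.union(i1, i2)
    groups: dict[int, list[Rearrangement]] = {}
    for i, r in enumerate(svs):
        groups.setdefault(uf.find(i), []).append(r)
    clusters = []
    for members in groups.values():
        members.sort(key=lambda r: (r.bnd1.chrom, r.bnd1.pos, r.bnd2.chrom, r.bnd2.pos))
        clusters.append(SvCluster(members, _build_footprints(members, d_fp)))
    clusters.sort(
        key=lambda c: (c.rearrangements[0].bnd1.chrom, c.rearrangements[0].bnd1.pos)
    )
    return clusters


# ---------------------------------------------------------------------------
# Simple-SV classification
# ---------------------------------------------------------------------------

def _cn_step_near(
    bnd: Breakend, boundaries: dict[str, np.ndarray] | None, tol: int
) -> bool:
    if boundaries is None:
        return False
    return _near_boundary(bnd, boundaries, tol)


def classify_simple(
    cluster: SvCluster,
    cn_boundaries: dict[str, np.ndarray] | None = None,
    inversion_tol: int = FOOTPRINT_GAP,
    bridge_tol: int = DELETION_BRIDGE_TOL,
    cn_tol: int = CN_BOUNDARY_TOL,
) -> str:
    """Label a cluster of <= 2 rearrangements.

    Size 1, intrachromosomal: (+,-) deletion; (-,+) tandem duplication;
    same-orientation lone inversion junction is simple_unclassified.
    Size 1, interchromosomal: unbalanced_translocation when a CN step lies
    near either breakend, else simple_unclassified.
    Size 2: two opposite inversion junctions sharing footprints make a
    balanced_inversion; a reciprocal interchromosomal pair makes a
    balanced_translocation when the breakend gaps stay within the
    deletion-bridge tolerance and no larger CN change is implied, else
    unbalanced_translocation. Anything else is simple_unclassified.
    """
    if cluster.size >= 3:
        raise ValueError("complex cluster: route to complex_events")
    if cluster.size == 1:
        r = cluster.rearrangements[0]
        if r.is_intrachromosomal:
            return SIMPLE_CLASS_BY_ORIENTATION.get(
                r.orientation_class, "simple_unclassified"
            )
        if _cn_step_near(r.bnd1, cn_boundaries, cn_tol) or _cn_step_near(
            r.bnd2, cn_boundaries, cn_tol
        ):
            return "unbalanced_translocation"
        return "simple_unclassified"

    a, b = cluster.rearrangements
    if (
        a.is_intrachromosomal
        and b.is_intrachromosomal
        and a.bnd1.chrom == b.bnd1.chrom
        and {a.orientation_class, b.orientation_class} == {"hh_inv", "tt_inv"}
        and abs(a.bnd1.pos - b.bnd1.pos) <= inversion_tol
        and abs(a.bnd2.pos - b.bnd2.pos) <= inversion_tol
    ):
        return "balanced_inversion"
    if (
        not a.is_intrachromosomal
        and not b.is_intrachromosomal
        and a.bnd1.chrom == b.bnd1.chrom
        and a.bnd2.chrom == b.bnd2.chrom
    ):
        gap1 = abs(a.bnd1.pos - b.bnd1.pos)
        gap2 = abs(a.bnd2.pos - b.bnd2.pos)
        reciprocal = (
            a.bnd1.orientation != b.bnd1.orientation
            and a.bnd2.orientation != b.bnd2.orientation
        )
        if reciprocal and gap1 <= bridge_tol and gap2 <= bridge_tol:
            return "balanced_translocation"
        return "unbalanced_translocation"
    return "simple_unclassified"


def orientation_counts(cluster: SvCluster) -> OrientationCounts:
    """Counts of intrachromosomal junction orientation classes."""
    counts = {k: 0 for k in ("del_like", "dup_like", "hh_inv", "tt_inv")}
    for r in cluster.rearrangements:
        oc = r.orientation_class
        if oc is not None:
            counts[oc] += 1
    return OrientationCounts(**counts)


# ---------------------------------------------------------------------------
# Kinase fusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    kinase_domain: Interval | None = None
    expressed: bool = True

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class FusionRecord:
    rearrangement_id: str
    partner_gene: str
    kinase_gene: str


def _in_gene(bnd: Breakend, gene: GeneModel) -> bool:
    return bnd.chrom == gene.chrom and gene.start <= bnd.pos < gene.end


def _kinase_side_ok(bnd: Breakend, gene: GeneModel) -> bool:
    """Breakend 5' of the kinase domain, retaining the domain-containing side."""
    dom = gene.kinase_domain
    if gene.strand == "+":
        # retained fragment must extend toward higher coordinates
        return bnd.pos <= dom.start and bnd.orientation == "-"
    return bnd.pos >= dom.end and bnd.orientation == "+"


def _partner_side_ok(bnd: Breakend, gene: GeneModel) -> bool:
    """Breakend retains the 5' portion of the partner gene."""
    if gene.strand == "+":
        return bnd.orientation == "+"
    return bnd.orientation == "-"


def detect_kinase_fusions(
    svs: list[Rearrangement],
    genes: list[GeneModel],
    kinase_genes: set[str],
) -> list[FusionRecord]:
    """Junctions fusing a partner gene 5' end to a kinase gene's kinase domain.

    The kinase domain must lie 3' of the junction in the kinase gene and the
    predicted transcription strands must be compatible. Kinase genes without
    a domain annotation are skipped with a warning.
    """
    kinase_models = []
    for g in genes:
        if g.name in kinase_genes:
            if g.kinase_domain is None:
                warnings.warn(f"kinase gene {g.name} lacks a domain annotation; skipped")
                continue
            kinase_models.append(g)
    partner_models = [g for g in genes if g.name not in kinase_genes]
    out: list[FusionRecord] = []
    for r in svs:
        for kb, pb in ((r.bnd1, r.bnd2), (r.bnd2, r.bnd1)):
            for kg in kinase_models:
                if not (_in_gene(kb, kg) and _kinase_side_ok(kb, kg)):
                    continue
                for pg in partner_models:
                    if _in_gene(pb, pg) and _partner_side_ok(pb, pg):
                        out.append(FusionRecord(r.id, pg.name, kg.name))
    return out


# ---------------------------------------------------------------------------
# BEDPE I/O
# ---------------------------------------------------------------------------

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]
EXTRA_COLUMNS = ["sample", "callers", "tumour_support_frac", "normal_support"]


def read_bedpe(path: str) -> list[Rearrangement]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    missing = [c for c in BEDPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"BEDPE missing columns: {missing}")
    out = []
    for row in df.itertuples():
        callers = frozenset(
            str(getattr(row, "callers", "")).split(",")
        ) - {"", "nan"}
        out.append(
            Rearrangement(
                id=str(row.name),
                sample_id=str(getattr(row, "sample", "S0")),
                bnd1=Breakend(row.chrom1, int(row.start1), row.strand1),
                bnd2=Breakend(row.chrom2, int(row.start2), row.strand2),
                callers=callers,
                tumour_support_frac=float(getattr(row, "tumour_support_frac", 1.0)),
                normal_support=int(getattr(row, "normal_support", 0)),
            )
        )
    return out


def write_bedpe(svs: list[Rearrangement], path: str) -> None:
    rows = []
    for r in svs:
        rows.append(
            {
                "chrom1": r.bnd1.chrom, "start1": r.bnd1.pos, "end1": r.bnd1.pos + 1,
                "chrom2": r.bnd2.chrom, "start2": r.bnd2.pos, "end2": r.bnd2.pos + 1,
                "name": r.id, "score": ".",
                "strand1": r.bnd1.orientation, "strand2": r.bnd2.orientation,
                "sample": r.sample_id,
                "callers": ",".join(sorted(r.callers)),
                "tumour_support_frac": r.tumour_support_frac,
                "normal_support": r.normal_support,
            }
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS + EXTRA_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_cluster_assignments(clusters: list[SvCluster], path: str) -> None:
    rows = []
    for ci, cl in enumerate(clusters):
        for r in cl.rearrangements:
            rows.append({"sv_id": r.id, "cluster": ci, "size": cl.size,
                         "label": cl.label or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
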