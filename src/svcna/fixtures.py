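"""Deterministic complex-event cluster templates for testing and benchmarks.

Each builder returns (SvCluster, cn_segments) constructed to satisfy or
violate specific chromothripsis/chromoplexy criteria.
"""

from __future__ import annotations

import numpy as np

from .catalog import Breakend, Rearrangement, SvCluster, group_clusters
from .cna import CnSegment
from .genome import Interval


def _mk(id_, c1, p1, o1, c2, p2, o2, sample="S0") -> Rearrangement:
    return Rearrangement(id_, sample, Breakend(c1, int(p1), o1),
                         Breakend(c2, int(p2), o2))


def _cluster(svs: list[Rearrangement]) -> SvCluster:
    clusters = group_clusters(svs, d_fp=10_000, d_cl=10_000_000_000)
    assert len(clusters) == 1
    return clusters[0]


def make_chromothripsis_cluster(
    n_junctions: int = 12,
    chrom: str = "chr1",
    origin: int = 10_000_000,
    spacing: int = 120_000,
    oscillating_cn: bool = True,
    interleaved: bool = True,
    balanced_orientations: bool = True,
    seed: int = 0,
) -> tuple[SvCluster, list[CnSegment]]:
    """A shatter-like cluster; flags switch individual criteria off.

    ``interleaved=True`` lays junction spans in a crossing ladder
    (span i = [x_i, x_{i+k}]); ``False`` nests them. Orientations cycle
    through all four classes when balanced, else all deletion-like.
    """
    rng = np.random.default_rng(seed)
    orients = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
    svs = []
    for i in range(n_junctions):
        o1, o2 = orients[i % 4] if balanced_orientations else ("+", "-")
        if interleaved:
            a = origin + i * spacing
            b = origin + (i + 2) * spacing + spacing // 2
        else:
            # strictly nested spans: no crossings
            a = origin + i * spacing
            b = origin + (2 * n_junctions + 4 - i) * spacing
        jitter = int(rng.integers(0, spacing // 10))
        svs.append(_mk(f"ct{i}", chrom, a + jitter, o1, chrom, b + jitter, o2))
    # CN segments tiling the cluster span
    span_lo = min(r.bnd1.pos for r in svs) - spacing
    span_hi = max(r.bnd2.pos for r in svs) + spacing
    n_seg = 8
    edges = np.linspace(span_lo, span_hi, n_seg + 1).astype(int)
    segs = []
    for i in range(n_seg):
        if oscillating_cn:
            c_maj, c_min = (2, 0) if i % 2 == 0 else (1, 0)
        else:
            c_maj, c_min = 1, 1
        segs.append(CnSegment(Interval(chrom, int(edges[i]), int(edges[i + 1])),
                              c_maj, c_min))
    return _cluster(svs), segs


def make_chromoplexy_cluster(
    n_chroms: int = 3,
    balanced: bool = True,
    n_extra: int = 0,
    gap: int = 1_000,
    seed: int = 0,
) -> SvCluster:
    """A chained reciprocal-translocation cycle across ``n_chroms`` chromosomes.

    ``balanced=False`` separates the paired breakends beyond the deletion
    bridge tolerance so footprints stop looking reciprocal. ``n_extra``
    appends extra intrachromosomal junctions to inflate the cluster size.
    """
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    anchors = {c: 20_000_000 + 1_000_000 * i for i, c in enumerate(chroms)}
    offset = gap if balanced else 500_000
    svs = []
    for i, c in enumerate(chroms):
        nxt = chroms[(i + 1) % n_chroms]
        svs.append(
            _mk(f"cp{i}", c, anchors[c], "+", nxt, anchors[nxt] + offset, "-")
        )
    for j in range(n_extra):
        c = chroms[0]
        base = anchors[c] + 300_000 + j * 40_000
        svs.append(_mk(f"cpx{j}", c, base, "+", c, base + 20_000, "-"))
    return _cluster(svs)
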