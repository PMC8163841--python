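"""Anchor-aligned composites, heat maps, +1 distance statistics, dyad
densities, Reb1 promoter scoring and grouping.

All anchor-aligned operations are strand-oriented: offsets are
downstream-positive in the anchor's orientation, and minus-strand
windows are reversed before aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nucposlab.dyad_tracks import DyadTrack, OccupancyTrack
from nucposlab.io_formats import Anchor
from nucposlab.nucleosome_calling import PlusOneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class CompositeProfile:
    offsets: np.ndarray  # -halfwidth..+halfwidth
    mean: np.ndarray
    n_contributing: np.ndarray


@dataclass
class HeatmapMatrix:
    values: np.ndarray  # rows = anchors (sorted), columns = offsets
    row_ids: list[str]
    offsets: np.ndarray
    sort_key_name: str


@dataclass
class DistanceStats:
    distances: pd.Series  # per gene, signed bp (downstream-positive)
    median: float
    iqr: tuple[float, float]
    n: int


def _extract_window(
    values: Mapping[str, np.ndarray], anchor: Anchor, halfwidth: int
) -> np.ndarray | None:
    arr = values[anchor.contig]
    lo, hi = anchor.pos - halfwidth, anchor.pos + halfwidth + 1
    if lo < 0 or hi > len(arr):
        return None
    w = arr[lo:hi]
    return w[::-1] if anchor.strand == "-" else w


def composite_profile(
    track: OccupancyTrack,
    anchors: Sequence[Anchor],
    halfwidth: int = 1000,
    per_anchor_norm: bool = True,
    norm: str = "mean",
) -> CompositeProfile:
    """Strand-oriented per-offset mean of anchor-centered windows.

    With ``per_anchor_norm`` each (2*halfwidth+1)-bp window is divided by
    its own mean (``norm="max"`` divides by its maximum); windows whose
    normalizer is 0 are dropped with a log message, as are windows that
    do not fit inside their contig.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    width = 2 * halfwidth + 1
    total = np.zeros(width)
    n = np.zeros(width, dtype=np.int64)
    dropped = 0
    for a in anchors:
        w = _extract_window(track.values, a, halfwidth)
        if w is None:
            dropped += 1
            continue
        if per_anchor_norm:
            denom = np.nanmean(w) if norm == "mean" else np.nanmax(w)
            if not denom:
                dropped += 1
                continue
            w = w / denom
        ok = ~np.isnan(w)
        total[ok] += w[ok]
        n += ok
    if dropped:
        logger.info("composite_profile: %d anchors dropped", dropped)
    if not n.any():
        raise ValueError("no anchor windows survive")
    mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return CompositeProfile(np.arange(-halfwidth, halfwidth + 1), mean, n)


def heatmap_matrix(
    track: OccupancyTrack,
    anchors: Sequence[Anchor],
    halfwidth: int,
    sort_key: str,
    per_anchor_norm: bool = True,
) -> HeatmapMatrix:
    """Anchor-aligned matrix with rows ordered by sort key, descending.

    Anchors lacking the key (or not fitting their contig) are dropped
    with a log message; ties in the key are broken by anchor id.
    """
    rows: list[tuple[float, str, np.ndarray]] = []
    dropped = 0
    for a in anchors:
        if sort_key not in a.sort_keys:
            dropped += 1
            continue
        w = _extract_window(track.values, a, halfwidth)
        if w is None:
            dropped += 1
            continue
        if per_anchor_norm:
            denom = np.nanmean(w)
            if not denom:
                dropped += 1
                continue
            w = w / denom
        rows.append((float(a.sort_keys[sort_key]), a.id, w))
    if dropped:
        logger.info("heatmap: %d anchors dropped", dropped)
    if not rows:
        raise ValueError("no anchors with the requested sort key survive")
    rows.sort(key=lambda t: (-t[0], t[1]))
    return HeatmapMatrix(
        np.vstack([r[2] for r in rows]),
        [r[1] for r in rows],
        np.arange(-halfwidth, halfwidth + 1),
        sort_key,
    )


def reb1_score(
    signal: OccupancyTrack,
    plus1_anchors: Sequence[Anchor],
    window: int = 120,
    upstream_offset: int = 160,
) -> dict[str, float]:
    """Mean signal in a window upstream of each +1 dyad, gene-oriented.

    The window spans ``window`` bp whose downstream edge sits
    ``upstream_offset`` bp upstream of the +1 dyad: for a plus-strand
    +1 at d the window is [d − upstream_offset − window,
    d − upstream_offset). Anchors whose window leaves the contig are
    dropped.
    """
    scores: dict[str, float] = {}
    for a in plus1_anchors:
        arr = signal.values[a.contig]
        if a.sign > 0:
            lo = a.pos - upstream_offset - window
            hi = a.pos - upstream_offset
        else:
            lo = a.pos + upstream_offset + 1
            hi = a.pos + upstream_offset + window + 1
        if lo < 0 or hi > len(arr):
            logger.info("reb1_score: anchor %s window outside contig, dropped", a.id)
            continue
        scores[a.id] = float(np.mean(arr[lo:hi]))
    return scores


def top_fraction(scores: Mapping[str, float], fraction: float = 0.125) -> set[str]:
    """Ids of the top ``fraction`` of anchors by score (ceil, ties by id)."""
    if not scores:
        return set()
    n = int(np.ceil(fraction * len(scores)))
    ordered = sorted(scores, key=lambda k: (-scores[k], k))
    return set(ordered[:n])


def group_promoters(
    reb1_hits: Sequence[Anchor],
    pwm_hits: Sequence[Anchor],
    plus1: Sequence[PlusOneAnnotation],
    genes: Sequence[Anchor],
    pwm_colocation: int = 50,
    upstream_limit: int = 400,
) -> dict[str, int]:
    """Group genes by Reb1-site orientation relative to transcription.

    A Reb1 hit qualifies for a gene when a PWM hit lies within
    ±pwm_colocation bp of it and the hit is within ``upstream_limit`` bp
    upstream of that gene's +1 dyad (gene orientation). Group 1: PWM on
    the gene's sense strand; group 2: antisense; group 3: the site
    serves two divergent genes (bidirectional promoter), overriding 1/2.
    Returns gene_id → group; ungrouped genes are omitted.
    """
    plus1_by_gene = {p.gene_id: p for p in plus1}
    gene_anchor = {g.id: g for g in genes}

    # gene → (reb1 hit, matched pwm) for qualifying sites
    matched: dict[str, tuple[Anchor, Anchor]] = {}
    served: dict[int, list[str]] = {}  # reb1-hit index → genes it serves
    for hi, hit in enumerate(reb1_hits):
        pwm_near = [
            p
            for p in pwm_hits
            if p.contig == hit.contig and abs(p.pos - hit.pos) <= pwm_colocation
        ]
        if not pwm_near:
            continue
        pwm = min(pwm_near, key=lambda p: (abs(p.pos - hit.pos), p.pos))
        for g in genes:
            ann = plus1_by_gene.get(g.id)
            if ann is None or ann.plus1_dyad is None or g.contig != hit.contig:
                continue
            upstream = (ann.plus1_dyad - hit.pos) * g.sign
            if 0 < upstream <= upstream_limit:
                matched.setdefault(g.id, (hit, pwm))
                served.setdefault(hi, []).append(g.id)

    groups: dict[str, int] = {}
    bidirectional: set[str] = set()
    for hi, gene_ids in served.items():
        strands = {gene_anchor[g].strand for g in gene_ids}
        if len(gene_ids) >= 2 and strands == {"+", "-"}:
            bidirectional.update(gene_ids)
    for gene_id, (hit, pwm) in matched.items():
        if gene_id in bidirectional:
            groups[gene_id] = 3
        elif pwm.strand == gene_anchor[gene_id].strand:
            groups[gene_id] = 1
        else:
            groups[gene_id] = 2
    return groups


def plus1_distance_stats(
    invitro: Sequence[PlusOneAnnotation],
    invivo: Sequence[PlusOneAnnotation],
) -> DistanceStats:
    """Signed in vitro − in vivo +1 dyad distances (downstream-positive)."""
    vivo = {p.gene_id: p for p in invivo if p.plus1_dyad is not None}
    dist: dict[str, float] = {}
    for p in invitro:
        q = vivo.get(p.gene_id)
        if q is None or p.plus1_dyad is None:
            continue
        sign = -1 if p.strand == "-" else 1
        dist[p.gene_id] = (p.plus1_dyad - q.plus1_dyad) * sign
    if not dist:
        raise ValueError("no genes with +1 defined in both annotation sets")
    s = pd.Series(dist)
    return DistanceStats(
        s,
        float(s.median()),
        (float(s.quantile(0.25)), float(s.quantile(0.75))),
        len(s),
    )


def dyad_density(
    dyads: DyadTrack,
    anchors: Sequence[Anchor],
    halfwidth: int = 1000,
    bin_size: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density of oriented dyad offsets pooled over anchors.

    Returns (bin_centers, density) with the density normalized to
    integrate to 1 over [−halfwidth, +halfwidth].
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    offsets: list[np.ndarray] = []
    for a in anchors:
        arr = dyads.counts[a.contig]
        lo = max(a.pos - halfwidth, 0)
        hi = min(a.pos + halfwidth + 1, len(arr))
        local = arr[lo:hi]
        pos = np.flatnonzero(local)
        if pos.size:
            off = (pos + lo - a.pos) * a.sign
            offsets.append(np.repeat(off, local[pos]))
    if not offsets:
        raise ValueError("no dyads in any anchor window")
    pooled = np.concatenate(offsets)
    edges = np.arange(-halfwidth, halfwidth + bin_size + 1, bin_size)
    counts, _ = np.histogram(pooled, bins=edges)
    density = counts / (counts.sum() * bin_size)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, density
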