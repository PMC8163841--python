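"""Joint dyad-region set, normalized occupancy matrix, and PCA/K-means
clustering of nucleosome positions across samples.

Per-sample dyad calls are enlarged to 20-bp regions, merged across
samples, filtered against tile borders and a blacklist, and fragment
centers are counted per region and sample. Counts are normalized as

    v = log2(((x / sum(x)) * 1000) + 0.001)

where sum(x) is the per-sample total over all regions. The region ×
sample matrix is decomposed by PCA (centering only) and the scores are
clustered with K-means; clusters are summarized by mean normalized
occupancy per sample and row-scaled for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from nucposlab.io_formats import Fragment
from nucposlab.nucleosome_calling import NucleosomeCall


@dataclass
class DyadRegionSet:
    """Sorted, pairwise-disjoint (contig, start, end) regions."""

    regions: list[tuple[str, int, int]]
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions, columns=["contig", "start", "end"])


@dataclass
class OccupancyMatrix:
    counts: pd.DataFrame  # regions x samples, integer
    normalized: pd.DataFrame  # same shape, v = log2(((x/sum(x))*1000)+0.001)


@dataclass
class ClusterResult:
    pc_scores: np.ndarray  # regions x components
    explained_variance: np.ndarray  # variance ratio per component
    labels: np.ndarray  # 1..k per region
    cluster_sample_score: pd.DataFrame  # clusters x samples, mean v
    row_scaled_score: pd.DataFrame  # clusters x samples, z-scored rows
    cluster_order: list[int]  # hierarchical leaf order of clusters


def _merge_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(intervals):
        if merged and merged[-1][0] == contig and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (contig, prev[1], max(prev[2], end))
        else:
            merged.append((contig, start, end))
    return merged


def build_joint_dyad_set(
    calls_by_sample: Mapping[str, Sequence[NucleosomeCall]],
    contig_lengths: Mapping[str, int],
    enlarge: int = 20,
    border_exclusion: int = 250,
    blacklist: Sequence[tuple[str, int, int]] = (),
    tile_boundaries: Mapping[str, Sequence[int]] | None = None,
) -> DyadRegionSet:
    """Enlarge per-sample dyads, merge across samples, filter.

    Each dyad d becomes [d − enlarge/2, d + enlarge/2); overlapping
    windows are joined. Joined regions within ``border_exclusion`` bp of
    a tile border (contig ends plus any listed internal boundaries) or
    overlapping the blacklist are removed.
    """
    if enlarge % 2:
        raise ValueError("enlarge must be even")
    if not calls_by_sample:
        raise ValueError("need calls from at least one sample")
    half = enlarge // 2
    windows = [
        (c.contig, max(c.dyad - half, 0), min(c.dyad + half, contig_lengths[c.contig]))
        for calls in calls_by_sample.values()
        for c in calls
    ]
    merged = _merge_intervals(windows)

    borders: dict[str, list[int]] = {
        c: [0, n] for c, n in contig_lengths.items()
    }
    if tile_boundaries:
        for c, bs in tile_boundaries.items():
            borders[c].extend(bs)

    def near_border(contig: str, start: int, end: int) -> bool:
        # region counts as near a border when any part of it comes within
        # border_exclusion bp of the border position
        return any(
            start - border_exclusion < b < end + border_exclusion
            for b in borders.get(contig, [])
        )

    def blacklisted(contig: str, start: int, end: int) -> bool:
        return any(
            contig == bc and start < be and bs < end for bc, bs, be in blacklist
        )

    kept = [
        r for r in merged if not near_border(*r) and not blacklisted(*r)
    ]
    return DyadRegionSet(kept, provenance=list(calls_by_sample))


def count_centers(
    regions: DyadRegionSet,
    fragments_by_sample: Mapping[str, Sequence[Fragment]],
) -> pd.DataFrame:
    """Count per-sample fragment centers falling in each (disjoint) region."""
    index = pd.MultiIndex.from_tuples(
        regions.regions, names=["contig", "start", "end"]
    )
    out = pd.DataFrame(
        0, index=index, columns=list(fragments_by_sample), dtype=np.int64
    )
    # per-contig sorted region bounds for searchsorted lookup
    by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    for row_idx, (contig, start, end) in enumerate(regions.regions):
        tmp.setdefault(contig, []).append((start, end, row_idx))
    for contig, triples in tmp.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        rows = np.array([t[2] for t in triples])
        by_contig[contig] = (starts, ends, rows)

    for sample, fragments in fragments_by_sample.items():
        centers: dict[str, list[int]] = {}
        for f in fragments:
            centers.setdefault(f.contig, []).append(f.center)
        col = np.zeros(len(regions), dtype=np.int64)
        for contig, cs in centers.items():
            if contig not in by_contig:
                continue
            starts, ends, rows = by_contig[contig]
            pos = np.asarray(cs)
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            np.add.at(col, rows[idx[ok]], 1)
        out[sample] = col
    return out


def normalize_occupancy(counts: pd.DataFrame) -> pd.DataFrame:
    """v = log2(((x / sum(x)) * 1000) + 0.001), per sample column."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total counts in regions: {list(zero.index)}"
        )
    return np.log2((counts / totals) * 1000 + 0.001)


def pca_regions(v: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the normalized occupancy matrix (regions = observations).

    Variables (samples) are centered but not scaled. Returns
    (scores, explained_variance_ratio, loadings); component signs are
    fixed so the largest-magnitude loading of each component is positive.
    """
    if v.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if v.shape[0] < 2:
        raise ValueError("PCA requires at least 2 regions")
    n_comp = min(v.shape[0], v.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(v.to_numpy())
    loadings = pca.components_
    for j in range(loadings.shape[0]):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return scores, pca.explained_variance_ratio_, loadings


def kmeans_regions(
    pc_scores: np.ndarray,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 25,
    components: int | None = None,
) -> np.ndarray:
    """Best-inertia K-means over seeded restarts; labels 1..k by size.

    Labels are renumbered by decreasing cluster size; ties broken by the
    first (lowest-index) region in each cluster. Deterministic given
    (seed, n_restarts).
    """
    X = pc_scores if components is None else pc_scores[:, :components]
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of regions {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    first = np.full(k, np.iinfo(np.int64).max)
    for i, lab in enumerate(raw):
        if first[lab] == np.iinfo(np.int64).max:
            first[lab] = i
    order = sorted(range(k), key=lambda c: (-sizes[c], first[c]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[l] for l in raw])


def cluster_summary(
    labels: np.ndarray, v: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Mean normalized occupancy per (cluster, sample), row-scaled scores,
    and a hierarchical ordering of the clusters.

    Row scaling z-scores each cluster row across samples (ddof=1); rows
    with zero variance become all-zero. Ordering is average-linkage
    hierarchical clustering of the row-scaled rows (Euclidean), leaf
    order as returned deterministically by the linkage.
    """
    labs = np.asarray(labels)
    score = v.groupby(labs).mean()
    score.index.name = "cluster"
    mean = score.mean(axis=1)
    sd = score.std(axis=1, ddof=1)
    scaled = score.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    if len(score) > 1:
        link = average(pdist(scaled.to_numpy(), metric="euclidean"))
        order = [int(score.index[i]) for i in leaves_list(link)]
    else:
        order = [int(score.index[0])]
    return score, scaled, order


def cluster_positions(
    v: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 25,
    components: int | None = None,
) -> ClusterResult:
    """PCA + K-means + summaries in one call."""
    scores, evr, _ = pca_regions(v)
    labels = kmeans_regions(scores, k=k, seed=seed, n_restarts=n_restarts,
                            components=components)
    css, rss, order = cluster_summary(labels, v)
    return ClusterResult(scores, evr, labels, css, rss, order)
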