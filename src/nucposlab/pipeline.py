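"""End-to-end orchestration and the synthetic recovery benchmark.

:class:`AnalysisConfig` holds every numeric parameter of the pipeline
with its default; :func:`run_positioning_analysis` composes the stages
(dyad tracks → calling → joint clustering → features → profiles) on
arbitrary inputs and writes a machine-readable manifest;
:func:`run_synthetic_benchmark` generates a synthetic study, runs the
full pipeline on it, and scores recovery of the planted ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from nucposlab import dyad_tracks, nucleosome_calling, position_clustering
from nucposlab.dna_features import window_features
from nucposlab.io_formats import Anchor, Fragment, GenomeSequence
from nucposlab.profiles_and_groups import dyad_density
from nucposlab.synthetic_data import (
    SyntheticConfig,
    SyntheticTruth,
    generate_reference,
    simulate_fragments,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All numeric pipeline parameters (defaults as used throughout)."""

    dyad_shift: int = 73
    read_extension: int = 50
    fragment_trim: int = 40
    gaussian_width: int = 100
    gaussian_sd: float = 25.0
    greedy_exclusion: int = 120
    greedy_keep_fraction: float = 0.90
    fft_pc_keep_comp: float = 0.02
    fft_threshold_pct: float = 99.0
    plus1_window: tuple[int, int] = (0, 500)
    joint_enlarge: int = 20
    border_exclusion: int = 250
    blacklist: list[tuple[str, int, int]] = field(default_factory=list)
    k_clusters: int = 8
    kmeans_restarts: int = 25
    composite_halfwidth: int = 1000
    shape_smooth_window: int = 5
    feature_window: int = 320
    reb1_window: int = 120
    reb1_upstream_offset: int = 160
    pwm_colocation: int = 50
    upstream_limit: int = 400
    reb1_density_halfwidth: int = 2000
    density_bin: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.gaussian_sd <= 0 or self.gaussian_width < 1:
            raise ValueError("invalid Gaussian filter parameters")
        if not (0 < self.greedy_keep_fraction <= 1):
            raise ValueError("greedy_keep_fraction must be in (0, 1]")
        if not (0 < self.fft_pc_keep_comp <= 1):
            raise ValueError("fft_pc_keep_comp must be in (0, 1]")
        if self.joint_enlarge % 2 or self.fragment_trim % 2:
            raise ValueError("joint_enlarge and fragment_trim must be even")

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "plus1_window" in kwargs:
            kwargs["plus1_window"] = tuple(kwargs["plus1_window"])
        if "blacklist" in kwargs:
            kwargs["blacklist"] = [tuple(b) for b in kwargs["blacklist"]]
        return cls(**kwargs)

    def to_mapping(self) -> dict[str, Any]:
        d = asdict(self)
        d["plus1_window"] = list(self.plus1_window)
        d["blacklist"] = [list(b) for b in self.blacklist]
        return d


def _checksum(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_positioning_analysis(
    config: AnalysisConfig,
    genome: GenomeSequence,
    fragments_by_sample: Mapping[str, Sequence[Fragment]],
    genes: Sequence[Anchor] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run dyads → calling → joint set → occupancy → PCA/K-means.

    Returns a bundle of in-memory results plus a manifest; when
    ``out_dir`` is given, tables and the manifest are also written there.
    """
    lengths = genome.lengths()
    stages: list[str] = []
    bundle: dict[str, Any] = {}

    dyads = {
        s: dyad_tracks.fragment_centers(frags, lengths)
        for s, frags in fragments_by_sample.items()
    }
    stages.append("dyad_tracks")
    coverage = {
        s: dyad_tracks.trimmed_coverage(frags, lengths, trim=config.fragment_trim)
        for s, frags in fragments_by_sample.items()
    }
    stages.append("trimmed_coverage")

    calls = {
        s: nucleosome_calling.fft_call(
            cov,
            pc_keep_comp=config.fft_pc_keep_comp,
            threshold_pct=config.fft_threshold_pct,
        )
        for s, cov in coverage.items()
    }
    stages.append("fft_calling")
    bundle["calls_by_sample"] = calls

    regions = position_clustering.build_joint_dyad_set(
        calls,
        lengths,
        enlarge=config.joint_enlarge,
        border_exclusion=config.border_exclusion,
        blacklist=config.blacklist,
        tile_boundaries=genome.tile_boundaries,
    )
    stages.append("joint_dyad_set")
    bundle["regions"] = regions

    counts = position_clustering.count_centers(regions, fragments_by_sample)
    v = position_clustering.normalize_occupancy(counts)
    stages.append("occupancy_matrix")
    bundle["counts"] = counts
    bundle["normalized"] = v

    cluster = position_clustering.cluster_positions(
        v, k=config.k_clusters, seed=config.seed, n_restarts=config.kmeans_restarts
    )
    stages.append("pca_kmeans")
    bundle["cluster"] = cluster

    if genes is not None:
        smoothed = {
            s: nucleosome_calling.gaussian_smooth(
                d, width=config.gaussian_width, sd=config.gaussian_sd
            )
            for s, d in dyads.items()
        }
        greedy = {
            s: nucleosome_calling.greedy_call(
                sm,
                exclusion=config.greedy_exclusion,
                keep_fraction=config.greedy_keep_fraction,
            )
            for s, sm in smoothed.items()
        }
        stages.append("greedy_calling")
        bundle["greedy_calls"] = greedy
        bundle["plus1"] = {
            s: nucleosome_calling.annotate_plus1_minus1(
                g, genes, window=config.plus1_window
            )
            for s, g in greedy.items()
        }
        stages.append("plus1_annotation")

    bundle["dyad_tracks"] = dyads
    manifest = {
        "stages": stages,
        "parameters": config.to_mapping(),
        "samples": {s: len(f) for s, f in fragments_by_sample.items()},
        "n_regions": len(regions),
        "input_checksums": {
            s: _checksum([(f.contig, f.start, f.end) for f in frags[:1000]])
            for s, frags in fragments_by_sample.items()
        },
    }
    bundle["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        regions.to_frame().to_csv(out / "regions.bed", sep="\t", header=False, index=False)
        counts.to_csv(out / "occupancy_counts.tsv", sep="\t")
        v.to_csv(out / "occupancy_normalized.tsv", sep="\t")
        pd.DataFrame(
            cluster.pc_scores,
            columns=[f"PC{i+1}" for i in range(cluster.pc_scores.shape[1])],
        ).to_csv(out / "pca.tsv", sep="\t", index=False)
        pd.Series(cluster.labels, name="cluster").to_csv(out / "labels.tsv", sep="\t", index=False)
        cluster.cluster_sample_score.to_csv(out / "cluster_scores.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle


def _region_truth_labels(
    regions: position_clustering.DyadRegionSet,
    truth: SyntheticTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted condition-preference label per region.

    A region is labeled by the planted dyad nearest its midpoint when
    that dyad is within ±(alt_dyad_offset/2 − 5) bp — closer to one
    planted position than the other by construction. True-+1 dyads give
    label 1, alternative dyads 0, unmatched regions −1 (unlabeled).
    Returns (labels, mask of labeled regions).
    """
    tol = 30
    by_tile: dict[str, list[tuple[int, int]]] = {}
    for g in truth.genes:
        by_tile.setdefault(g.tile, []).append((g.plus1_dyad, 1))
        by_tile.setdefault(g.tile, []).append((g.alt_dyad, 0))
    labels = np.full(len(regions), -1)
    for i, (contig, start, end) in enumerate(regions.regions):
        mid = (start + end) // 2
        best = None
        for d, lab in by_tile.get(contig, []):
            dist = abs(d - mid)
            if dist <= tol and (best is None or dist < best[0]):
                best = (dist, lab)
        if best is not None:
            labels[i] = best[1]
    return labels, labels >= 0


def run_synthetic_benchmark(
    analysis_config: AnalysisConfig | None = None,
    synthetic_config: SyntheticConfig | None = None,
    n_fragments: int = 200_000,
    n_replicates: int = 2,
    seed: int = 1,
) -> dict[str, float]:
    """Generate a synthetic study, run the pipeline, score recovery.

    Metrics:

    * ``plus1_recovery_pct`` — % of genes whose greedy-called +1 (in the
      condition preferring the true +1) lies within ±20 bp of the
      planted dyad;
    * ``cluster_ari`` — adjusted Rand index between planted region
      condition preferences and K-means clusters aggregated by which
      condition scores higher;
    * ``rigidity_peak_offset`` / ``rigidity_dip_offset`` — offsets (bp,
      relative to recovered +1 dyads) of the maximum of the rigidity
      composite and of the minimum between that peak and the dyad;
    * ``density_mode_offset`` — mode (bin center) of the Reb1
      motif-anchored dyad density.
    """
    acfg = analysis_config or AnalysisConfig(seed=seed)
    scfg = synthetic_config or SyntheticConfig()
    genome, truth = generate_reference(scfg, seed)
    lengths = genome.lengths()

    fragments: dict[str, list[Fragment]] = {}
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=16)
    i = 0
    for cond in scfg.conditions:
        for rep in range(n_replicates):
            sid = f"{cond}_rep{rep + 1}"
            fragments[sid] = simulate_fragments(
                genome, truth, scfg, cond, n_fragments, int(sub[i]), sample_id=sid
            )
            i += 1

    bundle = run_positioning_analysis(
        acfg, genome, fragments, genes=truth.tss_anchors()
    )

    # --- +1 recovery, pooled over the true-+1-preferring condition ---
    plus1_cond = next(
        c for c, which in truth.condition_preference.items() if which == "plus1"
    )
    pooled = [
        f
        for s, frags in fragments.items()
        if s.rsplit("_rep", 1)[0] == plus1_cond
        for f in frags
    ]
    pooled_dyads = dyad_tracks.fragment_centers(pooled, lengths)
    smoothed = nucleosome_calling.gaussian_smooth(
        pooled_dyads, width=acfg.gaussian_width, sd=acfg.gaussian_sd
    )
    greedy = nucleosome_calling.greedy_call(
        smoothed, exclusion=acfg.greedy_exclusion,
        keep_fraction=acfg.greedy_keep_fraction,
    )
    annotations = nucleosome_calling.annotate_plus1_minus1(
        greedy, truth.tss_anchors(), window=acfg.plus1_window
    )
    planted = {g.gene_id: g.plus1_dyad for g in truth.genes}
    hits = [
        a
        for a in annotations
        if a.plus1_dyad is not None and abs(a.plus1_dyad - planted[a.gene_id]) <= 20
    ]
    plus1_recovery_pct = 100.0 * len(hits) / len(truth.genes)

    # --- cluster recovery ---
    cluster = bundle["cluster"]
    regions = bundle["regions"]
    true_labels, mask = _region_truth_labels(regions, truth)
    score = cluster.cluster_sample_score
    cond_means = {
        cond: score[
            [c for c in score.columns if c.rsplit("_rep", 1)[0] == cond]
        ].mean(axis=1)
        for cond in scfg.conditions
    }
    # each cluster is assigned to the condition with the higher mean score
    assigned = pd.DataFrame(cond_means).idxmax(axis=1)
    pred = np.array(
        [1 if assigned[l] == plus1_cond else 0 for l in cluster.labels]
    )
    cluster_ari = float(adjusted_rand_score(true_labels[mask], pred[mask]))

    # --- rigidity composite around recovered +1 dyads ---
    gene_strand = {g.gene_id: g.strand for g in truth.genes}
    gene_tile = {g.gene_id: g.tile for g in truth.genes}
    recovered = [
        Anchor(gene_tile[a.gene_id], a.plus1_dyad, gene_strand[a.gene_id], a.gene_id)
        for a in annotations
        if a.plus1_dyad is not None
    ]
    half = acfg.feature_window // 2
    _, rigidity_mean, _ = window_features(genome, recovered, half, "rigidity")
    offsets = np.arange(-half, half + 1)
    peak_i = int(np.argmax(rigidity_mean))
    rigidity_peak_offset = int(offsets[peak_i])
    between = (offsets > rigidity_peak_offset) & (offsets < 0)
    dip_i = np.flatnonzero(between)[int(np.argmin(rigidity_mean[between]))]
    rigidity_dip_offset = int(offsets[dip_i])

    # --- Reb1 motif-anchored dyad density ---
    density_mode_offset = float("nan")
    if scfg.reb1_enabled:
        centers, density = dyad_density(
            pooled_dyads,
            truth.reb1_anchors(),
            halfwidth=acfg.composite_halfwidth,
            bin_size=acfg.density_bin,
        )
        density_mode_offset = float(centers[int(np.argmax(density))])

    return {
        "plus1_recovery_pct": plus1_recovery_pct,
        "cluster_ari": cluster_ari,
        "rigidity_peak_offset": float(rigidity_peak_offset),
        "rigidity_dip_offset": float(rigidity_dip_offset),
        "density_mode_offset": density_mode_offset,
        "n_regions": float(len(regions)),
        "n_genes": float(len(truth.genes)),
    }
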