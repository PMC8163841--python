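"""Per-bp DNA shape and mechanics features.

Three feature families:

* pentamer-table shape lookup (propeller twist, helix twist, minor
  groove width, electrostatic potential...), smoothed with a centered
  rolling mean;
* an A-tract rigidity score — at each position, the length of the
  longest A^n T^m element (n >= 0, m >= 0, n + m >= 2; a run of A's
  followed by a run of T's, no intervening TpA step or G/C) containing
  that position;
* poly(dA)/poly(dT) hexamer coverage.

Pentamer features are undefined in the 2 bp at each sequence end and
wherever the pentamer contains an N; rigidity and poly(dA/dT) are
defined everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nucposlab.io_formats import Anchor, GenomeSequence, revcomp


@dataclass
class PentamerShapeTable:
    """feature name → {5-mer → value} lookup."""

    features: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for feat, table in self.features.items():
            for p in table:
                if len(p) != 5 or set(p) - set("ACGT"):
                    raise ValueError(f"invalid pentamer {p!r} in feature {feat!r}")

    def is_complete(self, feature: str) -> bool:
        return len(self.features.get(feature, {})) == 4**5

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PentamerShapeTable":
        """Read a table with columns pentamer, feature, value (header row)."""
        df = pd.read_csv(path, sep="\t")
        feats: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            feats.setdefault(row.feature, {})[row.pentamer] = float(row.value)
        return cls(feats)


@dataclass
class FeatureProfile:
    """Per-bp feature values aligned to a sequence; NaN marks undefined."""

    values: np.ndarray
    feature_name: str
    smoothing: str = "none"


def shape_profile(
    sequence: str,
    table: PentamerShapeTable,
    feature: str,
    smooth_window: int = 5,
) -> FeatureProfile:
    """Pentamer shape lookup followed by a centered rolling mean.

    The value at position i (2 <= i <= L-3) is the table entry for the
    pentamer centered on i. Smoothing propagates NaN: an output position
    is undefined wherever the window overlaps an undefined value.
    """
    if feature not in table.features:
        raise ValueError(f"unknown feature {feature!r}")
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    lookup = table.features[feature]
    L = len(sequence)
    raw = np.full(L, np.nan)
    for i in range(2, L - 2):
        raw[i] = lookup.get(sequence[i - 2 : i + 3], np.nan)
    if smooth_window == 1:
        return FeatureProfile(raw, feature, "none")
    half = smooth_window // 2
    smoothed = np.full(L, np.nan)
    if L >= smooth_window:
        windows = np.lib.stride_tricks.sliding_window_view(raw, smooth_window)
        smoothed[half : L - half] = windows.mean(axis=1)  # NaN propagates
    return FeatureProfile(smoothed, feature, f"rollmean{smooth_window}")


def rigidity_profile(sequence: str) -> FeatureProfile:
    """A-tract rigidity score per position.

    score(i) = length of the longest substring matching A^n T^m
    (n + m >= 2) that contains position i; 0 where no such element
    exists. Runs in O(L) over the run-length decomposition: a position
    in an A-run can at best extend through the whole run plus an
    immediately following T-run, and symmetrically for T-runs.
    """
    L = len(sequence)
    score = np.zeros(L, dtype=np.int64)
    # run-length decomposition
    runs: list[tuple[str, int, int]] = []  # (base, start, end)
    i = 0
    while i < L:
        j = i
        while j < L and sequence[j] == sequence[i]:
            j += 1
        runs.append((sequence[i], i, j))
        i = j
    for r, (base, start, end) in enumerate(runs):
        if base == "A":
            n = end - start
            m = 0
            if r + 1 < len(runs) and runs[r + 1][0] == "T":
                m = runs[r + 1][2] - runs[r + 1][1]
            if n + m >= 2:
                score[start:end] = n + m
        elif base == "T":
            m = end - start
            n = 0
            if r > 0 and runs[r - 1][0] == "A":
                n = runs[r - 1][2] - runs[r - 1][1]
            if n + m >= 2:
                score[start:end] = n + m
    return FeatureProfile(score.astype(float), "rigidity")


def polyAT_coverage(
    sequence: str, k: int = 6, mode: str = "count"
) -> dict[str, FeatureProfile]:
    """Coverage of length-k homopolymer A (polyA) and T (polyT) stretches.

    mode="count": each (possibly overlapping) k-mer match adds 1 to all
    k of its positions. mode="binary": 1 where count > 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("count", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    L = len(sequence)
    out: dict[str, FeatureProfile] = {}
    for name, base in (("polyA", "A"), ("polyT", "T")):
        cov = np.zeros(L, dtype=float)
        if L >= k:
            arr = np.frombuffer(sequence.encode(), dtype="S1")
            is_base = arr == base.encode()
            run = np.lib.stride_tricks.sliding_window_view(is_base, k).all(axis=1)
            diff = np.zeros(L + 1)
            starts = np.flatnonzero(run)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, starts + k, -1.0)
            cov = np.cumsum(diff[:-1])
        if mode == "binary":
            cov = (cov > 0).astype(float)
        out[name] = FeatureProfile(cov, name)
    return out


def _feature_for_window(
    seq: str,
    feature: str,
    table: PentamerShapeTable | None,
    smooth_window: int,
    polyAT_mode: str,
) -> np.ndarray:
    if feature == "rigidity":
        return rigidity_profile(seq).values
    if feature in ("polyA", "polyT"):
        return polyAT_coverage(seq, mode=polyAT_mode)[feature].values
    if feature.startswith("shape:"):
        if table is None:
            raise ValueError("a pentamer table is required for shape features")
        return shape_profile(seq, table, feature[6:], smooth_window).values
    raise ValueError(f"unknown feature spec {feature!r}")


def window_features(
    genome: GenomeSequence,
    positions: Sequence[Anchor],
    halfwidth: int,
    feature: str,
    table: PentamerShapeTable | None = None,
    smooth_window: int = 5,
    polyAT_mode: str = "count",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-position feature matrix over [−halfwidth, +halfwidth] windows.

    Window sequences are reverse-complemented for minus-strand anchors
    so offsets are downstream-positive in gene orientation. Returns
    (matrix [n_kept x (2*halfwidth+1)], per-offset mean ignoring NaN,
    n_dropped out-of-range positions).
    """
    width = 2 * halfwidth + 1
    rows: list[np.ndarray] = []
    dropped = 0
    for a in positions:
        L = genome.length(a.contig)
        lo, hi = a.pos - halfwidth, a.pos + halfwidth + 1
        if lo < 0 or hi > L:
            dropped += 1
            continue
        seq = genome.fetch(a.contig, lo, hi)
        if a.strand == "-":
            seq = revcomp(seq)
        rows.append(_feature_for_window(seq, feature, table, smooth_window, polyAT_mode))
    if not rows:
        raise ValueError("no anchor windows survive the contig bounds")
    matrix = np.vstack(rows)
    assert matrix.shape[1] == width
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(matrix, axis=0)
    return matrix, mean, dropped
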