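"""Nucleosome dyad callers and +1/−1 annotation.

Two callers are provided:

* :func:`greedy_call` — Gaussian-smoothed dyad counts, iterative
  maximum picking with a ±exclusion masking zone, keeping the top
  fraction of calls by score.
* :func:`fft_call` — trimmed fragment coverage, low-pass FFT filtering
  keeping a small fraction of frequency components, then strict local
  maxima above a per-contig percentile threshold.

+1 nucleosomes are the called dyads nearest a TSS within 0..+500 bp
downstream in gene orientation; the −1 nucleosome is the first call
upstream of the +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from nucposlab.dyad_tracks import DyadTrack, OccupancyTrack
from nucposlab.io_formats import Anchor


@dataclass(frozen=True)
class NucleosomeCall:
    contig: str
    dyad: int
    score: float
    sample_id: str = ""


@dataclass(frozen=True)
class PlusOneAnnotation:
    """Per-gene +1/−1 dyads; ``None`` marks an undefined assignment."""

    gene_id: str
    strand: str
    plus1_dyad: int | None
    minus1_dyad: int | None

    @property
    def ndr_length(self) -> int | None:
        """Distance between −1 and +1 dyads (bp), defined when both are."""
        if self.plus1_dyad is None or self.minus1_dyad is None:
            return None
        return abs(self.plus1_dyad - self.minus1_dyad)


def gaussian_kernel(width: int = 100, sd: float = 25.0) -> np.ndarray:
    """Normalized Gaussian of 2*(width//2)+1 taps, mean 0, given sd."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if width < 1:
        raise ValueError("width must be >= 1")
    half = width // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def gaussian_smooth(
    track: DyadTrack | OccupancyTrack, width: int = 100, sd: float = 25.0
) -> OccupancyTrack:
    """Convolve per-contig signal with a normalized Gaussian (zero-padded edges)."""
    kernel = gaussian_kernel(width, sd)
    if isinstance(track, DyadTrack):
        arrays = {c: v.astype(float) for c, v in track.counts.items()}
        sample = track.sample_id
    else:
        arrays = track.values
        sample = track.sample_id
    smoothed = {
        c: convolve1d(v, kernel, mode="constant", cval=0.0) for c, v in arrays.items()
    }
    return OccupancyTrack(smoothed, sample_id=sample, provenance="smoothed")


def greedy_call(
    smoothed: OccupancyTrack,
    exclusion: int = 120,
    keep_fraction: float = 0.90,
) -> list[NucleosomeCall]:
    """Iterative maximum picking with masking of ±exclusion bp.

    Repeatedly record the highest-valued unmasked position and mask all
    positions within ±exclusion of it; stop when no unmasked value is
    positive. The top ceil(keep_fraction * n) recorded centers by score
    are retained (ties at the cut kept in coordinate order). Output is
    sorted by (contig input order, coordinate); within a contig the
    pairwise distance between calls exceeds ``exclusion``.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    recorded: list[NucleosomeCall] = []
    for contig, values in smoothed.values.items():
        work = np.array(values, dtype=float, copy=True)
        while True:
            i = int(np.argmax(work))  # leftmost maximum: deterministic tie-break
            v = work[i]
            if v <= 0:
                break
            recorded.append(NucleosomeCall(contig, i, float(v), smoothed.sample_id))
            work[max(i - exclusion, 0) : i + exclusion + 1] = -np.inf
    if not recorded:
        return []
    n_keep = int(np.ceil(keep_fraction * len(recorded)))
    # stable sort by descending score keeps recording (coordinate-scan) order at ties
    order = sorted(range(len(recorded)), key=lambda j: -recorded[j].score)
    kept = [recorded[j] for j in sorted(order[:n_keep])]
    contig_rank = {c: r for r, c in enumerate(smoothed.values)}
    kept.sort(key=lambda c: (contig_rank[c.contig], c.dyad))
    return kept


def fft_call(
    coverage: OccupancyTrack,
    pc_keep_comp: float = 0.02,
    threshold_pct: float = 99.0,
) -> list[NucleosomeCall]:
    """Low-pass FFT filtering followed by thresholded peak detection.

    Per contig: keep the DC term plus the lowest
    ceil(pc_keep_comp * N_freq) non-DC frequency components of the
    discrete Fourier transform (N_freq = number of non-DC rfft bins),
    zero the rest, and invert. Calls are strict local maxima of the
    filtered signal above the ``threshold_pct`` percentile of that
    contig's filtered values.
    """
    calls: list[NucleosomeCall] = []
    for contig, values in coverage.values.items():
        n = len(values)
        if n < 16:
            raise ValueError(f"contig {contig!r} too short for FFT filtering ({n} bp)")
        spectrum = np.fft.rfft(values)
        n_freq = len(spectrum) - 1
        n_keep = int(np.ceil(pc_keep_comp * n_freq))
        spectrum[1 + n_keep :] = 0.0
        filtered = np.fft.irfft(spectrum, n=n)
        threshold = np.percentile(filtered, threshold_pct)
        interior = filtered[1:-1]
        is_peak = (interior > filtered[:-2]) & (interior > filtered[2:]) & (
            interior > threshold
        )
        for i in np.flatnonzero(is_peak) + 1:
            calls.append(
                NucleosomeCall(contig, int(i), float(filtered[i]), coverage.sample_id)
            )
    return calls


def fft_filter(values: np.ndarray, pc_keep_comp: float = 0.02) -> np.ndarray:
    """The low-pass filter used by :func:`fft_call`, exposed for inspection."""
    spectrum = np.fft.rfft(values)
    n_freq = len(spectrum) - 1
    n_keep = int(np.ceil(pc_keep_comp * n_freq))
    spectrum[1 + n_keep :] = 0.0
    return np.fft.irfft(spectrum, n=len(values))


def annotate_plus1_minus1(
    calls: Sequence[NucleosomeCall],
    genes: Iterable[Anchor],
    window: tuple[int, int] = (0, 500),
) -> list[PlusOneAnnotation]:
    """Assign +1 and −1 nucleosomes to each gene (TSS anchor with strand).

    +1 is the call minimizing |dyad − TSS| among calls with
    window[0] <= (dyad − TSS)·sign <= window[1]; −1 is the nearest call
    strictly upstream of the +1 in gene orientation. Genes without a
    candidate get ``None`` entries.
    """
    by_contig: dict[str, list[NucleosomeCall]] = {}
    for c in calls:
        by_contig.setdefault(c.contig, []).append(c)
    for lst in by_contig.values():
        lst.sort(key=lambda c: c.dyad)

    out: list[PlusOneAnnotation] = []
    for g in genes:
        sign = g.sign
        cands = [
            c
            for c in by_contig.get(g.contig, [])
            if window[0] <= (c.dyad - g.pos) * sign <= window[1]
        ]
        if not cands:
            out.append(PlusOneAnnotation(g.id, g.strand, None, None))
            continue
        plus1 = min(cands, key=lambda c: (abs(c.dyad - g.pos), c.dyad))
        upstream = [
            c
            for c in by_contig.get(g.contig, [])
            if (c.dyad - g.pos) * sign < (plus1.dyad - g.pos) * sign
        ]
        minus1 = max(upstream, key=lambda c: (c.dyad - g.pos) * sign) if upstream else None
        out.append(
            PlusOneAnnotation(
                g.id, g.strand, plus1.dyad, minus1.dyad if minus1 else None
            )
        )
    return out
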