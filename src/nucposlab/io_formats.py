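"""Readers/writers for the standard formats the pipeline touches.

Coordinate contract: everything in this package is 0-based, half-open
(the BED convention). Anchors are single base pairs: for a minus-strand
BED interval the anchor position is ``end - 1`` so that an anchor always
names exactly one bp regardless of strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """An ordered collection of contigs (uppercase DNA over {A,C,G,T,N}).

    ``tile_boundaries`` optionally lists internal insert boundaries per
    contig (bp); contig ends 0 and L always count as tile borders when
    border filters are applied downstream.
    """

    contigs: dict[str, str]
    tile_boundaries: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig name")
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains invalid characters {bad}")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def reverse_complement(self) -> "GenomeSequence":
        """Mirror genome: every contig reverse-complemented, boundaries mirrored."""
        contigs = {c: revcomp(s) for c, s in self.contigs.items()}
        borders = {
            c: sorted(len(self.contigs[c]) - b for b in bs)
            for c, bs in self.tile_boundaries.items()
        }
        return GenomeSequence(contigs, borders)


@dataclass(frozen=True)
class Fragment:
    """A mapped (paired-end) fragment, half-open on one contig."""

    contig: str
    start: int
    end: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def center(self) -> int:
        # even lengths floor: start + len//2
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class ReadRecord:
    """A single-end read reduced to its 5' position and strand."""

    contig: str
    five_prime: int
    strand: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.five_prime < 0:
            raise ValueError("negative 5' position")


@dataclass(frozen=True)
class Anchor:
    """A single-bp alignment point (TSS, dyad, motif hit...) with strand."""

    contig: str
    pos: int
    strand: str = "."
    id: str = ""
    sort_keys: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def sign(self) -> int:
        """+1 for '+' or '.', −1 for '−'; '.' is treated as '+' for orientation."""
        return -1 if self.strand == "-" else 1


def read_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; record order is preserved. Duplicate contig
    names and empty records are hard errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        if "N" in seq:
            logger.info("contig %s contains ambiguous bases (N)", rec.id)
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fragments(
    path: str | Path,
    sample_id: str = "",
    genome: GenomeSequence | None = None,
) -> list[Fragment]:
    """Read fragments from BEDPE (6+ columns, two mates) or BED3+ files.

    BEDPE rows collapse to one fragment spanning min(start1,start2) to
    max(end1,end2). Rows with ``end <= start`` are rejected with a
    warning; a contig absent from a supplied genome is a hard error.
    """
    frags: list[Fragment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) >= 6 and _is_bedpe_row(cols):
                c1, s1, e1, c2, s2, e2 = cols[:6]
                if c1 != c2:
                    logger.warning("%s line %d: inter-contig mate pair skipped", path, ln)
                    continue
                contig = c1
                start = min(int(s1), int(s2))
                end = max(int(e1), int(e2))
            else:
                contig = cols[0]
                start, end = int(cols[1]), int(cols[2])
            if end <= start:
                logger.warning("%s line %d: empty/inverted interval rejected", path, ln)
                continue
            if genome is not None:
                if contig not in genome:
                    raise ValueError(f"{path} line {ln}: contig {contig!r} not in genome")
                if end > genome.length(contig):
                    raise ValueError(
                        f"{path} line {ln}: fragment [{start},{end}) exceeds "
                        f"contig {contig!r} length {genome.length(contig)}"
                    )
            frags.append(Fragment(contig, start, end, sample_id))
    return frags


def _is_bedpe_row(cols: list[str]) -> bool:
    """A BEDPE row has chrom2/start2/end2 in columns 4–6."""
    try:
        int(cols[4])
        int(cols[5])
    except ValueError:
        return False
    # BED6 column 5 is a score and column 6 a strand; strand never parses as int
    return True


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as BED3 rows (one fragment per line)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\n")


def read_anchors(path: str | Path) -> list[Anchor]:
    """Read single-bp anchors from a BED3/BED6 file.

    The anchor position is the interval start for '+'/'.' strand rows and
    ``end - 1`` for '−' strand rows. A numeric score column is kept as
    sort key ``"score"``.
    """
    anchors: list[Anchor] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"anchor{ln}"
            keys: dict[str, float] = {}
            if len(cols) > 4:
                try:
                    keys["score"] = float(cols[4])
                except ValueError:
                    pass
            strand = cols[5] if len(cols) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path} line {ln}: malformed strand {strand!r}")
            pos = end - 1 if strand == "-" else start
            anchors.append(Anchor(contig, pos, strand, name, keys))
    return anchors


def write_anchors(anchors: Iterable[Anchor], path: str | Path) -> None:
    """Write anchors as BED6 (inverse of the read convention)."""
    with open(path, "w") as fh:
        for a in anchors:
            # single-bp interval [pos, pos+1); minus-strand anchors read back as end-1 = pos
            score = a.sort_keys.get("score", 0)
            fh.write(f"{a.contig}\t{a.pos}\t{a.pos + 1}\t{a.id}\t{score:g}\t{a.strand}\n")


def write_track(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-bp values as bedGraph, run-length merging equal values.

    NaN positions are omitted from the output (they read back as NaN when
    the track is re-materialized over known contig lengths).
    """
    with open(path, "w") as fh:
        for contig, values in track.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                continue
            # run boundaries where the value changes (NaN != NaN splits runs,
            # but equal NaN runs should merge: compare via isnan too)
            change = np.zeros(values.size, dtype=bool)
            change[0] = True
            a, b = values[1:], values[:-1]
            change[1:] = ~((a == b) | (np.isnan(a) & np.isnan(b)))
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], values.size)
            for s, e in zip(starts, ends):
                v = values[s]
                if np.isnan(v):
                    continue
                fh.write(f"{contig}\t{s}\t{e}\t{float(v)!r}\n")


def read_track(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-bp arrays; uncovered positions are NaN."""
    track = {c: np.full(n, np.nan) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end, value = line.split("\t")[:4]
            if contig not in track:
                raise ValueError(f"bedGraph contig {contig!r} not in supplied lengths")
            track[contig][int(start) : int(end)] = float(value)
    return track
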