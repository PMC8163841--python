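"""Synthetic genomes and MNase-seq-like fragment sets with planted,
sequence-linked nucleosome preferences.

The generator emulates a tiled plasmid-library reconstitution: a set of
independent tiles (contigs) carrying genes whose true +1 nucleosome
dyads are flanked by planted sequence elements — a rigid A-tract
element centered 100 bp upstream of the dyad, a flexible (TpA/GC-rich)
element centered 55 bp upstream, and optionally a Reb1 motif (TTACCC)
whose start lies 145 bp upstream of the dyad, all in gene orientation.
Each gene also carries an alternative dyad (default +70 bp downstream
of the true +1) with a weak A-tract element of its own. Experimental
conditions differ only in which dyad they prefer: a "remodeled"-style
condition samples the true +1 with high probability, an "assembly-only"
style condition the alternative dyad. Fragments are ~147 bp (clipped
normal), centered on the sampled dyad plus Gaussian jitter, on a
uniform-background floor.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nucposlab.io_formats import Anchor, Fragment, GenomeSequence, revcomp

RIGID_ELEMENT = "AAAAAATTTTTT"  # A6T6: rigidity 12, reverse-complement invariant
FLEX_ELEMENT = "TACGTACGTACG"  # TpA steps + G/C: rigidity 0
ALT_ELEMENT = "AAAAA"  # weak A-tract at the alternative dyad's upstream flank
REB1_MOTIF = "TTACCC"


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the forward model."""

    n_tiles: int = 50
    tile_len: int = 10_000
    gc_fraction: float = 0.38
    genes_per_tile: int = 3
    rigid_len: int = 12
    rigid_center_offset: int = -100  # relative to true +1 dyad, gene orientation
    flex_center_offset: int = -55
    reb1_enabled: bool = True
    reb1_upstream: int = 145  # motif start → dyad distance (bp upstream)
    tss_offset: int = 60  # TSS sits this far upstream of the true +1 dyad
    alt_dyad_offset: int = 70  # alternative dyad downstream of true +1
    conditions: tuple[str, ...] = ("sgd", "remodeled")
    preference_weight: float = 0.8  # probability of the condition's preferred dyad
    jitter_sd: float = 5.0
    background_fraction: float = 0.3
    frag_mean: float = 147.0
    frag_sd: float = 10.0
    frag_min: int = 120
    frag_max: int = 180

    def __post_init__(self) -> None:
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if min(self.n_tiles, self.tile_len, self.genes_per_tile, self.rigid_len) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not (0 <= self.preference_weight <= 1):
            raise ValueError("preference_weight must be in [0, 1]")


@dataclass
class GeneTruth:
    gene_id: str
    tile: str
    tss: int
    strand: str
    plus1_dyad: int
    alt_dyad: int
    reb1_pos: int | None  # motif start on the sense-strand representation
    reb1_strand: str | None


@dataclass
class SyntheticTruth:
    genes: list[GeneTruth]
    condition_preference: dict[str, str] = field(default_factory=dict)
    # condition → "plus1" | "alt": which planted dyad the condition prefers

    def preferred_dyads(self, condition: str) -> list[tuple[str, int]]:
        which = self.condition_preference[condition]
        return [
            (g.tile, g.plus1_dyad if which == "plus1" else g.alt_dyad)
            for g in self.genes
        ]

    def tss_anchors(self) -> list[Anchor]:
        return [Anchor(g.tile, g.tss, g.strand, g.gene_id) for g in self.genes]

    def plus1_anchors(self) -> list[Anchor]:
        return [Anchor(g.tile, g.plus1_dyad, g.strand, g.gene_id) for g in self.genes]

    def reb1_anchors(self) -> list[Anchor]:
        return [
            Anchor(g.tile, g.reb1_pos, g.reb1_strand or ".", g.gene_id)
            for g in self.genes
            if g.reb1_pos is not None
        ]


def _plant(seq: list[str], start: int, element: str) -> None:
    if start < 0 or start + len(element) > len(seq):
        raise ValueError("planted element outside tile bounds; use a sparser layout")
    seq[start : start + len(element)] = list(element)


def _plant_oriented(
    seq: list[str], anchor: int, center_offset: int, element: str, strand: str
) -> None:
    """Plant ``element`` covering gene-oriented offsets
    [center_offset − len//2, center_offset − len//2 + len) from ``anchor``."""
    k = len(element)
    lo = center_offset - k // 2  # gene-oriented start offset
    if strand == "+":
        _plant(seq, anchor + lo, element)
    else:
        _plant(seq, anchor - lo - k + 1, revcomp(element))


def generate_reference(
    config: SyntheticConfig, seed: int
) -> tuple[GenomeSequence, SyntheticTruth]:
    """Generate the tiled genome with planted elements and the truth table.

    Background bases are i.i.d. with the configured GC fraction; planted
    elements overwrite the background at fixed offsets from each gene's
    true +1 dyad (orientation matched to gene strand). Gene layout is
    deterministic: true +1 dyads are evenly spaced along each tile,
    >= 500 bp from tile ends; strands alternate.
    """
    rng = np.random.default_rng(seed)
    p_gc = config.gc_fraction
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))

    contigs: dict[str, str] = {}
    genes: list[GeneTruth] = []
    margin = 500
    usable = config.tile_len - 2 * margin
    if usable <= 0 or config.genes_per_tile > usable // 400:
        raise ValueError("tile too short for the requested gene layout")
    spacing = usable // config.genes_per_tile

    for t in range(config.n_tiles):
        tile = f"tile{t:03d}"
        seq = list(rng.choice(bases, size=config.tile_len, p=probs))
        for g in range(config.genes_per_tile):
            gene_id = f"{tile}_g{g}"
            strand = "+" if (t * config.genes_per_tile + g) % 2 == 0 else "-"
            sign = 1 if strand == "+" else -1
            dyad = margin + g * spacing + spacing // 2
            tss = dyad - sign * config.tss_offset
            alt = dyad + sign * config.alt_dyad_offset
            _plant_oriented(seq, dyad, config.rigid_center_offset,
                            RIGID_ELEMENT[: config.rigid_len], strand)
            _plant_oriented(seq, dyad, config.flex_center_offset,
                            FLEX_ELEMENT, strand)
            _plant_oriented(seq, dyad, config.alt_dyad_offset - 100, ALT_ELEMENT, strand)
            reb1_pos: int | None = None
            reb1_strand: str | None = None
            if config.reb1_enabled:
                # motif start (gene-oriented 5' end) sits reb1_upstream bp
                # upstream of the true +1 dyad
                if strand == "+":
                    start = dyad - config.reb1_upstream
                    _plant(seq, start, REB1_MOTIF)
                    reb1_pos = start
                else:
                    start = dyad + config.reb1_upstream - len(REB1_MOTIF) + 1
                    _plant(seq, start, revcomp(REB1_MOTIF))
                    reb1_pos = start + len(REB1_MOTIF) - 1
                reb1_strand = strand
            genes.append(
                GeneTruth(gene_id, tile, tss, strand, dyad, alt, reb1_pos, reb1_strand)
            )
        contigs[tile] = "".join(seq)

    truth = SyntheticTruth(
        genes,
        condition_preference={
            config.conditions[0]: "alt",
            **{c: "plus1" for c in config.conditions[1:]},
        },
    )
    return GenomeSequence(contigs), truth


def simulate_fragments(
    genome: GenomeSequence,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    condition: str,
    n_fragments: int,
    seed: int,
    sample_id: str | None = None,
) -> list[Fragment]:
    """Draw MNase-seq-like fragments for one sample of one condition.

    Each fragment is background (uniform center on the genome) with
    probability ``background_fraction``; otherwise its center is a
    planted dyad drawn from the condition's preference distribution
    (preferred dyad with probability ``preference_weight``, the other
    planted dyad otherwise, uniform over genes) plus rounded Gaussian
    jitter. Lengths follow a clipped normal(frag_mean, frag_sd) law on
    [frag_min, frag_max]. Fragments that would cross a contig end are
    resampled (bounded retries, then dropped).
    """
    if condition not in truth.condition_preference:
        raise ValueError(f"condition {condition!r} not defined in truth")
    sample_id = sample_id or condition
    rng = np.random.default_rng(seed)

    tiles = list(genome.contigs)
    lengths = np.array([genome.length(t) for t in tiles])
    cum = np.cumsum(lengths)
    total = int(cum[-1])

    pref = truth.condition_preference[condition]
    plus1 = [(g.tile, g.plus1_dyad) for g in truth.genes]
    alt = [(g.tile, g.alt_dyad) for g in truth.genes]
    preferred, other = (plus1, alt) if pref == "plus1" else (alt, plus1)

    is_bg = rng.random(n_fragments) < config.background_fraction
    take_pref = rng.random(n_fragments) < config.preference_weight
    gene_idx = rng.integers(0, len(truth.genes), size=n_fragments)
    jitter = np.rint(rng.normal(0.0, config.jitter_sd, size=n_fragments)).astype(int)
    frag_len = np.clip(
        np.rint(rng.normal(config.frag_mean, config.frag_sd, size=n_fragments)),
        config.frag_min,
        config.frag_max,
    ).astype(int)
    bg_pos = rng.integers(0, total, size=n_fragments)

    frags: list[Fragment] = []
    dropped = 0
    for i in range(n_fragments):
        length = int(frag_len[i])
        for attempt in range(10):
            if is_bg[i]:
                flat = int(bg_pos[i]) if attempt == 0 else int(rng.integers(0, total))
                t = int(np.searchsorted(cum, flat, side="right"))
                contig = tiles[t]
                center = flat - (int(cum[t - 1]) if t else 0)
            else:
                src = preferred if take_pref[i] else other
                contig, dyad = src[int(gene_idx[i])]
                jit = int(jitter[i]) if attempt == 0 else int(
                    np.rint(rng.normal(0.0, config.jitter_sd))
                )
                center = dyad + jit
            start = center - length // 2
            end = start + length
            if 0 <= start and end <= genome.length(contig):
                frags.append(Fragment(contig, start, end, sample_id))
                break
        else:
            dropped += 1
    return frags


def write_outputs(
    genome: GenomeSequence,
    truth: SyntheticTruth,
    out_dir: str | Path,
    fragments: dict[str, list[Fragment]] | None = None,
) -> None:
    """Write genome.fa, tss.bed, plus1_truth.bed, reb1_sites.bed, truth.tsv
    and one BED fragment file per sample into ``out_dir``."""
    from nucposlab.io_formats import write_anchors, write_fragments, write_genome

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(genome, out / "genome.fa")
    write_anchors(truth.tss_anchors(), out / "tss.bed")
    write_anchors(truth.plus1_anchors(), out / "plus1_truth.bed")
    write_anchors(truth.reb1_anchors(), out / "reb1_sites.bed")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("gene_id\ttile\ttss\tstrand\tplus1_dyad\talt_dyad\treb1_pos\treb1_strand\n")
        for g in truth.genes:
            fh.write(
                f"{g.gene_id}\t{g.tile}\t{g.tss}\t{g.strand}\t{g.plus1_dyad}\t"
                f"{g.alt_dyad}\t{'' if g.reb1_pos is None else g.reb1_pos}\t"
                f"{g.reb1_strand or ''}\n"
            )
    for sample, frags in (fragments or {}).items():
        write_fragments(frags, out / f"{sample}.bed")
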