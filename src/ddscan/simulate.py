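"""Synthetic genomes and aligned read sets with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`make_genome` plants TALE sites, dimeric pair layouts and bare TC
  motifs of known editability into a random background, returning the
  genome together with a truth record of the planted coordinates;
* :func:`simulate_reads` emits pre-aligned SAM records tiling the genome at
  exact depth, with per-read Bernoulli draws at programmed positions
  (on-target editing, low-level off-target deamination, fixed-fraction
  cell-line variants) plus optional uniform sequencing error.

Identical seeds give byte-identical outputs. Alignment is out of scope for
the pipeline, so reads are emitted directly as aligned records; a FASTQ
export exists for users who want to run a real aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import Genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_EDIT_PRODUCT = {"C": "T", "G": "A"}
# transition partner used for planted cell-line variants at A/T positions
_TRANSITION = {"C": "T", "G": "A", "A": "G", "T": "C"}


class PlantingError(ValueError):
    pass


@dataclass(frozen=True)
class PlantTCMotif:
    """A bare TC motif: C at ``c_position`` on the given strand."""

    c_position: int
    strand: str = "+"


@dataclass(frozen=True)
class PlantMDdCBESite:
    """A monomeric layout: a T...T site of ``site_length`` starting at
    ``start`` with exactly one planted motif at ``target_offset`` downstream
    of its 3'-terminal thymidine.

    With ``exclusive`` (default) the surrounding background is scrubbed of
    T/A within a margin so no unplanned T-ended window overlaps the planted
    footprint.
    """

    start: int
    target_offset: int
    site_length: int = 14
    strand: str = "+"
    exclusive: bool = True


@dataclass(frozen=True)
class PlantDdCBEPair:
    """A dimeric layout on the forward orientation: left T...T site, spacer
    of ``spacer_length`` with one TC motif whose C sits at 0-based
    ``motif_offset`` within the spacer, right site bound on the - strand."""

    start: int
    spacer_length: int = 14
    motif_offset: int | None = None  # default: spacer midpoint
    site_length: int = 14
    exclusive: bool = True


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    seed: int
    gc_fraction: float = 0.44  # human mtDNA-like base composition
    circular: bool = True
    name: str = "synthetic"
    planted: tuple = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise PlantingError("length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise PlantingError("gc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class EditSpec:
    """Programmed per-read substitution fractions.

    ``per_position`` maps coordinate -> (alternate base, fraction) for
    editing events (C>T at ref C, G>A at ref G only); ``snv_positions``
    maps coordinate -> fraction for cell-line variants (emitted as the
    transition partner of the reference base, e.g. 1.0 for homoplasmy).
    Sequencing error substitutes a uniformly random other base and is
    applied after programmed substitution, so realized fractions at
    non-programmed positions are ~error_rate*2/3 toward any one base.
    """

    seed: int
    depth: int = 100
    read_length: int = 100
    per_position: dict[int, tuple[str, float]] = field(default_factory=dict)
    snv_positions: dict[int, float] = field(default_factory=dict)
    sequencing_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise PlantingError("depth must be >= 0")
        if self.read_length < 1:
            raise PlantingError("read_length must be >= 1")
        if not 0.0 <= self.sequencing_error_rate <= 1.0:
            raise PlantingError("sequencing_error_rate must be in [0, 1]")
        for pos, (alt, frac) in self.per_position.items():
            if not 0.0 <= frac <= 1.0:
                raise PlantingError(f"fraction {frac} at {pos} outside [0, 1]")
        for pos, frac in self.snv_positions.items():
            if not 0.0 <= frac <= 1.0:
                raise PlantingError(f"SNV fraction {frac} at {pos} outside [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth of a generated artifact; matches the generating spec."""

    planted: list[dict] = field(default_factory=list)
    programmed_rates: dict[int, tuple[str, float]] = field(default_factory=dict)


def _plant_footprint(directive, length: int) -> range:
    if isinstance(directive, PlantTCMotif):
        c = directive.c_position
        lo = c - 1 if directive.strand == "+" else c
        return range(lo, lo + 2)
    if isinstance(directive, PlantMDdCBESite):
        if directive.strand == "+":
            return range(directive.start, directive.start + directive.site_length + directive.target_offset)
        return range(directive.start - directive.target_offset, directive.start + directive.site_length)
    if isinstance(directive, PlantDdCBEPair):
        span = 2 * directive.site_length + directive.spacer_length
        return range(directive.start, directive.start + span)
    raise PlantingError(f"unknown planting directive {directive!r}")


def make_genome(spec: GenomeSpec) -> tuple[Genome, TruthRecord]:
    """Generate a random genome with the requested planted structures.

    Background bases are drawn from the GC fraction; planted directives are
    written last. Directives asserting exclusivity get their margin scrubbed
    of T/A (T->G, A->C) so no unplanned T-ended TALE window overlaps their
    footprint. Overlapping or out-of-bounds plantings are an error.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=spec.length, p=probs).copy()

    footprints: list[range] = []
    for directive in spec.planted:
        fp = _plant_footprint(directive, spec.length)
        if fp.start < 0 or fp.stop > spec.length:
            raise PlantingError(f"{directive!r} does not fit in genome of length {spec.length}")
        for prev in footprints:
            if fp.start < prev.stop and prev.start < fp.stop:
                raise PlantingError(f"{directive!r} overlaps another planted directive")
        footprints.append(fp)

    margin = 25  # > tale_len_max + spacer slack: kills unplanned overlapping sites
    truth = TruthRecord()
    scrub = np.zeros(spec.length, dtype=bool)
    for directive, fp in zip(spec.planted, footprints):
        if getattr(directive, "exclusive", False):
            lo = max(0, fp.start - margin)
            hi = min(spec.length, fp.stop + margin)
            scrub[lo:hi] = True
    seq[scrub & (seq == ord("T"))] = ord("G")
    seq[scrub & (seq == ord("A"))] = ord("C")

    def write(pos: int, s: str) -> None:
        seq[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    for directive in spec.planted:
        if isinstance(directive, PlantTCMotif):
            c = directive.c_position
            if directive.strand == "+":
                write(c - 1, "TC")
            else:
                write(c, "GA")
            truth.planted.append(
                {"kind": "tc_motif", "c_position": c, "strand": directive.strand}
            )
        elif isinstance(directive, PlantMDdCBESite):
            ln, off = directive.site_length, directive.target_offset
            if directive.strand == "+":
                start = directive.start
                write(start, "T" + "G" * (ln - 2) + "T")
                t3 = start + ln - 1
                c_pos = t3 + off
                if off >= 2:
                    write(t3 + 1, "G" * (off - 2) + "TC")
                else:  # the site's own terminal T provides the context
                    write(c_pos, "C")
                motif_strand = "+"
            else:
                start = directive.start
                write(start, "A" + "C" * (ln - 2) + "A")
                t3 = start
                c_pos = t3 - off
                if off >= 2:
                    write(c_pos, "GA" + "C" * (off - 2))
                else:
                    write(c_pos, "G")
                motif_strand = "-"
            truth.planted.append(
                {
                    "kind": "mddcbe_site",
                    "site_start": start,
                    "site_end": start + ln,
                    "strand": directive.strand,
                    "t3": t3,
                    "c_position": c_pos,
                    "motif_strand": motif_strand,
                    "target_offset": off,
                }
            )
        elif isinstance(directive, PlantDdCBEPair):
            ln, sp = directive.site_length, directive.spacer_length
            m_off = directive.motif_offset
            if m_off is None:
                m_off = sp // 2
            if not 0 <= m_off < sp:
                raise PlantingError("motif_offset outside spacer")
            start = directive.start
            write(start, "T" + "G" * (ln - 2) + "T")
            spacer_start = start + ln
            spacer = ["G"] * sp
            if m_off == 0:  # left site's terminal T provides the context
                spacer[0] = "C"
            else:
                spacer[m_off - 1] = "T"
                spacer[m_off] = "C"
            # avoid an accidental GA motif at the spacer/right-site boundary
            if sp - 1 > m_off:
                spacer[sp - 1] = "C"
            write(spacer_start, "".join(spacer))
            right_start = spacer_start + sp
            write(right_start, "A" + "C" * (ln - 2) + "A")
            truth.planted.append(
                {
                    "kind": "ddcbe_pair",
                    "left_start": start,
                    "left_end": start + ln,
                    "spacer_start": spacer_start,
                    "spacer_end": right_start,
                    "right_start": right_start,
                    "right_end": right_start + ln,
                    "c_position": spacer_start + m_off,
                    "motif_strand": "+",
                }
            )

    genome = Genome(name=spec.name, sequence=seq.tobytes().decode(), circular=spec.circular)
    return genome, truth


def _sam_header(genome: Genome) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{genome.name}\tLN:{genome.length}\n"


def simulate_reads(
    genome: Genome,
    spec: EditSpec,
    sam_path: str | Path,
    fastq_path: str | Path | None = None,
) -> TruthRecord:
    """Write a pre-aligned SAM read set with programmed substitutions.

    Reads tile the genome once per depth round (step = read length, final
    read truncated), so every position is covered exactly ``depth`` times.
    At each programmed position the alternate base is drawn independently
    per read with the programmed fraction; sequencing errors then replace
    bases with a uniformly random different base. Base qualities are a
    constant Q37. Returns the truth record of programmed rates.
    """
    if spec.read_length > genome.length:
        raise PlantingError("read_length exceeds genome length")
    rng = np.random.default_rng(spec.seed)
    L = genome.length
    ref = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)

    programmed: dict[int, tuple[int, float]] = {}
    truth = TruthRecord()
    for pos, (alt, frac) in spec.per_position.items():
        ref_base = genome.sequence[pos]
        if ref_base not in _EDIT_PRODUCT or alt != _EDIT_PRODUCT[ref_base]:
            raise PlantingError(
                f"editing entry at {pos}: ref {ref_base} -> {alt} is not a "
                "C>T / G>A conversion"
            )
        programmed[pos] = (ord(alt), frac)
        truth.programmed_rates[pos] = (alt, frac)
    for pos, frac in spec.snv_positions.items():
        if pos in programmed:
            raise PlantingError(f"position {pos} both edited and SNV")
        alt = _TRANSITION[genome.sequence[pos]]
        programmed[pos] = (ord(alt), frac)
        truth.programmed_rates[pos] = (alt, frac)

    starts = list(range(0, L, spec.read_length))
    # per-tile programmed positions, precomputed once
    tile_prog: list[tuple[int, list[tuple[int, int, float]]]] = []
    for s in starts:
        ln = min(spec.read_length, L - s)
        inside = [
            (pos - s, alt, frac)
            for pos, (alt, frac) in sorted(programmed.items())
            if s <= pos < s + ln
        ]
        tile_prog.append((ln, inside))

    qual_char = chr(37 + 33)
    sam_path = Path(sam_path)
    fq = open(fastq_path, "w") if fastq_path is not None else None
    try:
        with open(sam_path, "w") as out:
            out.write(_sam_header(genome))
            for rnd in range(spec.depth):
                for tile, s in enumerate(starts):
                    ln, inside = tile_prog[tile]
                    bases = ref[s : s + ln].copy()
                    for local, alt, frac in inside:
                        if rng.random() < frac:
                            bases[local] = alt
                    if spec.sequencing_error_rate > 0.0:
                        err = np.flatnonzero(rng.random(ln) < spec.sequencing_error_rate)
                        for i in err.tolist():
                            others = _BASES[_BASES != bases[i]]
                            bases[i] = rng.choice(others)
                    seq_str = bases.tobytes().decode()
                    name = f"r{rnd:05d}t{tile:04d}"
                    out.write(
                        f"{name}\t0\t{genome.name}\t{s + 1}\t60\t{ln}M\t*\t0\t0\t"
                        f"{seq_str}\t{qual_char * ln}\n"
                    )
                    if fq is not None:
                        fq.write(f"@{name}\n{seq_str}\n+\n{qual_char * ln}\n")
    finally:
        if fq is not None:
            fq.close()
    return truth
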