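"""Genome-wide enumeration of base-editable 5'-TC targets.

DddA-derived cytosine base editors deaminate cytosines in a 5'-TC context
on either strand of double-stranded DNA. The dimeric architecture (DdCBE)
needs two TALE arrays bound on opposite strands flanking a 14-18 bp spacer
in which the target C must lie; the monomeric architecture (mDdCBE) needs a
single TALE array with the target C within a fixed window downstream of the
3'-terminal thymidine of its binding site. This module enumerates, for a
reference genome:

* all TC motifs (both strands),
* all candidate TALE binding sites (thymidine at both termini of the bound
  sequence, length 14-20 bp),
* all valid dimeric pair designs and monomeric designs, and
* the editability report: how many motifs each architecture can reach, and
  the fraction reachable only by the monomeric editor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genome import Genome, Interval, SequenceError, fetch_window


@dataclass(frozen=True)
class ScanParams:
    """Site/spacer/window constraints of the target search.

    Defaults encode the architecture's geometry: TALE arrays built with
    thymidine-preferring N-terminal domains bind 14-20 bp sites starting and
    ending with T; the split deaminase reconstitutes over a 14-18 bp spacer;
    the monomeric editor reaches cytosines within 18 bp downstream of the
    3'-terminal thymidine of a single site.

    ``window_anchor`` selects whether the "within ``mono_window`` bp" rule is
    measured to the motif's C (``"c"``, default) or to its T (``"t"``); the
    source analysis does not pin this down, so both are exposed.

    ``spacer_containment`` selects what part of a motif must lie inside a
    dimeric spacer for the motif to count as editable by that pair:
    ``"dinucleotide"`` (default) requires both the T and the C inside the
    spacer — a context base buried under a bound TALE array is not
    accessible to the deaminase; ``"c"`` requires only the target cytosine.
    The default is the convention under which the genome-wide
    monomeric-only fraction on human mtDNA reproduces the published 8.4%.
    """

    tale_len_min: int = 14
    tale_len_max: int = 20
    spacer_len_min: int = 14
    spacer_len_max: int = 18
    mono_window: int = 18
    require_terminal_t: bool = True
    window_anchor: str = "c"
    spacer_containment: str = "dinucleotide"

    def __post_init__(self) -> None:
        if not (1 <= self.tale_len_min <= self.tale_len_max):
            raise ValueError("require 1 <= tale_len_min <= tale_len_max")
        if not (1 <= self.spacer_len_min <= self.spacer_len_max):
            raise ValueError("require 1 <= spacer_len_min <= spacer_len_max")
        if self.mono_window < 1:
            raise ValueError("mono_window must be >= 1")
        if self.window_anchor not in ("c", "t"):
            raise ValueError("window_anchor must be 'c' or 't'")
        if self.spacer_containment not in ("dinucleotide", "c"):
            raise ValueError("spacer_containment must be 'dinucleotide' or 'c'")


@dataclass(frozen=True, order=True)
class TCMotif:
    """One editable cytosine.

    ``c_position`` is the forward-strand coordinate of the target C for a
    + strand motif, or of the forward-strand G paired with the edited C for
    a - strand motif (where the forward sequence reads GA).
    """

    c_position: int
    strand: str


@dataclass(frozen=True, order=True)
class TALESite:
    """A candidate TALE binding window; ``bound_sequence`` is read 5'->3' on
    the bound strand."""

    interval: Interval
    bound_sequence: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    def three_prime_end(self, genome_length: int) -> int:
        """Forward-strand coordinate of the 3'-terminal base of the bound
        sequence."""
        if self.strand == "+":
            return (self.interval.end - 1) % genome_length
        return self.interval.start % genome_length


@dataclass(frozen=True)
class DdCBEDesign:
    """A dimeric pair: left site bound on +, right site bound on -, spacer
    between them containing >= 1 TC motif."""

    left_site: TALESite
    right_site: TALESite
    spacer: Interval
    editable_motifs: frozenset[TCMotif]


@dataclass(frozen=True)
class MDdCBEDesign:
    """A monomeric design: one site plus the motifs within its downstream
    editing window, each with its strand-relative offset from the site's
    3'-terminal thymidine."""

    site: TALESite
    editable_motifs: frozenset[tuple[TCMotif, int]]


@dataclass(frozen=True)
class EditabilityReport:
    total_motifs: int
    ddcbe_editable: int
    mddcbe_editable: int
    mddcbe_only: int
    mddcbe_only_fraction: float  # percent of total motifs
    motif_annotations: dict[TCMotif, str] = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict:
        return {
            "total_motifs": self.total_motifs,
            "ddcbe_editable": self.ddcbe_editable,
            "mddcbe_editable": self.mddcbe_editable,
            "mddcbe_only": self.mddcbe_only,
            "mddcbe_only_fraction_percent": round(self.mddcbe_only_fraction, 1),
            "mddcbe_only_fraction_percent_exact": self.mddcbe_only_fraction,
        }


def find_tc_motifs(genome: Genome) -> list[TCMotif]:
    """All TC motifs on both strands, sorted by (c_position, strand).

    A forward-strand ``TC`` yields a + motif at the C; a forward-strand
    ``GA`` (the reverse-strand TC) yields a - motif at the G. On a circular
    genome the dinucleotide spanning the origin junction is included.
    """
    seq = genome.sequence
    L = genome.length
    motifs: list[TCMotif] = []
    last = L if genome.circular else L - 1
    for i in range(last):
        a = seq[i]
        b = seq[(i + 1) % L]
        if a == "T" and b == "C":
            motifs.append(TCMotif(c_position=(i + 1) % L, strand="+"))
        if a == "G" and b == "A":
            motifs.append(TCMotif(c_position=i, strand="-"))
    motifs.sort(key=lambda m: (m.c_position, m.strand))
    return motifs


def enumerate_tale_sites(genome: Genome, params: ScanParams) -> list[TALESite]:
    """Exhaustive list of candidate TALE sites on both strands.

    A + strand site binds the forward sequence directly; a - strand site
    binds the reverse complement, so its terminal-T requirement reads as A
    at both ends of the forward-strand interval. Order is deterministic:
    (start, length, strand).
    """
    seq = genome.sequence
    L = genome.length
    sites: list[TALESite] = []
    max_start = L if genome.circular else L - params.tale_len_min + 1
    for start in range(max(max_start, 0)):
        first = seq[start]
        for ln in range(params.tale_len_min, params.tale_len_max + 1):
            if not genome.circular and start + ln > L:
                break
            if ln > L:
                break
            last = seq[(start + ln - 1) % L]
            for strand, terminal in (("+", "T"), ("-", "A")):
                if params.require_terminal_t and (first != terminal or last != terminal):
                    continue
                sites.append(
                    TALESite(
                        interval=Interval(start=start, end=start + ln, strand=strand),
                        bound_sequence=fetch_window(genome, start, ln, strand),
                    )
                )
    sites.sort(key=lambda s: (s.interval.start, s.interval.length, s.strand))
    return sites


def _motif_lookup(genome: Genome) -> dict[int, TCMotif]:
    """Map forward coordinate -> motif. A position holds at most one motif
    (its base is either the C of a + motif or the G of a - motif)."""
    return {m.c_position: m for m in find_tc_motifs(genome)}


def _motifs_in_spacer(
    by_pos: dict[int, TCMotif],
    spacer_start: int,
    spacer_len: int,
    L: int,
    circular: bool,
    params: ScanParams,
) -> list[TCMotif]:
    """Motifs counting as inside the spacer [spacer_start, spacer_start+spacer_len)."""

    def offset_in_spacer(pos: int) -> int:
        return (pos - spacer_start) % L if circular else pos - spacer_start

    hits = []
    for k in range(spacer_len):
        p = (spacer_start + k) % L if circular else spacer_start + k
        motif = by_pos.get(p)
        if motif is None:
            continue
        if params.spacer_containment == "dinucleotide":
            partner = p - 1 if motif.strand == "+" else p + 1
            if circular:
                partner %= L
            if not 0 <= offset_in_spacer(partner) < spacer_len:
                continue
        hits.append(motif)
    return hits


def find_ddcbe_designs(genome: Genome, params: ScanParams) -> list[DdCBEDesign]:
    """All valid dimeric pair designs.

    Exactly one orientation is enumerated (left site on +, right site on -);
    the mirrored assignment is the same physical configuration viewed from
    the other strand. The spacer must be 14-18 bp and contain >= 1 TC motif
    per ``params.spacer_containment``. Designs whose total span exceeds a
    circular genome's length (sites overlapping through the wrap) are
    excluded.
    """
    sites = enumerate_tale_sites(genome, params)
    L = genome.length
    by_pos = _motif_lookup(genome)
    plus = [s for s in sites if s.strand == "+"]
    minus_by_start: dict[int, list[TALESite]] = {}
    for s in sites:
        if s.strand == "-":
            minus_by_start.setdefault(s.interval.start % L, []).append(s)

    designs: list[DdCBEDesign] = []
    for left in plus:
        l_end = left.interval.end
        for spacer_len in range(params.spacer_len_min, params.spacer_len_max + 1):
            r_start = l_end + spacer_len
            key = r_start % L if genome.circular else r_start
            for right in minus_by_start.get(key, []):
                span = left.interval.length + spacer_len + right.interval.length
                if span > L:
                    continue
                motifs = frozenset(
                    _motifs_in_spacer(by_pos, l_end, spacer_len, L, genome.circular, params)
                )
                if not motifs:
                    continue
                designs.append(
                    DdCBEDesign(
                        left_site=left,
                        right_site=right,
                        spacer=Interval(start=l_end, end=r_start, strand="+"),
                        editable_motifs=motifs,
                    )
                )
    designs.sort(
        key=lambda d: (d.left_site.interval.start, d.spacer.length, d.right_site.interval.length)
    )
    return designs


def _anchor_position(motif: TCMotif, L: int, anchor: str) -> int:
    """Forward coordinate of the base the mono window rule is measured to."""
    if anchor == "c":
        return motif.c_position
    # the motif's T: upstream of the C on the motif's own strand
    if motif.strand == "+":
        return (motif.c_position - 1) % L
    return (motif.c_position + 1) % L


def find_mddcbe_designs(genome: Genome, params: ScanParams) -> list[MDdCBEDesign]:
    """All monomeric designs: sites with >= 1 motif whose anchored base lies
    at strand-relative offset 1..mono_window downstream of the site's
    3'-terminal thymidine."""
    sites = enumerate_tale_sites(genome, params)
    L = genome.length
    by_pos = _motif_lookup(genome)
    anchored: dict[int, TCMotif] = {
        _anchor_position(m, L, params.window_anchor): m for m in by_pos.values()
    }
    designs: list[MDdCBEDesign] = []
    for site in sites:
        t3 = site.three_prime_end(L)
        step = 1 if site.strand == "+" else -1
        hits: list[tuple[TCMotif, int]] = []
        for offset in range(1, params.mono_window + 1):
            pos = t3 + step * offset
            if genome.circular:
                pos %= L
            elif pos < 0 or pos >= L:
                break
            motif = anchored.get(pos)
            if motif is not None:
                hits.append((motif, offset))
        if hits:
            designs.append(MDdCBEDesign(site=site, editable_motifs=frozenset(hits)))
    designs.sort(key=lambda d: (d.site.interval.start, d.site.interval.length, d.site.strand))
    return designs


def ddcbe_editable_motifs(designs: list[DdCBEDesign]) -> set[TCMotif]:
    out: set[TCMotif] = set()
    for d in designs:
        out |= d.editable_motifs
    return out


def mddcbe_editable_motifs(designs: list[MDdCBEDesign]) -> set[TCMotif]:
    out: set[TCMotif] = set()
    for d in designs:
        out |= {m for m, _ in d.editable_motifs}
    return out


def editability_report(genome: Genome, params: ScanParams | None = None) -> EditabilityReport:
    """Count motifs reachable by each architecture and the monomeric-only
    fraction. Editability is set membership on motif identity
    (c_position, strand): a motif reachable via many placements counts once.
    """
    params = params or ScanParams()
    motifs = find_tc_motifs(genome)
    dd = ddcbe_editable_motifs(find_ddcbe_designs(genome, params))
    md = mddcbe_editable_motifs(find_mddcbe_designs(genome, params))
    only = md - dd
    total = len(motifs)
    if total == 0:
        warnings.warn("genome contains no TC motifs; fraction reported as 0")
        fraction = 0.0
    else:
        fraction = 100.0 * len(only) / total
    annotations = {}
    for m in motifs:
        in_dd, in_md = m in dd, m in md
        annotations[m] = (
            "both" if in_dd and in_md else "ddcbe" if in_dd else "mddcbe" if in_md else "none"
        )
    return EditabilityReport(
        total_motifs=total,
        ddcbe_editable=len(dd),
        mddcbe_editable=len(md),
        mddcbe_only=len(only),
        mddcbe_only_fraction=fraction,
        motif_annotations=annotations,
    )
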