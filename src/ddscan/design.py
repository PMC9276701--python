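"""Design enumeration for a user-specified target cytosine.

Given one TC-context cytosine, list every dimeric pair whose spacer covers
it and every monomeric design whose downstream window reaches it, and rank
the monomeric designs by how the target sits relative to the empirically
preferred editing window (offsets 4-11 downstream of the TALE site).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome, SequenceError, fetch_window
from .scan import (
    DdCBEDesign,
    MDdCBEDesign,
    ScanParams,
    TCMotif,
    find_ddcbe_designs,
    find_mddcbe_designs,
)


@dataclass(frozen=True)
class WindowParams:
    """Preferred monomeric editing window, in 1-based offsets downstream of
    the 3'-terminal thymidine of the TALE site (default 4-11)."""

    preferred_min: int = 4
    preferred_max: int = 11

    def __post_init__(self) -> None:
        if not (1 <= self.preferred_min <= self.preferred_max):
            raise ValueError("require 1 <= preferred_min <= preferred_max")


@dataclass(frozen=True)
class RankedDesign:
    """A monomeric design scored by target placement.

    ``rank_score`` is 1/(1+d) where d is the distance of ``target_offset``
    to the preferred window (0 inside): the window itself is all the
    underlying data defines, so any bounded monotone transform of the
    distance serves; this one is documented and stable.
    """

    design: MDdCBEDesign
    target_offset: int
    in_preferred_window: bool
    rank_score: float


@dataclass(frozen=True)
class TargetDesignReport:
    """All designs covering one target cytosine. Monomeric designs are
    ranked; dimeric designs carry no intra-spacer position preference and
    are listed unranked."""

    target: TCMotif
    monomeric: tuple[RankedDesign, ...]
    dimeric: tuple[DdCBEDesign, ...]


def _validate_target(genome: Genome, c_position: int, strand: str) -> TCMotif:
    L = genome.length
    if not 0 <= c_position < L:
        raise SequenceError(f"position {c_position} outside genome of length {L}")
    if strand == "+":
        if c_position == 0 and not genome.circular:
            context = "." + genome.sequence[0]
        else:
            context = fetch_window(genome, (c_position - 1) % L, 2, "+")
        if context != "TC":
            raise SequenceError(
                f"position {c_position} (+) is not a TC-context cytosine: "
                f"observed dinucleotide {context!r}"
            )
    elif strand == "-":
        if c_position == L - 1 and not genome.circular:
            context = genome.sequence[c_position] + "."
        else:
            context = fetch_window(genome, c_position, 2, "+")
        if context != "GA":
            raise SequenceError(
                f"position {c_position} (-) is not a TC-context cytosine: "
                f"observed forward dinucleotide {context!r} (expected 'GA')"
            )
    else:
        raise SequenceError(f"invalid strand {strand!r}")
    return TCMotif(c_position=c_position, strand=strand)


def rank_offset(offset: int, window: WindowParams) -> tuple[bool, float]:
    """(inside preferred window, rank score) for a monomeric target offset."""
    if window.preferred_min <= offset <= window.preferred_max:
        return True, 1.0
    d = (
        window.preferred_min - offset
        if offset < window.preferred_min
        else offset - window.preferred_max
    )
    return False, 1.0 / (1.0 + d)


def design_for_target(
    genome: Genome,
    c_position: int,
    strand: str,
    scan_params: ScanParams | None = None,
    window_params: WindowParams | None = None,
) -> TargetDesignReport:
    """Every design that can edit the given target cytosine.

    Monomeric designs are sorted best-first: inside-window first, then by
    distance to the window (via ``rank_score``), ties broken by shorter
    offset, then by smaller site start.
    """
    scan_params = scan_params or ScanParams()
    window_params = window_params or WindowParams()
    target = _validate_target(genome, c_position, strand)

    dimeric = tuple(
        d for d in find_ddcbe_designs(genome, scan_params) if target in d.editable_motifs
    )

    ranked: list[RankedDesign] = []
    for d in find_mddcbe_designs(genome, scan_params):
        for motif, offset in d.editable_motifs:
            if motif == target:
                inside, score = rank_offset(offset, window_params)
                ranked.append(
                    RankedDesign(
                        design=d,
                        target_offset=offset,
                        in_preferred_window=inside,
                        rank_score=score,
                    )
                )
    ranked.sort(
        key=lambda r: (-r.rank_score, r.target_offset, r.design.site.interval.start)
    )
    return TargetDesignReport(target=target, monomeric=tuple(ranked), dimeric=dimeric)
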