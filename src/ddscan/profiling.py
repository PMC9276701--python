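"""Editing-window profiling relative to TALE binding sites.

Monomeric editors deaminate downstream of the 3'-terminal thymidine of
their single binding site. Mapping per-position editing frequencies of many
constructs into strand-relative offsets (1-based from that thymidine, the
same coordinate system as the scan's ``mono_window``) and averaging across
constructs recovers the empirical editing window — elevated conversion at
offsets 4-11.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome, SequenceError
from .scan import TALESite


@dataclass(frozen=True)
class SiteProfile:
    """Editing percentages of one construct, keyed by strand-relative
    offset downstream of its TALE site."""

    site: TALESite
    frequencies: dict[int, float]

    def __post_init__(self) -> None:
        for off, pct in self.frequencies.items():
            if off < 1:
                raise ValueError(f"offset {off} < 1")
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage {pct} outside [0, 100]")


@dataclass(frozen=True)
class EditingWindowProfile:
    per_offset_mean: dict[int, float]
    per_offset_n: dict[int, int]
    called_window: tuple[int, int] | None

    def as_dict(self) -> dict:
        return {
            "per_offset_mean": {str(k): v for k, v in sorted(self.per_offset_mean.items())},
            "per_offset_n": {str(k): v for k, v in sorted(self.per_offset_n.items())},
            "called_window": list(self.called_window) if self.called_window else None,
        }


def offset_to_coordinate(site: TALESite, offset: int, genome: Genome) -> int:
    """Forward-strand coordinate at a strand-relative downstream offset."""
    L = genome.length
    t3 = site.three_prime_end(L)
    pos = t3 + offset if site.strand == "+" else t3 - offset
    if genome.circular:
        return pos % L
    if not 0 <= pos < L:
        raise SequenceError(f"offset {offset} falls outside linear genome")
    return pos


def align_profile_to_site(
    site: TALESite,
    genome_position_frequencies: dict[int, float],
    genome: Genome,
) -> SiteProfile:
    """Convert forward-coordinate frequencies into site-relative offsets.

    Positions at or upstream of the site's 3'-terminal base (offset <= 0)
    are dropped; minus-strand sites flip orientation, so downstream means
    decreasing forward coordinate. On a circular genome every non-site
    position is downstream at some wrapped offset; callers interested only
    in the editing window should restrict the input accordingly.
    """
    L = genome.length
    t3 = site.three_prime_end(L)
    sign = 1 if site.strand == "+" else -1
    freqs: dict[int, float] = {}
    for coord, pct in genome_position_frequencies.items():
        if not 0 <= coord < L:
            raise SequenceError(f"coordinate {coord} outside genome of length {L}")
        delta = sign * (coord - t3)
        if genome.circular:
            delta %= L
        if delta <= 0:
            continue
        freqs[delta] = pct
    return SiteProfile(site=site, frequencies=freqs)


def aggregate_window(
    profiles: list[SiteProfile], threshold_fraction: float = 0.5
) -> EditingWindowProfile:
    """Mean per-offset percentage across constructs and the called window.

    The called window is the maximal contiguous run of observed offsets,
    containing the peak offset, whose mean is >= ``threshold_fraction``
    times the peak mean. The relative-height rule is a documented artifact
    choice — the underlying data define the window only loosely — and the
    threshold is exposed. All-zero profiles yield no called window.
    """
    if not profiles:
        raise ValueError("need >= 1 profile")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    sums: dict[int, float] = {}
    ns: dict[int, int] = {}
    for prof in profiles:
        for off, pct in prof.frequencies.items():
            sums[off] = sums.get(off, 0.0) + pct
            ns[off] = ns.get(off, 0) + 1
    means = {off: sums[off] / ns[off] for off in sums}
    if not means:
        return EditingWindowProfile(per_offset_mean={}, per_offset_n={}, called_window=None)
    peak_mean = max(means.values())
    if peak_mean <= 0.0:
        return EditingWindowProfile(per_offset_mean=means, per_offset_n=ns, called_window=None)
    peak = min(off for off, m in means.items() if m == peak_mean)
    cut = threshold_fraction * peak_mean
    lo = peak
    while lo - 1 in means and means[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi + 1 in means and means[hi + 1] >= cut:
        hi += 1
    return EditingWindowProfile(per_offset_mean=means, per_offset_n=ns, called_window=(lo, hi))
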