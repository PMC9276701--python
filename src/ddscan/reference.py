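"""Naive reference enumerators for the targetability scan.

Everything here re-derives the site/spacer/window criteria literally from
window strings, one candidate at a time, without sharing any logic with the
optimized scan in :mod:`ddscan.scan`. It is deliberately slow (quadratic in
genome length for pair enumeration) and exists as an independent
cross-check; use it only on small genomes.
"""

from __future__ import annotations

from .genome import Genome, fetch_window
from .scan import ScanParams


def naive_tc_motifs(genome: Genome) -> set[tuple[int, str]]:
    """(c_position, strand) of every TC motif, by literal window inspection."""
    L = genome.length
    out: set[tuple[int, str]] = set()
    for pos in range(L):
        base = genome.sequence[pos]
        if base == "C":
            # + motif: the base 5' of the C on the forward strand is T
            if pos > 0 or genome.circular:
                if fetch_window(genome, (pos - 1) % L, 2, "+") == "TC":
                    out.add((pos, "+"))
        elif base == "G":
            # - motif: reading the reverse strand 5'->3' across (pos, pos+1) gives TC
            if pos < L - 1 or genome.circular:
                if fetch_window(genome, pos, 2, "-") == "TC":
                    out.add((pos, "-"))
    return out


def naive_tale_sites(genome: Genome, params: ScanParams) -> set[tuple[int, int, str]]:
    """(start, length, strand) of every valid site: bound-strand sequence
    begins and ends with T, length within bounds."""
    L = genome.length
    out: set[tuple[int, int, str]] = set()
    for start in range(L):
        for ln in range(params.tale_len_min, params.tale_len_max + 1):
            if ln > L:
                continue
            if not genome.circular and start + ln > L:
                continue
            for strand in ("+", "-"):
                bound = fetch_window(genome, start, ln, strand)
                if not params.require_terminal_t or (
                    bound.startswith("T") and bound.endswith("T")
                ):
                    out.add((start, ln, strand))
    return out


def _is_motif(genome: Genome, pos: int, strand: str) -> bool:
    """Literal test: does forward position pos carry the target C of a motif
    on the given strand?"""
    L = genome.length
    base = genome.sequence[pos]
    if strand == "+":
        if base != "C" or (pos == 0 and not genome.circular):
            return False
        return fetch_window(genome, (pos - 1) % L, 2, "+") == "TC"
    if base != "G" or (pos == L - 1 and not genome.circular):
        return False
    return fetch_window(genome, pos, 2, "-") == "TC"


def _motif_strand_at(genome: Genome, pos: int) -> str | None:
    """Strand of the motif whose target C maps to forward position pos, if any."""
    if _is_motif(genome, pos, "+"):
        return "+"
    if _is_motif(genome, pos, "-"):
        return "-"
    return None


def naive_ddcbe_designs(
    genome: Genome, params: ScanParams
) -> set[tuple[int, int, int, int, frozenset[tuple[int, str]]]]:
    """Every valid dimeric pair as
    (left_start, left_len, right_start, right_len, motifs).

    Literal double loop over all + site / - site combinations.
    """
    L = genome.length
    sites = naive_tale_sites(genome, params)
    plus = [(s, ln) for (s, ln, st) in sites if st == "+"]
    minus = [(s, ln) for (s, ln, st) in sites if st == "-"]
    out = set()
    for ls, ll in plus:
        for rs, rl in minus:
            if genome.circular:
                spacer_len = (rs - (ls + ll)) % L
            else:
                spacer_len = rs - (ls + ll)
            if not params.spacer_len_min <= spacer_len <= params.spacer_len_max:
                continue
            if ll + spacer_len + rl > L:
                continue
            spacer_positions = [(ls + ll + k) % L for k in range(spacer_len)]
            motifs = set()
            for p in spacer_positions:
                strand = _motif_strand_at(genome, p)
                if strand is None:
                    continue
                if params.spacer_containment == "dinucleotide":
                    partner = (p - 1) % L if strand == "+" else (p + 1) % L
                    if partner not in spacer_positions:
                        continue
                motifs.add((p, strand))
            if motifs:
                out.add((ls, ll, rs, rl, frozenset(motifs)))
    return out


def naive_mddcbe_designs(
    genome: Genome, params: ScanParams
) -> set[tuple[int, int, str, frozenset[tuple[int, str, int]]]]:
    """Every valid monomeric design as
    (start, length, strand, {(c_position, motif_strand, offset)}).

    For each site, walk 1..mono_window bases downstream of the 3'-terminal
    thymidine on the bound strand and test each position literally for an
    anchored motif.
    """
    L = genome.length
    out = set()
    for start, ln, strand in naive_tale_sites(genome, params):
        if strand == "+":
            t3 = (start + ln - 1) % L
            step = 1
        else:
            t3 = start % L
            step = -1
        hits = set()
        for offset in range(1, params.mono_window + 1):
            pos = t3 + step * offset
            if genome.circular:
                pos %= L
            elif pos < 0 or pos >= L:
                break
            for mstrand in ("+", "-"):
                # anchored base at pos: the C itself, or the T whose C is adjacent
                if params.window_anchor == "c":
                    cpos = pos
                else:
                    cpos = (pos + 1) % L if mstrand == "+" else (pos - 1) % L
                    if not genome.circular and not 0 <= cpos < L:
                        continue
                if _is_motif(genome, cpos, mstrand):
                    hits.add((cpos, mstrand, offset))
        if hits:
            out.add((start, ln, strand, frozenset(hits)))
    return out


def naive_editable_sets(
    genome: Genome, params: ScanParams
) -> tuple[set[tuple[int, str]], set[tuple[int, str]]]:
    """(ddcbe-editable, mddcbe-editable) motif identity sets."""
    dd: set[tuple[int, str]] = set()
    for *_, motifs in naive_ddcbe_designs(genome, params):
        dd |= motifs
    md: set[tuple[int, str]] = set()
    for *_, hits in naive_mddcbe_designs(genome, params):
        md |= {(c, s) for (c, s, _o) in hits}
    return dd, md
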