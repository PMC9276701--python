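"""Per-position C>T / G>A conversion calling from aligned reads.

A conversion rate at a reference C is the fraction of high-quality covering
read bases showing T (at a reference G: showing A — the same biological
C>T event read from the other strand; the two are pooled downstream as
C*G-to-T*A editing). The off-target summary applies the study's filters:
positions inside on-target windows are removed, positions converted at
>= 50% are removed as pre-existing cell-line variants (apparent
homoplasmy/heteroplasmy rather than editing), the genome-wide mean is taken
over ALL remaining C/G positions, and positions at >= 0.1% are reported as
candidate off-target sites. Averaging over all retained positions — not
only candidates — is what makes a sub-threshold mean (an untreated
control's ~0.02%) arithmetically possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import Genome, Interval


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the caller.

    ``min_candidate_rate`` (0.1%) and ``snv_exclusion_rate`` (50%) define
    the candidate and variant-exclusion filters; depth and quality cutoffs
    are conventional pileup hygiene (surfaced in every report header, since
    absolute off-target means depend on them).
    """

    min_candidate_rate: float = 0.001
    snv_exclusion_rate: float = 0.5
    min_depth: int = 100
    min_base_quality: int = 20
    min_mapping_quality: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.min_candidate_rate < self.snv_exclusion_rate <= 1:
            raise ValueError(
                "require 0 < min_candidate_rate < snv_exclusion_rate <= 1"
            )


@dataclass(frozen=True)
class PositionConversion:
    position: int
    ref_base: str
    depth: int
    converted: int

    @property
    def rate(self) -> float:
        return self.converted / self.depth


@dataclass(frozen=True)
class PileupResult:
    """Conversions at C/G positions meeting ``min_depth``; positions whose
    coverage fell below it are flagged in ``insufficient_depth`` rather than
    silently reported as zero."""

    conversions: tuple[PositionConversion, ...]
    insufficient_depth: tuple[int, ...]


@dataclass(frozen=True)
class OffTargetSummary:
    mean_offtarget_rate: float
    n_positions_retained: int
    n_excluded_snv: int
    n_excluded_target: int
    candidates: tuple[PositionConversion, ...]

    def as_dict(self) -> dict:
        return {
            "mean_offtarget_rate": self.mean_offtarget_rate,
            "mean_offtarget_percent": 100.0 * self.mean_offtarget_rate,
            "n_positions_retained": self.n_positions_retained,
            "n_excluded_snv": self.n_excluded_snv,
            "n_excluded_target": self.n_excluded_target,
            "n_candidates": len(self.candidates),
            "candidates": [
                {
                    "position": c.position,
                    "ref_base": c.ref_base,
                    "depth": c.depth,
                    "converted": c.converted,
                    "rate": c.rate,
                }
                for c in self.candidates
            ],
        }


_CONVERTED_BASE = {"C": "T", "G": "A"}


def pileup_conversions(
    alignments: str | Path,
    genome: Genome,
    params: CallerParams | None = None,
) -> PileupResult:
    """Pile up a SAM file and count conversion evidence at every reference
    C and G.

    Depth at a position counts reads contributing a high-quality call of
    any nucleotide there (mismatches to bases other than the conversion
    product stay in the denominator); deletions, skips and N calls are
    excluded. Overlapping segments sharing a query name (mate pairs) are
    counted once, the higher-quality base winning. Input need not be
    sorted.
    """
    params = params or CallerParams()
    path = str(alignments)
    L = genome.length
    ref_arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    is_cg = (ref_arr == ord("C")) | (ref_arr == ord("G"))
    # conversion product per reference position: T at C, A at G
    product = np.zeros(L, dtype=np.uint8)
    product[ref_arr == ord("C")] = ord("T")
    product[ref_arr == ord("G")] = ord("A")

    depth = np.zeros(L, dtype=np.int64)
    converted = np.zeros(L, dtype=np.int64)

    def tally(rpos: np.ndarray, bases: np.ndarray) -> None:
        if rpos.size and rpos.max() >= L:
            raise CallingError(
                f"alignment position {int(rpos.max())} beyond reference length {L}"
            )
        mask = is_cg[rpos]
        rp = rpos[mask]
        np.add.at(depth, rp, 1)
        conv = bases[mask] == product[rp]
        np.add.at(converted, rp[conv], 1)

    # paired reads are buffered and merged per query name so a mate-overlapped
    # position is counted once, the higher-quality base winning
    pending: dict[str, dict[int, tuple[int, int]]] = {}

    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        names = list(sam.references)
        if genome.name not in names:
            raise CallingError(
                f"reference {genome.name!r} not in SAM header references {names}"
            )
        for read in sam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
                or read.is_duplicate
            ):
                continue
            if read.reference_name != genome.name:
                continue
            if read.mapping_quality < params.min_mapping_quality:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
            rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
            bases = np.frombuffer(seq.encode(), dtype=np.uint8)[qpos]
            quals = read.query_qualities
            if quals is not None:
                q = np.asarray(quals, dtype=np.int64)[qpos]
            else:
                q = np.full(len(pairs), 255, dtype=np.int64)
            keep = (q >= params.min_base_quality) & (bases != ord("N"))
            rpos, bases, q = rpos[keep], bases[keep], q[keep]
            if read.is_paired:
                best = pending.setdefault(read.query_name, {})
                for rp, b, qv in zip(rpos.tolist(), bases.tolist(), q.tolist()):
                    prev = best.get(rp)
                    if prev is None or qv > prev[1]:
                        best[rp] = (b, qv)
            else:
                tally(rpos, bases)

    for best in pending.values():
        if not best:
            continue
        rpos = np.fromiter(best.keys(), dtype=np.int64, count=len(best))
        bases = np.fromiter((b for b, _ in best.values()), dtype=np.uint8, count=len(best))
        tally(rpos, bases)

    records: list[PositionConversion] = []
    shallow: list[int] = []
    for pos in np.flatnonzero(is_cg).tolist():
        if depth[pos] >= params.min_depth:
            records.append(
                PositionConversion(
                    position=pos,
                    ref_base=genome.sequence[pos],
                    depth=int(depth[pos]),
                    converted=int(converted[pos]),
                )
            )
        elif depth[pos] > 0:
            shallow.append(pos)
    return PileupResult(conversions=tuple(records), insufficient_depth=tuple(shallow))


def quantify_on_target(
    conversions: tuple[PositionConversion, ...] | list[PositionConversion],
    window: Interval,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Per-position editing percentages restricted to one window.

    Numbers are identical to the genome-wide computation at those
    positions — this is the substitution part of the amplicon-style
    "reads containing base conversions among total reads" quantification.
    """
    rows = [
        {
            "position": c.position,
            "ref_base": c.ref_base,
            "depth": c.depth,
            "converted": c.converted,
            "percent": 100.0 * c.rate,
        }
        for c in conversions
        if window.contains(c.position, genome_length)
    ]
    return pd.DataFrame(rows, columns=["position", "ref_base", "depth", "converted", "percent"])


def summarize_offtarget(
    conversions: tuple[PositionConversion, ...] | list[PositionConversion],
    target_windows: list[Interval],
    params: CallerParams | None = None,
    genome_length: int | None = None,
) -> OffTargetSummary:
    """Genome-wide off-target summary with the study's exclusions.

    Positions inside any on-target window are removed first; of the rest,
    positions with conversion rate >= ``snv_exclusion_rate`` (inclusive) are
    removed as cell-line variants. The mean is over all retained C/G
    positions; candidates are the retained positions at
    >= ``min_candidate_rate``.
    """
    params = params or CallerParams()
    on_target: list[PositionConversion] = []
    snv: list[PositionConversion] = []
    retained: list[PositionConversion] = []
    for c in conversions:
        if any(w.contains(c.position, genome_length) for w in target_windows):
            on_target.append(c)
        elif c.rate >= params.snv_exclusion_rate:
            snv.append(c)
        else:
            retained.append(c)
    if not retained:
        raise CallingError("no retained positions; refusing to report a mean of nothing")
    mean = sum(c.rate for c in retained) / len(retained)
    candidates = tuple(
        sorted(
            (c for c in retained if c.rate >= params.min_candidate_rate),
            key=lambda c: c.position,
        )
    )
    return OffTargetSummary(
        mean_offtarget_rate=mean,
        n_positions_retained=len(retained),
        n_excluded_snv=len(snv),
        n_excluded_target=len(on_target),
        candidates=candidates,
    )
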