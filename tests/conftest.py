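from __future__ import annotations

import pytest

from ddscan.genome import Genome

# 42-bp dimeric construct: left T-ended site, 14-bp spacer with one TC motif,
# right site bound on the minus strand
DDCBE_CONSTRUCT = "TGGGGGGGGGGGGT" + "GGGGGGTCGGGGGG" + "AGGGGGGGGGGGGA"
# 21-bp monomeric construct: T-ended site plus a TC motif 5 bp downstream
MDDCBE_CONSTRUCT = "TGGGGGGGGGGGGT" + "GGGTCGG"


@pytest.fixture
def ddcbe_genome() -> Genome:
    return Genome(name="pair", sequence=DDCBE_CONSTRUCT, circular=False)


@pytest.fixture
def mddcbe_genome() -> Genome:
    return Genome(name="mono", sequence=MDDCBE_CONSTRUCT, circular=False)


def write_sam(path, genome: Genome, reads, extra_header: str = "") -> str:
    """Write a minimal SAM file.

    ``reads`` is an iterable of dicts with keys name, pos (0-based), seq and
    optionally flag, mapq, qual, cigar.
    """
    lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{genome.name}\tLN:{genome.length}"]
    if extra_header:
        lines.append(extra_header.rstrip("\n"))
    for r in reads:
        seq = r["seq"]
        qual = r.get("qual", "I" * len(seq))
        cigar = r.get("cigar", f"{len(seq)}M")
        lines.append(
            "\t".join(
                [
                    r["name"],
                    str(r.get("flag", 0)),
                    r.get("rname", genome.name),
                    str(r["pos"] + 1),
                    str(r.get("mapq", 60)),
                    cigar,
                    "*",
                    "0",
                    "0",
                    seq,
                    qual,
                ]
            )
        )
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def rotate(seq: str, k: int) -> str:
    k %= len(seq)
    return seq[k:] + seq[:k]
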