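# Methods

## Scope and model

`ddscan` implements the computational side of mitochondrial base-editor
design and evaluation for DddA-derived cytosine base editors: enumeration
of editable 5′-TC targets for the dimeric (DdCBE) and monomeric (mDdCBE)
architectures, per-target design ranking, per-position C•G→T•A conversion
calling from aligned reads with genome-wide off-target summarization, and
editing-window profiling. Read alignment, indel quantification and nuclear
off-target analysis are out of scope; the caller consumes aligned SAM and
the simulator emits pre-aligned records.

## Coordinates and topology

All coordinates are 0-based, half-open, forward-strand; strand-specific
sequences are derived views (BED-compatible; user-facing tables add
1-based columns). Organellar genomes are treated as circular by default:
motif, site and spacer windows may span the origin junction, with an
interval's `end` exceeding the genome length as the unwrapped image of a
wrapped window. Linear treatment is a flag. On human mtDNA the choice moves
the monomeric-only fraction from 8.365% (circular) to 8.751% (linear);
both values are tabulated in every scan report. Ambiguity codes other than
N are rejected rather than expanded, since expansion would silently change
motif counts; N never matches any scan pattern, but a window containing
interior N can still be a TALE site if its terminal bases are T.

## Targetability scan

A TC motif is identified by the forward-strand coordinate of its target C
(for bottom-strand motifs, of the forward G paired with the edited C) plus
a strand. TALE sites are all 14–20 bp windows with T at both ends of the
bound strand, on both strands. Dimeric designs pair a + strand site with a
− strand site across a 14–18 bp spacer containing ≥1 motif; exactly one
orientation is enumerated, because the mirrored left/right assignment is
the same physical configuration seen from the other strand — this is what
makes the scan exactly strand-symmetric. Monomeric designs list motifs at
strand-relative offsets 1–18 downstream of a site's 3′-terminal thymidine.
Editability is deduplicated to motif identity; the headline fraction is
|monomeric-only| / |all motifs|.

Two conventions the criteria leave open are exposed as parameters:

* `window_anchor` (`c` default | `t`): whether the 18 bp monomeric window
  is measured to the motif's C or its T. On human mtDNA the choice is
  immaterial (the monomeric-editable set saturates either way).
* `spacer_containment` (`dinucleotide` default | `c`): whether a motif
  counts as inside a dimeric spacer only when both bases of the
  dinucleotide lie in the spacer, or whenever its C does. The strict
  convention is the default on two grounds: mechanistically, a context T
  buried under a bound TALE array is not accessible to the deaminase; and
  empirically, it is the convention under which the genome-wide
  monomeric-only fraction on human mtDNA reproduces the published 8.4%
  (the C-only convention yields 4.6%).

Dimeric designs whose total span (left site + spacer + right site) exceeds
a circular genome's length are excluded — the two sites would physically
overlap through the wrap. This never triggers at organelle scale and
matters only for tiny synthetic genomes.

A deliberately naive enumerator (`ddscan.reference`) re-derives every
criterion literally from window strings — per-candidate string inspection,
quadratic pair loops — and shares no logic with the optimized scan. The
test suite requires exact set equality between the two on hundreds of
random genomes under all convention combinations, alongside
reverse-complement invariance, full rotation invariance on circular
genomes, monotonicity in the window/spacer parameters, and the set algebra
of the report.

## Reference sequence

The bundled human mtDNA FASTA is NC_001807.4 (16,571 bp), the older human
mitochondrial reference, included because it is redistributable sequence
data available to the package; any user FASTA (in particular the rCRS,
NC_012920, 16,569 bp) is accepted. The two references differ at a few
dozen positions; on the bundled sequence the scan yields 1,817 motifs,
1,665 dimeric-editable, 152 monomeric-only = 8.365% → 8.4% at the one-
decimal precision at which the fraction is conventionally quoted.

## Design ranking

For a validated target cytosine, all covering dimeric and monomeric
designs are returned. Monomeric designs are ranked by placement of the
target relative to the preferred editing window (offsets 4–11):
`rank_score = 1/(1+d)` with `d` the distance to the window (0 inside).
The underlying data define only a window, not a positional efficiency
model, so any bounded monotone transform of the distance is equally
defensible; this one is simple and stable. Ties break by shorter offset,
then smaller site start. Dimeric designs are reported unranked — no
intra-spacer position preference is defined for pairs.

## Conversion calling

The caller piles up a SAM file natively. At each reference C (G), depth
counts reads contributing a base call of any nucleotide with base quality
≥20 from reads with mapping quality ≥20 (defaults, overridable);
deletions, reference skips and N calls are excluded from depth; only T at
a reference C (A at a reference G) counts as converted, and mismatches to
other bases remain in the denominator, matching standard variant-fraction
practice. Paired segments sharing a query name are merged per position
before counting, the higher-quality base winning, so mate-overlapped
amplicon coverage is not double-counted. Positions below the depth floor
(default 100) are flagged as insufficient rather than reported as zero.

The off-target summary excludes positions inside any on-target window,
then positions converted at ≥50% (inclusive) as pre-existing cell-line
variants. The genome-wide mean is taken over **all** retained C/G
positions; the ≥0.1% threshold defines only the reported candidate list.
This ordering of semantics is forced by arithmetic: an untreated control
averages ~0.02%, which would be impossible if the mean ran over only
positions passing the 0.1% cut. Depth/quality cutoffs are echoed in every
report header because absolute genome-wide means depend on them;
consequently, published absolute off-target averages from other samples
are only comparable under matched caller settings.

## Synthetic data

The genome generator draws background bases from a GC fraction (default
0.44, human-mtDNA-like) and plants directives last: bare TC motifs,
monomeric site layouts (T-terminated site plus one motif at a requested
downstream offset), and dimeric pair layouts (left site, spacer with one
motif, right site), each with its footprint collision-checked. Directives
marked exclusive get a 25 bp margin scrubbed of T/A so that no unplanned
T-ended window overlaps the planted footprint; planted bases themselves can
still combine into additional valid windows (e.g. a site's 5′ T with a
planted motif's T), which the scan correctly reports — recovery tests
assert presence of the planted design, not uniqueness.

The read simulator tiles the genome once per depth round (step = read
length, final read truncated), so interior coverage is exact, and emits
pre-aligned single-end SAM records with constant Q37 base qualities, flag
0 and mapping quality 60. At each programmed position the alternate base
is drawn per read as an independent Bernoulli trial: editing entries are
restricted to C→T/G→A; cell-line variant entries substitute the transition
partner of the reference base at the requested fraction (1.0 ≈
homoplasmy). Uniform sequencing error is applied after programmed
substitution to a uniformly random different base, so realized fractions
at non-programmed positions sit near 2ε/3 toward any one alternative and
recovery tolerances account for it. Identical specs and seeds give
byte-identical FASTA/SAM output. The simulator does not model quality
decay, strand bias, PCR duplicates or structural variation; passing
recovery tests therefore demonstrate correctness of the counting and
filtering logic under ideal noise, not robustness to real library
artifacts.

## Window profiling

Per-position frequencies are mapped to 1-based strand-relative offsets
from a site's 3′-terminal thymidine (the same coordinate system as the
monomeric scan window); offsets ≤0 are dropped, and minus-strand sites
flip orientation. Aggregation averages each offset over the profiles that
observe it. The called window is the maximal contiguous run of observed
offsets containing the peak whose mean is ≥50% of the peak mean; the
relative-height rule and its threshold are exposed and recorded in output
metadata, since the window is defined only loosely by the data. All-zero
profiles call no window; uniform profiles call the full contiguous
observed range.

## Problem sizes in tests and the acceptance script

The shipped checks run the oracle-equivalence comparison on 200 random
genomes of 60–300 bp, rotation invariance over every rotation of 20
circular genomes of 200–300 bp, off-target recovery at depth 1000 over a
1,500 bp genome (50 background positions at 0.3%, two homoplasmic
variants, one 20% on-target window), the control-level background at
depth 10,000 over 300 bp (uniform 0.02%), and on-target requantification
at depth 2,000. These sizes give binomial standard errors small enough for
3-sigma recovery assertions while keeping the whole suite inside a couple
of minutes on one core. Wet-lab editing magnitudes reported for specific
constructs (tens of percent on-target; absolute off-target averages of
0.018–0.23%) depend on cells and on the original caller settings and are
represented here only through programmed simulations of the same
magnitudes.

## Known limitations

* The bundled reference is NC_001807.4, not the rCRS; per-motif
  coordinates differ slightly between the two (supply an rCRS FASTA for
  revised-coordinate output).
* TALE binding is modeled purely by the terminal-thymidine and length
  rules; no RVD-level affinity, mismatch tolerance or composition rules.
* The caller handles substitutions only; indels are ignored by
  construction of the aligned-pair walk.
* Circular-genome support assumes reads themselves do not wrap the origin
  (the simulator never emits wrapping reads; aligners conventionally
  soft-clip them).
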