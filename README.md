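# ddscan

Target scanning and conversion calling for DddA-derived cytosine base
editors on organellar genomes.

DddA<sub>tox</sub> deaminates cytosines in a 5′-TC context on
double-stranded DNA. Fused to TALE DNA-binding arrays it yields two editor
architectures for mitochondrial (and chloroplast) genome editing:

* **DdCBE** — dimeric: two TALE arrays, each carrying an inactive half of
  the deaminase, bind opposite strands flanking a 14–18 bp spacer; the
  reconstituted enzyme edits TC motifs inside the spacer.
* **mDdCBE** — monomeric: one TALE array fused to a non-toxic full-length
  deaminase edits TC motifs within 18 bp downstream of the 3′-terminal
  thymidine of its single binding site.

Because conventional TALE arrays require thymidine at both termini of the
bound site, some cytosines can only be reached by the monomeric
architecture. `ddscan` answers, for any reference genome, *which* cytosines
each architecture can reach, designs editors for a chosen target, and
quantifies realized editing — on-target frequencies and genome-wide
off-target C•G→T•A conversion — from aligned amplicon or
whole-organelle-genome reads. It is aimed at groups designing mitochondrial
base-editing experiments and at reanalysis of their deep-sequencing output.

## The scan criteria

With coordinates 0-based and half-open on the forward strand:

* a **TC motif** is a 5′-TC dinucleotide on either strand (forward `TC`,
  or forward `GA` read as TC on the bottom strand); the C is the editable
  base;
* a **TALE site** is any 14–20 bp window whose bound-strand sequence starts
  and ends with T;
* a **dimeric design** is a + strand site and a − strand site separated by
  a 14–18 bp spacer containing at least one TC motif (both bases of the
  dinucleotide inside the spacer, so the context T is not buried under a
  bound TALE);
* a **monomeric design** is a site with at least one motif whose C lies at
  offset 1–18 downstream of the site's 3′-terminal thymidine (strand-
  relative; the anchor can be switched to the motif's T with
  `--window-anchor t`).

Editability is set membership on motif identity `(c_position, strand)`:
a motif reachable through many placements counts once. The **monomeric-only
fraction** is the percentage of all TC motifs reachable by mDdCBE but not
by any dimeric pair.

The empirical **editing window** of monomeric editors — offsets at which
conversions concentrate, 4–11 downstream of the TALE site — is used to rank
candidate designs and can be re-derived from per-construct frequency
profiles with the `profile` stage.

## Worked example

The package bundles a human mitochondrial genome (NC_001807.4, 16,571 bp —
an older redistributable human mtDNA reference; pass your own FASTA, e.g.
the rCRS NC_012920, for revised-reference coordinates):

```
$ ddscan scan --genome src/ddscan/data/human_mtDNA_NC_001807.fasta \
      --circular --out report.json --motifs motifs.tsv
scan: NC_001807.4 (16571 bp, circular)
scan: 1817 motifs, 1665 dimeric-editable, 152 monomeric-only (8.4%)
```

Of the 1,817 TC motifs in human mtDNA, 1,665 (91.6%) sit in a valid
dimeric spacer, every motif has a TALE site within monomeric reach, and 152
(8.4%) can be edited by a monomeric editor but by no dimeric pair — sites
where only one terminal-T TALE array can be placed. `report.json` also
tabulates the fraction under the open conventions (window anchored at the
motif's C vs T; circular vs linear treatment of the origin junction):
8.365% circular, 8.751% linear, identical under either anchor.

Other stages, analogously:

```
ddscan design --genome ref.fa --position 5824 --one-based --strand + --out designs.tsv
ddscan offtarget --genome ref.fa --alignments sample.sam --targets targets.bed --out summary.json
ddscan profile --genome ref.fa --sites sites.tsv --freqs freqs.tsv --out window.json
ddscan simulate genome --spec genome_spec.json --out sim
ddscan simulate reads --genome sim.fasta --spec edit_spec.json --out sim.sam
```

`offtarget` reports the mean C•G→T•A conversion rate over all reference C/G
positions after excluding on-target windows and positions converted at
≥50% (pre-existing cell-line variants), plus the list of candidate
off-target positions at ≥0.1%.

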