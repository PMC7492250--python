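# ipcrseq

Reconstructing a transgene and its host-genome flanking sequence from
targeted nanopore sequencing of inverse-PCR amplicons.

## The problem

Regulatory laboratories detect genetically modified (GM) plant material with
qPCR assays against common screening elements such as the CaMV 35S promoter
(p35S). When a screen is positive but no event-specific assay identifies the
GM event, the insertion is unknown and its sequence must be recovered — with
the screening element as the only prior knowledge. A fast wet-lab route is:
shear genomic DNA into ~6 kb fragments, circularize them, degrade the
remaining linear DNA with exonuclease, and amplify every circle that carries
p35S with an outward-facing ("inverse") primer pair. The amplicons span the
transgene and its junction with the plant genome and are sequenced on a
long-read instrument at ~6% per-base error.

`ipcrseq` is a self-contained toolkit for the computational half of that
protocol:

* a ground-truthed **simulator** of the full molecular geometry — locus
  construction, shearing, circularization, exonuclease selection, inverse
  PCR (including the molecule-specific circularization junction every
  amplicon carries), and noisy long-read generation — so the whole pipeline
  is testable without sequencing data;
* the **analysis pipeline**: per-read quality filtering (Q >= 10 on the
  error-probability-mean scale), selection of reads > 1,000 bp containing
  one of the two p35S inverse primers (Smith–Waterman, >= 18/22 matched
  bases, either strand), ten iterations of greedy overlap-layout-consensus
  assembly on random 300-read subsamples, selection of the two longest
  distinct contigs (one per side of the screening element), orientation by
  the known seed sequence, a parallel de Bruijn assembly of 200 bp fragments
  from 500 sampled reads, unitig-based contig extension, joining of the two
  arms through the known seed, and a majority-vote pileup polish iterated to
  a fixed point;
* **reporting**: depth profile (bedGraph), depth statistics, percent
  identity against a reference over the aligned span, and the coordinate of
  the plant/transgene junction — the sequence an event-specific qPCR assay
  would target.

## Worked example

```bash
ipcrseq -v run-all --seed 1 --outdir run_out
```

simulates a run (3,000 bp plant flank + 6,168 bp construct carrying a 350 bp
p35S-like element + 3,000 bp downstream flank; 20,000 sheared molecules of
which 10% derive from the locus; ~2,000 reads, mean length 1,879 bp at ~6%
error), analyses it, and prints:

```
consensus length        11074
depth min       0
depth max       197
depth mean      66
identity vs reference   99.7% over 11085 bp
plant/transgene junction        2754
plant flank     2754 bp
insert (covered)        8320 bp
```

Reading the numbers: the polished consensus covers ~11 kb of the locus; its
identity to the (simulated) true locus sequence is 99.7% over the 11,085 bp
they share contiguously. Depth is highest next to the primer sites and
falls off with distance (only the longest reads reach far from p35S); the
minimum of 0 is the short inter-primer gap, which no amplicon covers and
which is filled from the known screening-element sequence. The
plant/transgene junction sits at consensus position 2,754 — the simulator's
truth places it at locus position 3,000, and the consensus starts 246 bp
into the flank, so the call is exact. Individual stages are available as `ipcrseq simulate`,
`qc`, `select`, `assemble`, `frag-assemble`, `merge`, `polish` and `report`;
the same functionality is importable from `ipcrseq` as a library.

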