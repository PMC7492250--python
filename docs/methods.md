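# Methods

## Protocol model

The simulator reproduces the molecular geometry of targeted inverse-PCR
sequencing of a transgene insertion:

1. **Locus.** A plant locus is the concatenation `flank5 + transgene +
   flank3` (defaults 3,000 + 6,168 + 3,000 bp, uniform-random composition).
   The transgene carries a 350 bp p35S-like screening element at offset
   2,750. The element embeds, on its plus strand, the reverse complement of
   the reverse primer (`AATCCCACTATCCTTCGCAAGA`), an 80 bp inter-primer gap,
   and the forward primer (`CAATCCACTTGCTTTGAAGACG`) — the configuration in
   which a conventional p35S qPCR assay would amplify the gap and the
   inverse pair points outward.
2. **Shear / circularize / exonuclease.** 20,000 molecules are drawn, 10%
   from the locus and 90% from a 60 kb non-target background (the genomic
   majority, which never amplifies and exists to demonstrate target
   specificity). Fragment lengths are Normal(6,000, 600) truncated to
   [500 bp, 3x mean]. Each fragment circularizes with probability 0.9;
   linear molecules survive the exonuclease with probability 0.01. A circle
   is stored linearized at its ligation point, so the molecule-specific
   shear junction sits between the last and first stored base. The pool
   size matters: distinct template circles must vastly outnumber sampled
   reads, as in a real library, so that reads sharing a circularization
   junction are rare (a small pool makes each chimeric junction look
   multi-read-supported, which no assembler should be asked to survive).
3. **Inverse PCR.** Primer sites are located by exact match on the circular
   sequence (both strands). The product runs from the start of the forward
   primer site, the long way around the circle, to the plus-strand end of
   the reverse site: the whole circle minus the open inter-primer gap, with
   primer sites at both product ends. Ground truth records the covered
   source intervals and the position of the shear junction inside the
   product.
4. **Reads.** Each read picks an amplicon uniformly (PCR copy number is
   taken as uniform across circles — the protocol cannot constrain it), a
   Normal(1,879, 1,200) length, and a window that may overhang either
   amplicon end, clipped to keep at least 100 bp inside. The overhang
   models library-prep shearing, which leaves end-anchored pieces; without
   it essentially no read would contain a primer and the selection stage of
   the protocol could not work. The dispersion (sd 1,200) reflects a run
   whose mean read length is far below its maximum (1.9 kb vs 9.5 kb);
   Normal(mean, 600) would cap reads near 3.7 kb and starve the flanks.
   Errors are applied per base (substitution 0.03, insertion 0.015,
   deletion 0.015; expected accuracy ~94%). Base qualities are drawn as
   `round(-10*log10(total error rate))` with Gaussian jitter (sd 1.5),
   clipped to [2, 41] — the run-level mean read quality then sits near
   12.2.

What the simulator does **not** model: PCR efficiency or length bias,
PCR-chimera artifacts other than circularization junctions, and
homopolymer-conditioned nanopore error modes. Errors are i.i.d. per base,
which is exactly the regime in which an unweighted majority pileup is a
consistent estimator; passing tests therefore show pipeline correctness
under an unbiased error model, not robustness to systematic basecaller
bias (a neural polisher's job).

## Pipeline

**QC.** Read quality is the error-probability mean converted back to Phred
(`Q = -10 log10(mean 10^(-q/10))`) — the basecaller convention that a
"quality threshold of 10" refers to; the threshold is inclusive. Summary
statistics (pass fraction at one decimal, mean quality/length over passing
reads, maximum length) form the run report.

**Primer selection.** A read is primer-bearing when the best Smith–Waterman
local alignment of any of the four primer variants (two primers, both
strands) contains >= 18 matched bases of 22, with the non-matching columns
(mismatches plus gap columns) fitting the same budget (<= 4). The alignment
view tolerates indels inside the primer at the ~6% error rate; the column
budget is what keeps random hits rare — without it, gappy chance alignments
in multi-kb reads reach 18 matches about 2% of the time, versus <= 1% with
it. Reads must also be strictly longer than 1,000 bp.
Scoring is (match +2, mismatch -3, gap open -5, gap extend -2); a gap of
length L costs `open + (L-1)*extend`. The aligner is exact (affine-gap DP
with packed traceback, numba-compiled) and is checked against an
independent brute-force DP in the test suite.

**Draft assembly.** Ten iterations each draw 300 reads without replacement.
Overlaps are found by shared 15-mers (index every 2nd position, query every
4th, >= 3 co-diagonal votes) and verified with a banded edit-distance
alignment over the implied overlap region (>= 300 bp at >= 80% identity).
The greedy layout merges best-score-first (score = overlap length x
identity; ties broken by read id). A join is vetoed when the implied layout
contradicts at least two already-placed reads, where contradiction is
either an existing overlap record whose offset/strand disagrees (tolerance
max(150 bp, 8% of the overlap length) — k-mer median offsets drift with
overlap length, and a fixed tolerance spuriously flags long reads) or a
*missing* overlap: a cross-group read pair stacked by more than 600 bp with
no verified record, the signature of a shear-junction chimera. The rule is
deliberately strict — permitting joins that a couple of records contradict
was observed to let the two amplicon arms fuse through chimera bridges,
a misassembly no later stage can undo. After
merging, a reassignment sweep demotes any read whose overlap records mostly
point at a different group — this dismantles the cascade in which a single
junction-spanning read bridges genuine reads of the other amplicon arm into
a group one at a time. Per group, a backbone is chained through
record-verified extensions (at joins, the higher-quality base wins
disagreements), then all group reads are realigned to the backbone and
majority-voted — the consensus stage that brings contigs from read-level
(~94%) to consensus-grade accuracy, without which the 95%-identity
duplicate rule below could never fire. Contigs are trimmed to >= 2-read
support at the ends.

Because selected reads are primer-anchored, the two real contigs are the
two "arms" flanking the screening element; their reach is set by the read
length distribution, and the raggedness near the element (junction-read
prefixes piling at circle-specific offsets) is inherent to the protocol —
it is the reason a second, fragment-based assembly exists.

**Contig selection and orientation.** All contigs from all iterations are
pooled; single-read contigs rank last. Two contigs are "the same" when one
aligns to the other at >= 95% identity over >= 90% of the shorter (either
strand); the longest and the longest-not-same are kept. Orientation
searches the known seed (the screening element) on both strands and keeps
the better one; each arm contains only one side of the seed (the middle is
the unamplified gap), so a hit is accepted at >= 80% identity over >= 50 bp
rather than a fraction of the seed.

**Fragment assembly.** 500 selected reads are sampled, cut into
non-overlapping 200 bp windows (trailing window kept when >= k), and
assembled through a de Bruijn graph over canonical 21-mers; maximal
non-branching paths are reported as unitigs (>= 2k bp), each once,
strand-normalized. The count filter is depth-matched: the function default
(2) suits sparse data, but at the pipeline's ~50-100x fragment depth pairs
of reads sharing an error position create duplicated error k-mers
(~0.1/position) that a count-2 filter keeps, shredding unitigs to ~60 bp;
the pipeline uses 4, at which true k-mers (>= 10 clean copies) survive and
coincident-error k-mers do not, yielding 0.5-1 kb unitigs at 100% identity.

**Merge.** Unitigs are locally aligned to each oriented arm (>= 90%
identity over >= 100 bp); per end, the unitig with the longest overhang is
spliced on (draft bases are never altered; only overhang is appended), for
up to 20 rounds. The two arms are then joined: if their seed-adjacent ends
overlap directly (>= 50 bp at >= 90%) the overlap is merged keeping the
upstream contig's bases; otherwise the join runs through the seed itself —
upstream arm up to its seed hit, the full known seed (this is what fills
the unsequenced inter-primer gap; nothing is fabricated beyond the supplied
known sequence), then the downstream arm after its seed hit. The result is
normalized so the seed lies on the plus strand.

**Polish and report.** All selected reads are mapped to the merged sequence
(15-mer seeding to pick strand and window, edlib infix alignment; accepted
at >= 80% identity — junction-straddling reads align near 75% and would
otherwise corrupt low-depth columns — over >= 200 bp). Per reference
column, the majority base wins (deletion votes can remove a column; an
insertion is applied when more than half of the spanning reads insert the
same sequence at a boundary; ties keep the reference base). Mapping and
voting iterate to a fixed point (<= 5 rounds), then the consensus is
trimmed to its outermost positions with >= 5 supporting reads: a majority
call is meaningless on single-molecule fringes, which is also where
chimeric tails accumulate. Percent identity versus a reference is the best
local alignment's matches over aligned columns, with the aligned span
reported; pairs too large for the exact DP (> ~8e7 cells) use an
edlib-infix alignment trimmed to its maximal-scoring segment under the same
scoring — a faithful surrogate when one sequence is near-contained in the
other, which is the only large case the pipeline meets. The
plant/transgene junction is the last consensus position assigned to the
best local alignment of the plant reference (0-based; the transgene starts
at the junction), reported only when both references align at >= 90% over
>= 200 bp.

## Default problem sizes

The default configuration — ~2,000 reads over ~1,700 distinct amplifiable
circles, one locus — is the package's reference scale: one full run
(simulation + analysis) takes about a minute on one CPU, and the acceptance
checks repeat it across ten seeds. At this scale the consensus typically
spans 7-11.5 kb of the locus at >= 99.7% identity, and the junction call is
exact to the base; coverage (and with it, reach into the plant flank)
grows with read count, so larger runs only help.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open on the plus strand; strand is carried
separately. A single master seed spawns child seeds (simulator, draft
subsampler, fragment subsampler) via `numpy.random.SeedSequence`, making
every stage reproducible and independently re-runnable. Ties are broken
deterministically everywhere (score then identifier). Degenerate inputs
follow one rule: impossible requests raise (empty alignment input, absent
seed, empty contig pool), while empty-but-valid results warn and continue
(no amplicons, no primer-bearing reads, undersized sampling pools).

## Known limitations

* The unweighted majority polisher assumes unbiased errors; with a real
  basecaller's systematic homopolymer errors it would converge to the
  biased mode, as any counting polisher does.
* Contig reach is bounded by the longest reads: the plant-side flank is
  recovered only as far as reads anchored at the reverse-primer site
  extend. The 3' end of the covered region likewise fades with depth.
* Terminal sequence derived from junction-spanning reads can survive in a
  draft contig when it happens to be locally consistent; the support trim
  and the final local-alignment reporting contain, but do not provably
  eliminate, such tails.
* The duplicate rule compares consensus-grade contigs; it is not meaningful
  for raw-read "contigs", which is why those rank last in selection.
* When a contig's chimeric fringe is just large enough to push containment
  coverage below the 90% duplicate threshold, two versions of the same arm
  can be selected; the seed-based join and the final report still complete
  (and the junction is still recovered), but the opposite arm's reach is
  lost for that run.
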