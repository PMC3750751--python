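# Methods

## Model and procedure

`regscout` operationalizes a three-stage in silico nomination of remote
regulatory regions for a gene G:

1. **Anchor and partner ranking.** The genome is partitioned into
   fixed-size bins (default 1 Mb); the anchor is the bin containing the
   midpoint of G (the midpoint rule makes the choice unambiguous for
   genes straddling a bin boundary). Each pre-normalized contact map —
   one per restriction-enzyme experiment — is queried for all bins
   touching the anchor, ranked by interaction count descending;
   self-interaction of the anchor is excluded and missing pairs count 0.
   Ties break by (chromosome name, bin index) so rankings are
   deterministic. `scope` restricts partners to cis (`intra`, the
   default), trans (`inter`) or both.
2. **Consensus across enzyme maps.** The published analyses report each
   enzyme map separately and state no combination rule, so the combiner
   is this package's explicit choice: over the union of each map's
   top-*k* partners, bins are ordered by (number of maps supporting the
   bin, best rank across maps, chromosome, index). A partner seen in
   every map's top-*k* therefore precedes one seen in a single map, while
   each map's own ranking (and counts) remain reportable unchanged.
3. **Peak selection and screening.** Within each selected bin (top
   partners plus, by default, the anchor bin itself), the
   highest-enrichment region of the enhancer-mark track is called (rule
   below); bins with no positive signal are dropped. Candidates are
   ranked by peak height, classified distal/proximal/trans, and exported
   as BED sequencing targets. Cohort variants are assigned to candidates
   by inclusive interval membership, annotated for novelty against the
   catalog by exact (chrom, pos, ref, alt) match — position-only matching
   would mislabel a different allele at a catalogued site — and
   intersected with TF-binding-site intervals.

## Coordinate conventions

All in-memory positions are 1-based and inclusive at both ends, matching
printed genomic coordinates; BED/bedGraph files are 0-based half-open on
disk and converted exactly once at I/O. Bin index arithmetic is
`floor(pos / bin_size)`, so the 1-Mb bin of index 29 covers
29,000,000–29,999,999 — literal agreement with the worked example's
printed bin boundaries. "Upstream" is strand-aware; distances are
reported in bp and rounded to the nearest kb only for display.

## Peak-calling rule and its knobs

"The relatively short region of highest enrichment" is not a defined
quantity in ChIP-seq terms, so the package fixes one deterministic rule:
with in-window maximum M, keep positions with signal ≥ `frac`·M, merge
runs separated by ≤ `max_gap` bp, drop merged runs shorter than
`min_width` bp, and return the run containing the (leftmost) maximum.
Defaults `frac=0.5`, `max_gap=200` bp, `min_width=100` bp produce single,
plateau-sized regions on typical enhancer-scale signal; all three are
exposed in the CLI and config. The signal is treated as piecewise
constant per bedGraph semantics — no smoothing or interpolation. Raising
`frac` can only narrow the returned region (tested as a property), and
the region always contains an argmax of the signal in the window. A
`return_all` option yields every surviving run for multi-peak scans.

## Synthetic-data generator

The generator emulates the statistical shape of the three inputs, not any
particular genome:

* **Contact maps** — expected intra-chromosomal count at bin distance d
  is `base_count · d^(−decay_exponent)` with `decay_exponent` defaulting
  to 1.0 (the well-known approximate scaling of contact frequency with
  genomic distance); inter-chromosomal pairs get a flat expectation
  (`inter_count`). Planted pairs multiply the expectation. Realized
  counts are Poisson draws — counts are event tallies, and Poisson is the
  simplest defensible noise model — so simulated maps are integer even
  though the data model admits fractional (normalized) counts.
* **Signal tracks** — fixed-width background tiles (default 100 bp) with
  i.i.d. exponential heights (mean `signal_background`) plus planted
  rectangular plateaus that replace the background under them.
* **Cohorts** — exactly the planted (site → carrier set) structure,
  optionally plus uniform background variants inside a stated span.

Every generator is a pure function of the `SimulationConfig`, seed
included; per-component substreams are derived from the seed via
`numpy.random.SeedSequence` spawn keys plus a CRC32 of the enzyme label,
so two enzyme maps from one config are independent but reproducible.

What the simulations do **not** model: restriction-fragment structure,
mappability and GC bias (maps are consumed post-normalization anyway),
domain/compartment structure in the decay, read-level ChIP-seq noise,
linkage disequilibrium or realistic allele-frequency spectra. Passing
recovery tests therefore demonstrates that the selection logic finds what
its own model plants, not that the model captures every property of real
Hi-C or ChIP-seq data.

## Fixture conventions

The fixture encodes the worked example's published quantities: the two
enzyme maps around the NF1-containing bin (703/255, 222/699, 59/150, and
the 21-count trans pair on chr1 bin 0), the NF1 annotation, regions A/B
as signal plateaus, the three TF sites, the two catalogued SNPs
(maf 0.007 / mac 16) and a 47-patient cohort. Where the source gives only
partial information the fixture fixes a documented convention: plateau
heights 10 vs 4 (only the ordering A > B is published), alleles G>A and
C>A for the two catalogued SNPs (only rs ids and positions are
published), heterozygous zygosity for all three variants, and carrier
sets P01–P02 / P01,P03,P04 / P02,P03,P05 — the per-site carrier counts
(2/3/3) and the total of 5 distinct carriers are the published structure;
the exact patient overlap is the fixture's choice. Low background blocks
(values 1.0/1.2) sit far from the plateaus so called regions equal the
plateaus exactly.

## Recovery-study conditions

The planted-truth studies run at reduced scale so they complete in
seconds on one core: two chromosomes of 20 bins at 10 kb, `base_count`
50, `inter_count` 1, a planted partner at bin distance 5 with multiplier
20, and a 1-kb plateau of height 10 over exponential background of mean 1
(≥ 5× background). Under these conditions the end-to-end pipeline's top
candidate overlaps the planted enhancer in ≥ 90% of 100 seeded replicates
(observed ~98%), and the called region's midpoint lands within 200 bp of
the plateau midpoint in ≥ 95% of replicates. A parameter grid over decay
exponents {0.8, 1.0, 1.5} at multiplier 20 is exercised in the test
suite.

## Degenerate inputs and tie-breaks

Empty map → empty ranking and empty candidate list; `top_k=0` with the
anchor bin included degenerates to a single-bin enhancer scan of the
gene's own bin; an all-zero signal window returns no region (never a
zero-height region); ties on the maximal signal value anchor the region
at the leftmost maximum; equal peak heights among candidates sort by
label. Asymmetric contact rows, overlapping bedGraph intervals, negative
counts/values and duplicate (patient, site) records are rejected with the
offending line number where applicable.

## Known limitations

The pipeline consumes 1-Mb-binned maps and has no sub-bin interaction
resolution: a candidate's support is its whole bin's contact count.
Statistical significance of contact counts (vs. distance-decay
expectation) is not assessed — partners are ranked by raw normalized
count, as in the source analysis. Novelty annotation is only as complete
as the supplied catalog, and the screen does not attempt pathogenicity
assessment. Primer design for the exported targets is external by design.
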