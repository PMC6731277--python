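# Methods

## Coordinate and strand conventions

All genomic coordinates are 0-based, half-open (BED convention); 1-based
conversion happens only at I/O boundaries for formats that require it.
Spacers are reported 5'→3' on the protospacer strand with the 3-nt PAM
immediately 3'. Mismatch positions count 1..20 from the spacer 5' end, so
position 20 is PAM-proximal — the native convention of CFD weight tables.
The blunt SpCas9 cut is placed between spacer positions 17 and 18 (3 nt 5'
of the PAM) and recorded as the 0-based coordinate of the base immediately
3' of the cut on the + strand: `start + 17` for + strand guides,
`start + 3` for − strand guides. Spacers or candidate windows containing
`N` are excluded everywhere rather than treated as wildcards: base pairing
and CFD weights are undefined for unknown bases.

## Off-target search

`find_offtarget_sites` is contractually exhaustive: it returns exactly the
set of both-strand windows whose adjacent PAM matches the configured PAM set
and whose protospacer is within the Hamming budget (default 3) of the
spacer. The implementation is a vectorized all-window scan (numpy sliding
windows over a byte-encoded genome); the test suite verifies set-equality
against an independent pure-Python early-exit scan on 200 kb genomes with
planted sites, for both the {NGG, NAG} and {NGG}-only PAM configurations.
The PAM set defaults to {NGG, NAG} — NAG being the canonical tolerated
SpCas9 alternate — and is configurable because upstream tools do not
document their choice.

Two distinct count-based eligibility rules operate on the mismatch-class
tally (which includes the on-target perfect match in class 0):

- **Searchability**: exactly one perfect match and zero 1-mismatch sites.
  Unsearchable guides are excluded from scoring entirely (`score = None`,
  never 0): they are removed from analyses, not ranked within them.
- **Legacy count filter**: fail if any class count strictly exceeds
  {0: 2, 1: 10, 2: 50, 3: 200}; boundary values pass (the rules are worded
  as strict "greater than").

## Specificity score

Per-site CFD = product of mismatch weights (position, guide base, target
base) × PAM weight; a perfect NGG site scores 1. The aggregate specificity
score is `S = 1 / (1 + Σ CFD)` over sites with 2–3 mismatches (the single
0-mismatch site is the on-target; 1-mismatch sites already made the guide
unsearchable). The class set is configurable for sensitivity analyses.
Invariants covered by tests: S ∈ (0, 1], S = 1 iff the CFD sum is 0, strict
monotone decrease under site addition, permutation invariance, and the
closed form S = 1/(1 + n) under a degenerate all-1 weight table.

The packaged weight table (`data/cfd_*_synthetic.tsv`) is **synthetic**: a
deterministic construction with PAM-proximal mismatches penalized most
(linear decay toward the PAM), per-mismatch-type factors that tolerate
wobble-like pairs (rG:dT, rU:dG analogues) more than purine-purine clashes,
and PAM suffix weights GG = 1 > AG > GA > others. It exists so the package
builds, tests, and demos offline; the loader accepts any measured table in
the same TSV schema (position, guide_base, target_base, weight; separate
PAM table keyed by 3-mer or 2-nt suffix, with NGG ≡ 1 enforced).

## Library filters

Sequence rules, each an independent predicate (so filtering is idempotent
and order-free): GC in [0.20, 0.80] with boundary values passing and strict
inequalities failing (the sources state only "<20%" / ">80%"; the boundary
choice is ours and configurable); no TTTT substring (Pol III terminator);
no GGGGG suffix of the 20-mer (the transcribed guide 3' end, where G runs
disrupt expression/PCR); no restriction sites CTGCAG, GAAGAC, GTCTTC,
CCANNNNNNTGG, GCTNAGC. Restriction patterns are IUPAC-expanded and matched
against both the spacer and its reverse complement, since restriction
recognition is double-stranded; listing both BbsI orientations explicitly is
therefore redundant but harmless.

The exclusion filter re-runs the off-target search at ≤ 1 mismatch and fails
a guide whose near-exact sites overlap (≥ 1 shared base, half-open) any
exclusion region (exons, DNase-hypersensitive sites, other target sites).

Per-motif selection keeps guides whose cut position falls inside the motif,
at most 5 per site, ranked by specificity score, ties broken by distance of
the cut from the motif center and then guide id; motifs with fewer than two
survivors are flagged under-covered. Element targetability counts eligible
guides with score strictly above the cutoff (default 0.2): Cas9 mode
requires the cut inside the element (narrow motifs must be hit directly),
CRISPRi/a modes require the protospacer to lie fully within the element's
± window (default ±100 bp for TSS-style designs). Only the baseline
motif-selection pipeline is implemented; alternative site-selection variants
are out of scope.

## Screen analysis

Guide enrichment is `log2((cpm_endpoint + p) / (cpm_plasmid + p))` per
endpoint replicate, with counts-per-million normalization applied before the
pseudocount (default p = 1; both exposed). This is a deliberately explicit
reimplementation of the guide-level log2 fold-change statistic; upstream
maximum-likelihood screen-analysis frameworks and their FDR hit calling are
out of scope. Replicates are aggregated by arithmetic mean with standard
error sd/√k.

The quadrant association crosses depletion (mean log2FC ≤ −2) with low
specificity (score ≤ 0.2); both thresholds are parameters since appropriate
values are screen-dependent. The Fisher exact p-value is computed by exact
integer enumeration: hypergeometric probabilities are compared as integer
numerators over the common denominator C(n, column margin), so the two-sided
minimum-likelihood rule has exact tie handling with no floating-point
tolerance. scipy's implementation serves as an independent cross-check in
the tests (>10⁴ tables, relative agreement 1e−9). The odds ratio is reported
exactly with ±∞ permitted on zero cells; a Haldane–Anscombe +0.5 option
gives finite ORs. Element calls require ≥ 2 concordantly depleted guides;
single-guide evidence is reported separately because it is the signature of
off-target-driven false positives. The specificity filter removes guides
with score ≤ cutoff (inclusive) and all unsearchable/unscored guides.

## Coverage rescaling

FRiP (fraction of reads overlapping merged peaks, ≥ 1 shared base) scales
coverage tracks multiplicatively: `C* = C · max_D(FRIP) / FRIP_D`, so the
strongest track is unchanged and weaker tracks are scaled up. The transform
is exactly invertible and commutes with restriction to sub-intervals. RPM
conversion is a loader responsibility (total mapped reads supplied as
metadata); alignment and peak calling are consumed as inputs only.

## Synthetic data generator

`random_genome` draws i.i.d. bases at a target GC. `implant_sites` plants
protospacer copies at requested mismatch counts/positions and PAMs at
random non-overlapping locations, after destroying chance background
matches found by a pre-scan (a ~200 kb random genome contains O(1) chance
3-mismatch matches per spacer, so this step is required for exact truth);
the final genome is re-scanned and planting fails loudly if the found set
differs from the planted truth.

`simulate_screen` models a pooled growth screen: plasmid abundances are
Dirichlet-uniform; endpoint abundance is proportional to
`a_i · 2^(g·(e_on + e_tox·confounded))`; counts are negative-binomial
(gamma-Poisson, variance μ + φμ²) around depth-scaled abundances. NB noise
with a shared dispersion is the standard count model for pooled screens;
toxicity enters as an additive per-doubling fitness term on flagged guides,
mirroring how confounded guides phenocopy essential-gene guides. All
randomness flows through one seeded generator; count matrices are
bit-identical per seed.

Default study conditions (used by tests and the acceptance script): 200
elements × 5 guides = 1000 guides, 20% of elements truly essential at
e_on = −0.5 per doubling, 30% of guides flagged low-specificity (synthetic
scores ≤ 0.2 versus > 0.2), toxicity e_tox = −1.5 per doubling when enabled,
g = 7 doublings, 500× depth, φ = 0.05, 2 replicates. The null condition
keeps the on-target effects and sets e_tox = 0, so depleted guides exist but
are independent of the specificity flag and the quadrant odds ratio is
well-defined and centered at 1. What the generator does **not** emulate:
guide-to-guide efficacy variation, position effects within elements,
copy-number amplifications, replicate batch effects, and any sequence
dependence of off-target toxicity — so passing simulation tests demonstrates
correctness of the statistical machinery under the stated model, not
performance on real screen data.

## Problem sizes and numerics

Oracle equivalence is checked at 50 spacers × 200 kb (and 1 Mb-scale scans
remain exact by construction); Fisher enumeration is validated on 11⁴-grid
tables with N ≤ 40; simulation calibration uses 200 null and 100 toxicity
seeds. The exact-integer Fisher test is O(support size) per table with
big-integer binomials and is practical to n of several thousand guides.
Degenerate inputs: zero-margin tables return p = 1 with a warning; all-zero
count samples, empty genomes, unsearchable guides passed to the aggregator,
and zero FRiP values raise errors rather than propagating silently.

## Known limitations

- The synthetic CFD table preserves the structure, not the values, of
  measured mismatch tolerances; absolute scores from it are not comparable
  to published score distributions.
- The off-target search is exhaustive-scan based and sized for desk-scale
  genomes (≤ tens of Mb); whole-genome designs would want a k-mer or trie
  index behind the same contract.
- Bulge/indel off-targets and on-target activity scores are not modeled.
- Enrichment reimplements the guide-level log2FC only; published screen
  effect sizes computed by maximum-likelihood frameworks will differ in
  normalization details.
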