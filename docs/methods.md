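# Methods

This note documents the models and procedures implemented in `lignoamp`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Primer matching and in-silico PCR

A degenerate primer is a string over the IUPAC nucleotide codes plus
inosine (`I`). Matching is **ungapped** (Hamming-style) within the primer
footprint: primers are short (17–20 nt here), the downstream read filter
counts *mismatches*, and indel-containing bindings are treated as
non-matches. A window position matches when the template base is in the
primer code's base set. Two asymmetric conventions:

* primer `I` and `N` match any template base (inosine is a physical
  universal-pairing analog; it differs from `N` only in name);
* a template `N` is an *unknown* base, not a wildcard — it matches only a
  primer `I`/`N` position.

In-silico PCR enumerates all (forward-site, reverse-site) combinations on
both strands whose product length lies within bounds (default: expected
product length ± 30 %). Products include both primer footprints, matching
the convention that published product lengths count the primers.
Coordinates are 0-based half-open throughout. Default mismatch tolerance
is 2 per primer, mirroring the read filter; the tolerance used when
auditing genomic copies is not independently documented anywhere, so the
same default is exposed as configuration.

The **amplifiability audit** searches the spliced coding sequence (the
template in an RNA-derived assay). Verdict logic, in priority order:

1. both sites found within tolerance and product in bounds, but a footprint
   crosses an exon junction → `intron_disrupted` (the genomic copy's primer
   region is interrupted by an intron);
2. both footprints contained in single exons → `amplifiable`;
3. sites only found above the tolerance → `divergent_site`;
4. otherwise → `no_product`.

A window counts as a "recognisable but divergent" site up to ⌈L/4⌉
mismatches (L = primer length); beyond that the site is treated as absent.
This ceiling separates `divergent_site` from `no_product`: without it any
window would qualify as an arbitrarily-divergent site and `no_product`
would be unreachable.

## Read merging and QC

The merger is a bespoke best-ungapped-overlap algorithm (not a reimplementation
of any specific published tool, whose parameters the original analyses did
not pin down): the reverse mate is reverse-complemented and slid along the
forward mate; the overlap with the most matches wins (ties: longest
overlap, then smallest offset); acceptance requires overlap ≥ 20 nt and a
mismatch fraction ≤ 0.25; disagreements resolve toward the higher-quality
base (ties toward the forward mate). Functional equivalence is established
on synthetic data: at zero error rate, 100 % of pairs merge into exactly
their source amplicons.

Filters are pure predicates, so accept/reject status is order-independent:
any `N` rejects; a homopolymer run strictly longer than 7 nt rejects; more
than 2 mismatches against either primer footprint rejects. Primer matching
for trimming is anchored at the termini (amplicons begin and end at primer
sites by construction); both read orientations are tried and the sense
strand normalised to the forward primer. GH7 products (515 bp) cannot be
merged from 2×250 chemistry; the forward read alone is truncated to
exactly 210 nt after the forward primer footprint.

Libraries pool several families per run and reads arrive demultiplexed by
sample but not by family; reads are assigned to families by the
best-scoring forward-primer footprint at the 5′ terminus of the forward
read (ties or no footprint within tolerance → unassigned). This assignment
rule is an interpretation — pooled designs do not document one.

## Chimera (bimera) screen

PCR chimeras are mosaics of two more-abundant parents. After per-sample
dereplication (exact grouping, descending abundance, lexicographic
tie-break), each unique is tested against candidate parents with abundance
≥ 2× its own: it is flagged when some breakpoint splits it into a left
segment ≥ 99 % identical to one parent and a right segment ≥ 99 % identical
to another, and the two-parent model explains at least 2 more positions
than the best single parent. The breakpoint scan is exhaustive and
vectorised; verdicts are deterministic and invariant to input order.

This is a deliberately compact functional substitute for k-mer-chunked
chimera detectors — the screen is a filter here, not the object of study —
and it compares queries only against equal-length candidates: the pipeline
is substitution-centric and per-family amplicon lengths are fixed.
Screening is per-sample because abundance skew is a within-sample signal.

## Identity, clustering and the delta-plateau cutoff

Pairwise identity comes from a global alignment (match +1, mismatch −1,
gap open −2, extend −1) with free terminal gaps: identity = matches /
aligned columns, where columns span the aligned region only (internal gaps
count, terminal gaps do not — deliberately, because amplicons may be
truncated, e.g. the 210-nt GH7 fragments, and a contained fragment should
score 1.0 against its source). One numerical guard: the denominator is
floored at the shorter sequence's length, because for two *unrelated*
sequences the score-optimal end-gap-free alignment can span a handful of
columns and would otherwise report a spuriously high identity.

Clustering is greedy over abundance-sorted uniques: each sequence joins
the first cluster whose representative it matches at or above the cutoff,
else seeds a new cluster. Greedy order was chosen (over unspecified
hierarchical linkage) for determinism and because representatives are
*defined* as the most abundant member, which greedy seeding matches.
Samples are pooled for clustering and per-sample counts tabulated
afterwards — required by both the shared-cluster statistic and the
singleton rule.

Because coding families evolve at different rates, the cutoff is selected
per family from the data: cluster counts N(d) are computed on a 0–15 %
dissimilarity grid in 1-point steps, and the selected d* is the smallest
d ≥ 1 with |N(d) − N(d−1)| < 6 % × N(0) — the beginning of the plateau of
the cluster-count curve. If no step qualifies the largest grid value is
returned with an explicit flag. N(0) always equals the unique-sequence
count.

Singleton policy: clusters holding a single read overall (necessarily
detected in only one sample) are presumed sequencing artifacts and
removed; a cluster with one read in each of two samples is retained —
independent detection in two samples is evidence of reality.

## AA2 subfamily classification

Class II peroxidase subfamilies are distinguished by two diagnostic
residues: the Mn-binding aspartate (homolog of Asp-175 in
*P. chrysosporium* MnP1, GenBank AAA33744) and the catalytic tryptophan
(homolog of Trp-171 in LiPH8, GenBank AAA53109). The query peptide is
globally aligned to each anchor protein (BLOSUM62, gap open −10, extend
−1, terminal gaps free) and the residue in the anchor column read off:
D∧¬W → MnP, W∧¬D → LiP, D∧W → VP, ¬D∧¬W → GP. Coverage of both anchor
columns is mandatory — an anchor column falling in a terminal gap makes
the call `unclassifiable`; the ~400 bp AA2 amplicons span both anchor
regions by design, so covered queries always receive exactly one of the
four labels.

The bundled anchor files are deterministic **synthetic stand-ins** for the
two GenBank records (marked `synthetic_` in filename and header): the
diagnostic residues are pinned at the published positions on a shared
random backbone, and the synthetic AA2 amplicons derive from the same
backbone, so anchor-column alignment is exact by construction. Reading
frames are inferred by the fewest-internal-stops rule (ties: longest
stop-free stretch, then lowest frame); an internal stop is one followed by
at least one further codon — a stop as the final complete codon is
terminal and passes the screen.

GH5-5 subfamily confirmation (done with family-internal HMMs by a third
party in the original workflow) is replaced by a nearest-reference
similarity check — positive-BLOSUM62 positions over aligned columns, with
the conventional 70 % gate — against a bundled panel; the panel shipped
here is synthetic for the same offline reason.

## Diversity

Rarefaction is a multivariate hypergeometric draw (sampling individuals
without replacement) to the minimum total across the samples being
compared; Shannon uses the natural logarithm and Chao1 defaults to the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) (the classic form
S_obs + F1²/(2F2) is available and falls back to the bias-corrected form
when F2 = 0, where it is undefined). Reports give means ± sd over 100
rarefactions under a mandatory seed, computed both with and without
singletons so the effect of the singleton policy is visible.

## The synthetic-data generator

`simulate_family` builds an ancestor around exact (concretised) primer
sites at the published product spacing and evolves variants by random
substitutions that avoid primer footprints, never create stop codons in
the design frame, and (for AA2) leave the two anchor codons frozen at
their planted subfamily values. Each variant carries exactly one forward
and one reverse binding site within tolerance. The per-variant mutation
count k is chosen so that two variants differ at ≈ 2k − 1.25k²/L
positions, and the realised minimum pairwise divergence must land within
20 % of the target or the family is re-drawn (explicit failure after a
bounded number of attempts).

`simulate_community` draws ranked abundances (geometric with ratio r = 0.8
by default — few dominant variants and a long rare tail, the typical shape
of soil fungal-taxon abundances — or a log-series alternative); each
sample receives its own random rank order over its support, and
`shared_fraction` controls the support overlap between samples (0 =
disjoint, 1 = common), emulating the low between-stand overlap of real
paired designs. A support floor of one read per variant is applied by
default before the multinomial remainder so planted richness is realised.

`simulate_reads` emulates a 2×250 run: per-base substitution errors
(default 0.2 %), rare `N`s (0.1 %), optional homopolymer artifacts, and
chimeric pairs (default 1 %) spliced from two abundance-weighted parents.
Chimeric junctions are drawn uniformly over the **central 70 %** of the
product: a junction in the terminal ~15 % is in principle indistinguishable
from a parent sequence, so generating such reads would make any stated
detection-sensitivity figure ill-posed rather than informative. Every read
is traceable through a truth table, and all outputs are byte-identical
under a fixed seed.

What the generator does **not** emulate: quality- and position-dependent
instrument error profiles, PCR amplification bias, indel errors
(substitution-only by default, because both primer matching and clustering
identity are Hamming-centric), and real phylogenetic structure among
variants (star-like divergence from one ancestor). Passing tests therefore
demonstrate the pipeline's correctness under its stated model, not its
robustness to, e.g., homopolymer-indel-heavy chemistry.

## Problem sizes and verification choices

The packaged verification runs use 20 variants per family at ~10 %
divergence, two samples of 1 000 reads per family, 1 000 random curves for
the cutoff-rule oracle, and 100 rarefactions for estimator summaries —
sizes at which every property is sharp (exact recovery, exact verdicts)
while the whole suite runs in well under a minute.

The Chao1 richness-recovery check (40 variants observed at depth 500) uses
a geometric ratio of r = 0.93 rather than the community default of 0.8:
recovery is only a meaningful test when the rarest taxon has non-negligible
detection probability (expected count ≈ 2 at depth 500 under r = 0.93),
whereas under r = 0.8 the rarest taxa are essentially undetectable at that
depth and *no* abundance-based estimator could recover the true richness —
Chao1 estimates the unseen mass only from singleton/doubleton counts.

## Known limitations

* Greedy clustering is order-dependent by design; the cluster-count curve
  is monotone non-increasing in practice but this is not a theorem under
  greedy assignment.
* The bimera screen does not detect multi-parent (> 2) chimeras or
  chimeras between different-length templates, and its per-read
  concordance with k-mer-based detectors is not claimed.
* Anchor-residue classification depends on alignable homology with the
  anchor proteins; with the synthetic stand-in anchors this is guaranteed
  for simulated data but real AA2 amplicons should be classified against
  the real GenBank records (drop-in FASTA replacement).
* Phylogenetic placement is out of scope: the pipeline exports peptide
  FASTA for external alignment/tree tools.
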