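# Methods

## Synthetic genome and annotation

A MIC genome is one or more chromosomes tiled exactly by alternating MDS
and IES intervals; every IES is strictly internal (MDS on both sides, never
abutting another IES or a chromosome end, minimum MDS gap 500 bp so that
metagene flanks exist). Defaults: 5 Mb total, one chromosome, 300 IESs,
IES fraction 1/3, matching the field's rule of thumb that IESs occupy about
a third of the germline genome.

IES lengths are drawn log-uniformly over (1,000, 20,000) bp and then scaled
by a single common factor (with per-locus integer rounding and a residual
nudge) so that total IES bp equals `round(ies_fraction × G)` exactly. The
wide range reflects the real situation in which the 1–5 kb loci used for
metagene compilation are a large subset — not the entirety — of the IES
complement; 300 loci of at most 5 kb could not sum to a third of 5 Mb, so
the fraction target and the 1–5 kb class cannot both be literal. With the
defaults, roughly half the loci land in the 1–5 kb class. Setting
`ies_fraction: null` disables rescaling and uses the drawn lengths as-is
(useful for exact geometric fixtures). Infeasible requests (IES mass
leaving less than the minimum MDS gaps) raise a parameter error before any
sequence is generated.

Sequences are i.i.d. uniform A/C/G/T; no attempt is made to mimic ciliate
base composition, repeats or mappability. All randomness flows through one
user seed, expanded into independent per-stage substreams keyed by stage
name (CRC-32 of e.g. `wgs:WT`), so regenerating one sample never perturbs
another.

## Read simulation

Reads are *placed records* — (chrom, start, end, source, channel) — not
sequences; the downstream statistics operate on mapped counts and
alignment is deliberately out of scope (optional FASTQ export exists for
interoperability). Read count per sample is `depth × G / read_length`
(default 20 × 5 Mb / 50 nt = 2,000,000).

* **MIC reference, ChIP input, contaminant reads:** start positions uniform
  over intact MIC coordinates; reads may straddle MDS/IES boundaries.
* **Somatic new-MAC reads:** the number of contaminant reads is
  Binomial(N, c); the rest are drawn from the spliced somatic template in
  which MDS contributes per-bp weight 1 and IES *i* weight equal to its
  retained fraction r_i ∈ [0, 1]. A somatic read is confined to its source
  segment, because a read crossing an excision junction would not map
  contiguously back to MIC coordinates; this makes "complete elimination +
  c = 0 ⇒ zero IES-overlapping reads" exact at the cost of a slight
  coverage deficit within `read_length` of segment edges.
* **ChIP IP reads:** the read *midpoint* is sampled from a per-bp weight
  that equals the enrichment factor E on IES bodies and the background
  weight elsewhere, so the midpoint-rule count fraction in IES space is
  exactly Ef / (Ef + b(1−f)).

Contamination c is a *per-read* fraction. The biological literature
quantifies MIC carry-over only as an approximate percentage; per-read is
the convention under which the count-ratio statistic recovers c directly
(median RI of a fully eliminating sample → c), and it is what the
simulator's Binomial draw implements.

## Counting and the retention index

Reads are assigned by the **midpoint rule**: a read counts toward the
unique interval containing its midpoint (searchsorted on the sorted
interval starts). This partitions counts exactly — no double counting at
boundaries — and is stable under small boundary shifts. Reads outside the
annotated chromosomes are skipped and logged.

RI_i = (n_i/N)_newMAC / (n_i/N)_MIC with N = total assigned reads of the
sample ("counts per million" normalization). An alternative normalization
by MDS-assigned reads only is available (`norm="mds"`); per-bp coverage
mode (`per_bp=True`) divides both counts by IES length, which cancels in
the ratio and exists for interoperability. IESs with zero reference count
are dropped with a logged count, never reported as infinite. Summaries
report median, quartiles and threshold fractions at configurable cut
points (defaults 0.001, 0.1 and 1, the edges of the reported wild-type
band and the retention point).

Expected behaviour under the mixture model: for retained fraction r and
contamination c, E[RI] ≈ c + (1−c)·r/(1 − f(1−r̄)) where f is the IES
fraction and r̄ the mean retained fraction (the denominator reflects that
the somatic template shrinks as IESs are eliminated). At r = 0 this is c;
at r = 1 it is 1; it is monotone in r at fixed c. The acceptance suite
verifies the c-recovery within 20% relative error at 20× depth across
c ∈ {0.02, 0.05, 0.10}, and the ±0.1 band around 1 for the null.

## ChIP fold enrichment and the modeled IES

Fold enrichment per fixed-width window (default 50 bp) is
(IP CPM + p)/(input CPM + p) with pseudocount p = 0.5 CPM; windows with
zero input reads are flagged low-confidence. The windowed ratio of noisy
counts carries a Jensen bias of order 1/(reads per window); therefore the
package also provides an aggregate estimator (`enrichment_ratio`) — the
input-normalized per-bp IP density over IES bodies divided by that over
MDS, computed from raw interval counts with no pseudocount — which is the
quantity that recovers the simulated E unbiasedly and is what the
acceptance check uses. Window width, pseudocount and bin counts are
package defaults chosen for smoothness at 20× depth; none is dictated by
the underlying experimental convention, and all are configurable.

The **modeled IES** metagene compiles every IES whose length lies in the
inclusive class [1,000, 5,000] bp: the body is rescaled to 50 bins by
linear interpolation of window values at bin-center positions; flanks of
2,000 bp on each side are sampled at native scale in 50 bins; bins are
averaged arithmetically across loci and the locus count n is reported.
Loci whose flanks would overrun a chromosome end are dropped and logged.
A constant track yields a constant profile for any mixture of in-class
lengths (no binning artifact), and n is invariant to window width.

## Phospho-sites, mutants and net charge

Site inventories are sets of (position, residue ∈ {S,T,Y}, provenance).
Merging is set union by position with provenance union; the same position
reported with different residue letters is a hard error. The shipped
fixture reproduces the published bookkeeping — 31 sites from one MS study,
10 from another of which 2 are novel, 33 merged — on a **synthetic**
Pdd1p-like sequence (480 aa, regions NT 1–80, CD1 81–140, HNG1 141–240,
CD2 241–300, HNG2 301–400, CSD 401–480). The real site coordinates are
published only graphically, so the fixture positions are placeholders;
real sequences and site tables load from FASTA/TSV through the same API.

Mutant specs are ordered edits against the pre-edit coordinate system:
substitutions (position, from, to) with a from-residue check, then
insertions applied back-to-front; region ranges shift consistently past
insertions. MIM-k selects the k most N-terminal merged S/T sites within
NT+HNG1+HNG2 for S/T→E substitution (the selection order is a package
convention; only the counts and regions are constrained by the biology).
Ins6K inserts six single Lys residues at fixed hinge points; Sub6K
substitutes the first six Gln/Asn in the same regions with Lys.

Net charge of a region is the sum of side-chain charges at neutral pH:
D/E −1, K/R +1, H 0, all else 0; a phosphorylated S/T adds −2 (the
≈1.5–2 negative charges of a phosphate at pH 7; configurable). A
phospho-mimic Glu contributes only −1 — deliberately distinct, since Glu
only partially mimics phosphate charge. Consequences checked by the
suite: MIM22 shifts the NT+hinge charge by exactly −22, full
phosphorylation at those 22 sites by −44, both +6 Lys variants by +6
relative to MIM22, shifts are additive for non-interacting edits, and the
series orders strictly WT > MIM10 > MIM14 > MIM18 > MIM22.

## Equilibrium binding and Kd fitting

n_sites independent identical sites per RNA; per-site occupancy
θ = P_free/(K_d + P_free). With depletion on (default), P_free solves
P_free = P_total − n·R_total·θ, i.e. the positive root of
P_free² + (K_d + nR − P)P_free − K_d·P = 0, unique in [0, P]. Fraction
bound is f = 1 − (1−θ)ⁿ — the probability an RNA carries ≥1 protein,
matching gel quantification where every shifted band counts — and the
shift-class distribution is Binomial(n, θ), whose multi-band prediction is
the model's account of multiple gel shifts. At R ≤ K_d/100 the depletion
and free≈total forms agree to <1%. Cooperativity (Hill) is deliberately
excluded from the default model.

Titrations use the standard ladder (0, 10.4, 26.3, 52.5, 78.3, 104, 158,
210, 420, 630 nM protein; 10.4 nM RNA) plus optional Gaussian noise
clipped to [0,1]. Fitting minimizes the sum of squared residuals over
log₁₀K_d in [10⁻², 10⁵] nM — a coarse 71-point grid to bracket the
optimum, then bounded scalar minimization (xatol 10⁻¹⁰) — so positivity
and ladder-scale conditioning are automatic. A series whose maximum
observed fraction is below 0.02 is reported as an explicit **no-binding**
result carrying a K_d lower bound P_max(1−t)/t rather than a numeric
estimate. Bootstrap CIs resample titration points with replacement.
Noise-free recovery at the ladder is exact to ≪1%; under noise sd 0.03
the median relative error stays below 15% across K_d ∈ [30, 630] nM
(200 replicates per value in the suite).

## Problem sizes and determinism

The default study conditions — 5 Mb, 300 IESs, 20×, 50-nt reads, c = 0.05
— are the package's desk-scale rendering of a genome-wide experiment
(50 Mb of IES, >8,000 loci, of which 5,606 are 1–5 kb): per-locus depth
and the count-ratio statistics are scale-free, so medians and recovery
errors transfer, while anything requiring the real locus catalogue
(genome-wide profiles of specific loci) is out of scope. Every simulation
is reproducible byte-for-byte from (config, seed); the orchestration
writes logs with the config hash, library versions and all dropped-record
counts.

## What the synthetic data do not show

Uniform read placement ignores GC/mappability bias, fragment-length
effects and PCR duplicates; elimination is modeled per-IES as a retained
fraction with no boundary heterogeneity or alternative excision; ChIP
enrichment is a two-level step function with no peak shape inside IES
bodies; EMSA noise is i.i.d. Gaussian on the bound fraction rather than
gel-quantification error. Passing tests therefore validate the statistics
and their implementations, not the biology of any particular dataset.
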