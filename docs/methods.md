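# Methods

## The problem

Somatic variants at allele frequencies of 10^-3 to 10^-4 sit well below
the combined error floor of standard library preparation and Illumina
sequencing. `umivar` implements the two-stage strategy used by barcoded
amplicon assays to reach ~1/10,000: (1) collapse all reads deriving from
one captured template molecule into a single consensus, which removes
errors that arise after the first copy of the template; (2) compare the
surviving calls against an empirical, position- and substitution-specific
background measured in control samples, which removes the reproducible
damage artifacts that consensus building cannot touch.

## Assay model

A capture is one probe-hybridisation event on one single-stranded
template molecule. The captured insert (default 126 bp) is flanked by
two 12-base random UMIs, so a 150 bp fully overlapping read pair covers
UMI + insert + UMI. A sample is ~30,000 captures per probe region at
~30X reads per capture (~30 M reads over ~1 M captures); desk-scale runs
use one probe and 10X.

Error channels, by where they strike:

* **Endogenous variants** (round 0): on the template; present in ~100%
  of the capture's reads.
* **Template damage and first-round synthesis errors** (round 1):
  lesions acquired ex vivo (oxidation, deamination) or polymerase errors
  in the founding copy of the template. Everything sequenced descends
  from that founding copy, so these also appear in ~100% of the
  capture's reads and are indistinguishable from endogenous variants at
  the capture level. They are removed only by demanding that a variant
  recur in >= 5 independent captures.
* **Exponential PCR errors** (round k >= 2): an error in cycle k arises
  on one of the 2^(k-1) copies made from the duplex founder and ends at
  a 2^-k fraction of the strand pool — 25% of reads for round 2, less
  for later rounds. The 75% within-bin agreement rule removes all of
  them.
* **Sequencing errors**: independent per mate; a base survives
  paired-end merging only if both mates agree, so a sequencing error
  must hit the same position with the same wrong base twice
  (probability ~e^2/3 per site instead of e); the within-bin agreement
  rule then removes the stragglers.

## Consensus construction

Read pairs are merged position-wise (disagreement or N -> N; this keeps
more information than discarding mismatched pairs). The merged read's
barcode is the 5' UMI + 3' UMI + first five post-UMI bases (29
informative symbols). Reads are binned greedily: unique barcodes in
descending read support (ties broken lexicographically), each joining
the first established bin within Hamming distance 1, else founding a
bin. N is an ordinary fifth symbol — it mismatches every base (so an
N-bearing barcode can diverge by at most one position) but matches
another N. Reads whose anchor is entirely N are dropped.

A bin with fewer than `min_reads` (default 5) members is rejected.
Otherwise each position takes the most common non-N base when its count
reaches `agreement` (default 0.75) of *all* members, N-bearing members
included in the denominator; ties and sub-threshold majorities give N
("call nothing" beats "guess").

## Alignment and calling

The targets are a few dozen known 150 bp regions, so consensus reads are
placed by seed-and-verify: every 20-mer of every region (both strands)
is indexed; a read's first clean 20-mer window nominates placements,
each verified by Hamming comparison (N excluded); best placement wins,
rejection above `max_mismatch` (default 10, exposed as a flag since no
canonical value exists). This replaces a general-purpose aligner +
haplotype caller, which add nothing for fixed amplicons and substitution
calls; a VCF import path exists for pipelines that prefer external
callers. Reverse-orientation reads are stored reverse-complemented so
pileups are always plus-strand.

Calls are per (position, alt): emitted when supported by >=
`min_capture_support` (default 5) captures; VAF = supporting / non-N
covering captures. N never supports ref or alt and is excluded from the
denominator. Indels are out of scope: the recurrent indel artifacts of
this library chemistry cannot be separated from signal without protocol
changes, so only substitutions are modelled.

## Background model

For every (chrom, pos, ref, alt) observed in >= 1 of n control samples,
the control VAF vector (0 where a control lacks the call; VAFs above
`het_ceiling` = 0.25 treated as germline and replaced by 0) is fitted,
after removing the `outlier_drop` (default 1) highest values, as a
Student's t with df = n - 1, location = mean, scale = sample standard
deviation. The central alpha-mass interval gives (low, high); low is
floored at 0 and kept for diagnostics only — a call is significant iff
its VAF strictly exceeds *high*. The interval is central rather than an
upper-tail bound; a one-sided variant would only shift the effective
alpha and the choice is recorded here for reproducibility.

Keys never seen in controls are judged against a generic fallback: one t
distribution per complement-collapsed (trinucleotide context, alt)
class, pooling one VAF per interior panel position per control (zeros
included). Pooling cold positions into the class is deliberate: it is
exactly why a context-only background underestimates hot positions and
overestimates clean ones, the failure mode that motivates the positional
model. Edge positions (no context) are never called significant.

Alpha is expressed as a count of trailing nines (1 -> 0.9, 10 ->
0.9999999999); sweeps over 1..15 nines are monotone by construction and
are asserted as such.

Degenerate case: a key whose retained control VAFs are all equal (most
often all zero) has scale 0 and a point interval, so any test VAF above
that point is significant. An all-zero background is real evidence of a
clean position, not missing data; the consequence — a variant seen in
only one control can leave a zero threshold behind after outlier
removal — is mitigated by capturing controls at the same depth as test
samples so controls see every hotspot the test sample can reach.

## Simulator

The generator emulates: diploid molecules (two haplotypes; germline
variants ride their haplotype deterministically so linked SNPs co-occur
on reads; somatic carriers are Binomial(captures, VAF) subsets pinned to
one haplotype), fresh random UMI pairs per capture, position-specific
template damage, founding-synthesis errors, capped branching-process PCR,
Poisson read depth per capture, and independent per-base per-mate
sequencing errors. Everything is recorded in `SimTruth` down to
individual reads.

Key defaults and their origin:

* `pcr_cycles` 29, `reads_per_capture_mean` 30, UMI length 12, sample
  index 16 — the assay's standard protocol values.
* `pcr_error_rate` 3e-6 per base per synthesis: chosen so a paper-scale
  sample (32 probes x 30,000 captures x ~126 nt) accrues ~400
  first-round errors, the scale at which the multi-capture rule is
  stressed. An exact-count injection (`first_round_errors`) exists for
  controlled experiments.
* `seq_error_rate` 1e-3: typical Illumina substitution rate.
* `ct_bias` 8: given an error at C (or G), the C>T (G>A) substitution is
  chosen with 8x weight, reproducing a C>T-dominated artifact spectrum
  (~half of events) without calibrating to any measured spectrum.
* `pool_cap` 512 strands per capture with uniform (hypergeometric)
  subsampling after each doubling: 29 literal doublings are intractable
  and the cap preserves lineage fractions in expectation. Joint
  subsampling across lineages of one capture is approximated by
  independent hypergeometric draws with a corrective trim, exact in the
  regimes the tests probe (no cap, or rare lineages).
* Damage landscape (`make_damage_profile`): each interior (position,
  alt) key is a hotspot with a class-dependent probability (C>T 0.12,
  CpG C>T 0.45, C>A 0.06, T>C 0.05, C>G 0.02, T>A 0.015, T>G 0.004);
  hotspot rates are lognormal (median 5e-4, sigma 0.5), everything else
  is clean. This reproduces the qualitative structure of real amplicon
  backgrounds — position-specific, recurrent across samples,
  C>T/CpG-dominated, T>G almost never hot — with rates that make
  hotspot calls comfortably clear the 5-capture rule at the capture
  depths used. A profile is a property of the experiment; samples of
  one experiment share it, another experiment is its lognormal
  perturbation (`DamageProfile.perturb`).

What the generator does **not** emulate: quality-score structure
(constant placeholders; the method never consults qualities), indels,
GC-dependent capture efficiency, partially overlapping mates, chimeric
amplicons, sample-index hopping. Passing tests therefore demonstrate the
algorithmic error-elimination chain under the stated error model, not
robustness to every artifact of real libraries.

## Validation studies (problem sizes)

* Spike-in: one probe, 50,000 test captures, 10 controls at 50,000
  captures each, 10X reads, spike VAF 1e-4, alpha ten nines. Control
  depth matches test depth so positional backgrounds cover every
  reachable hotspot. Note that 50,000 x 1e-4 = 5 expected carrier
  molecules against a 5-capture support threshold: detection of a
  1/10,000 spike is intrinsically marginal (P ~ 0.5 over capture
  sampling), which is the honest meaning of a "limit of detection". The
  spike site is chosen damage-free (T>G class), matching the observation
  that the limit holds only where the local background is low.
* First-round errors: 32 probes x 940 captures, 400 injected errors, all
  other channels off; survivors of the 5-capture rule are counted
  (expected: zero; ~12,000 possible substitution keys make a 5-fold
  collision vanishingly unlikely).
* Dilution series: dilutions 1 .. 2e-4 (expected VAF 0.5 .. 1e-4) with
  capture depth scaled to keep >= ~5 expected carriers per point;
  detection plus log-log slope of observed vs expected VAF.

## Known limitations

* Substitutions only; no indel or structural-variant significance.
* The greedy 1-mismatch barcode clustering can, in principle, chain
  two true captures whose UMIs differ by one base; with 24 random UMI
  bases the collision probability is negligible at the depths used.
* The t model treats per-control VAFs as exchangeable; batch structure
  within an experiment is not modelled (an external-background mode
  exists but no hierarchical model).
* Positions at probe edges have no trinucleotide context and are never
  declared significant.
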