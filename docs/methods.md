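# Methods

## Setting

A diploid hybrid of two polymorphic haploid yeast isolates (parents P1 and
P2) is sporulated; all four viable spores of each tetrad are sequenced and
genotyped at the markers where the parents differ.  Each marker in each spore
is assigned a parental origin (P1, P2, or NA), giving a markers × 4 matrix
per tetrad.  Under Mendelian segregation every marker segregates 2:2; meiotic
recombination and pre-meiotic homozygosis produce the deviations this package
detects and quantifies.

## Event model

The caller works on maximal runs of constant spore-origin 4-tuples
("segments").  2:2 segments are *anchors*; consecutive non-2:2 segments
between two anchors form one event cluster, classified by the total phase
change between the anchors:

| spores switching | cluster call |
|---|---|
| 0 | conversion tracts only (`NCO_31`, `NCO_40`) |
| 2 | one crossover (`CO_with_GC31` if a qualifying 3:1 tract is present, else `CO_plain`) |
| 4 | a double crossover (`doubleCO_with_GC40` / `doubleCO`) |

A conversion tract is reported only when it covers at least
`min_gc_markers = 3` markers; shorter non-2:2 runs still transmit the phase
comparison between their flanking anchors.  4:0 tracts whose
midpoint-convention span exceeds `loh_threshold_bp = 10 000` are emitted as
`LOH`; a tract of exactly 10 kb is still a conversion.  Because the 2:2
phases flanking an LOH are unrelated (the region was homozygosed before the
final meiosis), no phase-change call is made across an LOH.  1:3 and 0:4
patterns are mirrored onto 3:1 and 4:0 with a `retained_parent` attribute.
An internal LOH has two initiation points (LOHips), a tract touching one
analyzed boundary has one, and a tract covering a whole analyzed block has
none.

Tract coordinates use the midpoint convention: from the midpoint between the
last non-converted and first converted marker to the midpoint between the
last converted and next non-converted marker; boundary-touching tracts extend
to the analyzed boundary.  The CO point estimate used for densities and
interference is the tract midpoint, or the inter-anchor midpoint for
tractless COs.  Exclusion regions (user-supplied BED, e.g. subtelomeres) act
as analyzed-block boundaries: no event is called across them.  All interval
outputs are 0-based half-open; variant-table inputs are 1-based (VCF
convention).

The rationale for cluster-level classification (rather than a complex-event
taxonomy) is that the observable is the anchor phase change; two COs with no
2:2 marker between them are intrinsically one cluster and cannot be resolved.

## RTG accounting

A tetrad is flagged "with RTG" when it carries at least one double CO or one
LOH tract.  RTG-derived crossovers are counted as `double_co + 2·loh_internal
+ 1·loh_telomeric = double_co + lohips`.  Meiotic COs falling inside LOH are
invisible; assuming a homogeneous recombination rate, the expected hidden
count is `observed_COs × loh_bp / non_loh_bp`, of which a detectability
fraction (default 100/190 ≈ 0.53, reflecting that only odd numbers of COs
inside an LOH shift its borders detectably) is added to the per-meiosis
numerator.  Detected per-RTG rates are underestimates because only two of the
four prophase chromatids are retained in the analyzed daughter cell; the
conventional 2/3 correction is reported alongside, never substituted.

## Simulator

The simulator is mechanistic at the chromatid level.  A meiosis replicates
each homolog into two sister chromatids (four int8 origin vectors over the
marker map) and applies events left to right:

* **CO placement** — a stationary gamma renewal process per chromosome with
  shape *k* (interference; *k* = 1 is Poisson) and scale θ (kb).  The process
  is started 50 mean intervals upstream so the first CO follows the
  equilibrium interval distribution and marginal CO density is uniform.
  Candidate COs initiating inside a coldspot, or whose conversion tract
  would overlap the pericentromeric halo, are discarded.
* **Rate calibration** — the fitted (k, θ) of real inter-CO distances on
  short chromosomes describes censored spacings, not the renewal intensity:
  a stationary renewal at θ = 187 kb over 12 Mb would give ~44 COs per
  meiosis.  The simulator therefore treats `co_per_meiosis_mean` (default
  19.9) as the calibration target: the renewal scale is rescaled internally
  so the expected CO count over the analyzed (non-coldspot, non-halo) genome
  matches, while the shape — the interference structure — is preserved.
  Setting `co_per_meiosis_mean=None` uses θ literally (useful for
  parameter-recovery studies on long chromosomes).
* **Chromatid choice** — each CO involves one chromatid per homolog, chosen
  uniformly (no chromatid interference).  After earlier exchanges the two
  chosen chromatids may locally carry the same parent, in which case the
  exchange is genotype-silent; truth events record this as `visible=False`.
  Roughly 15–30 % of COs on multi-CO chromosomes are silent — the classical
  reason genetic maps saturate — so callers are validated against *visible*
  truth COs.
* **Conversion tracts** — lognormal lengths parameterized by median
  (defaults 2.9 kb for CO-associated, 2.2 kb for NCO tracts) and log-sd 0.8
  (the data constrain only medians; lognormal is the conventional
  right-skewed choice).  A CO tract is resolved by copying one involved
  strand's local content onto both (3:1 where they differed); an NCO copies
  a uniformly chosen opposite-homolog chromatid's content onto the
  recipient.
* **NCO placement** — uniform over the non-coldspot genome, independent of
  COs; expected count `nco_per_meiosis_mean` (default 5.6).
* **Obligate CO** — optional (off by default, because zero-exchange
  chromosomes are a real and frequent outcome in low-recombination
  species): chromosomes drawing zero COs are redrawn once.  Note this model
  lifts the expected count of small chromosomes only modestly; it does not
  force the CO-vs-length regression intercept to 1, and the package's test
  asserts only a positive intercept.
* **Pericentromeric halo** — no conversion tract may overlap
  `centromere_halo_bp` (default 5 kb) around each centromere, emulating the
  observed centromere-proximal suppression and guaranteeing that
  centromere-linked markers stay heterozygous through RTG.

**Return to growth** is simulated as: (1) a full prophase event set as
above; (2) mitotic segregation retaining one chromatid per homolog per
chromosome, chosen uniformly among those whose centromere-proximal origin
matches each parent (centromeres stay heterozygous); (3) a complete second
meiosis on the retained diploid.  The truth set contains the raw prophase
events (`rtg_prophase`), the final-meiosis events (`meiosis`), and the
observable signatures the retention leaves in the diploid (`rtg`): maximal
homozygous runs (LOH above 10 kb, else 4:0 conversion tracts; runs whose
heterozygous flanks switch parent on both homologs are double-CO tracts) and
tractless double-CO points where both homologs switch at the same marker
boundary.  These `rtg` signatures use the caller's own midpoint convention,
so truth and calls are directly comparable.  Exactly one RTG round is
modeled, and prophase NCO frequency equals the meiotic one (the data do not
constrain either choice).

**Default genome** — eight chromosomes named chrA–chrH totalling 12 Mb, one
1-Mb coldspot covering the left arm of chrC (the introgressed,
recombination-refractory arm carrying the mating-type locus in the motivating
system), centromeres mid-chromosome.  **Markers** are placed with
i.i.d. Uniform(0.5 s, 1.5 s) gaps at s = 196 bp so that both the median and
mean spacing match the target (~61 000 markers); real marker maps are more
skewed, with occasional multi-kb gaps near repeats, which this generator does
not emulate.  All randomness flows from explicit seeds; per-tetrad
substreams are drawn deterministically from a master seed.

### What passing tests on simulated data do and do not show

The simulator reproduces the segregation patterns, event-size scales, rates
and RTG signatures the caller is designed for, so round-trip tests validate
the calling logic, the coordinate conventions and the accounting arithmetic.
They do not exercise alignment artifacts, coverage-dependent genotype noise
(NA is modeled as uniform random missingness), translocated subtelomeres, or
site-specific hotspot machinery — on real data those are handled upstream by
the marker filters and the user-supplied exclusion BED.

## Hotspot null

Hotspot candidates are disjoint 5-kb windows holding ≥7 CO points (including
double COs and LOH borders, which carry pre-RTG crossovers; a flag restricts
to meiotic COs).  The null places the same number of COs uniformly over the
analyzed (non-excluded) genome 10⁵ times.  The default empirical p is
family-wise — the fraction of randomizations whose *maximum* window count
reaches the observed count — the stricter of the two possible readings of a
genome-wide randomization test; a per-window variant is available.  The
family-wise null is validated against exact multinomial enumeration on toy
genomes.

## Interference

Inter-CO distances are pooled per (tetrad, chromosome), in kb, and fitted by
maximum likelihood to a gamma distribution (`scipy.stats.gamma.fit` with
location fixed at 0).  The no-interference test is a Kolmogorov–Smirnov test
of the distances against an exponential with the sample mean
(`reference_shape=1`); a second KS test against an arbitrary reference shape
(e.g. another species' fitted *k*, scale matched to the sample mean) supports
cross-dataset comparison — the test is data-vs-model, the simplest
construction consistent with a two-shape comparison.  LOH sizes are fitted
the same way; their following approximately the same gamma law as inter-CO
distances is evidence of their aborted-meiotic origin.  Shape estimates from
short chromosomes are biased by interval censoring; parameter-recovery
guarantees (±10 % at n = 5 000) hold in the low-censoring regime (long
chromosomes or direct gamma samples).

## Numerical conventions and edge cases

* Filter boundary semantics: parental coverage bounds inclusive; parental
  mapping quality ≥ 100 but spore mapping quality > 100 (both as specified
  for the respective stages, despite the asymmetry); allele-frequency
  equality to 0/1 within 1e-9; NA fraction threshold inclusive at 30 %;
  balance bounds exclusive at 30 %/70 %.
* Markers with any NA spore are disregarded per tetrad before calling.
* A chromosome (or analyzed block) with fewer than two markers yields a
  warning and no events.
* Degenerate gamma fits (constant samples) raise rather than returning an
  infinite shape.
* `filter_matrix` is idempotent and row-order independent because all
  statistics are per-marker.
* Two COs with at least one 2:2 anchor marker between them are distinct;
  with none they form one cluster and are intrinsically unresolvable.

## Problem sizes

Defaults used by the test suite and examples: ~61 000 markers over 12 Mb;
cohorts of 8–49 tetrads for round-trip and accounting checks; 500 meioses
for rate calibration; 5 000 observations for gamma parameter recovery;
2×10⁴–10⁵ randomizations for the hotspot null.  These sizes give Monte-Carlo
errors comfortably inside the asserted tolerances while keeping the full
suite fast on a single CPU.

## Known limitations

* Spores are proxies for chromatids; sister-chromatid phasing is not
  attempted, and chromatid interference is not modeled.
* The RTG model assumes exactly one abortive prophase; repeated RTG rounds
  would stack signatures this package would read as one.
* The homogeneous-rate extrapolation of COs inside LOH ignores local rate
  variation, and the parity argument (even CO numbers inside an LOH are
  invisible) is applied as a fixed detectability fraction, not modeled
  probabilistically.
* Read-level phenomena (mapping error, coverage dips, aneuploidy, spore
  inviability) are out of scope; the marker filters expect variant summary
  tables produced upstream.
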