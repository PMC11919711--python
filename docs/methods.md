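# Methods

## Arrays, direct repeats and library designs

A crRNA array is modelled as the exact interleaved concatenation
`DR0 + s1 + DR1 + … + sN + DRN`: N spacers of 19–23 nt, each preceded by
a 19-nt direct repeat, plus a terminal repeat, giving a total length of
`19·(N+1) + Σ|s_i|`. Eleven DR variant sequences are built in (the
natural AsCas12a repeat `WT`, numbered variants `DR1…DR18`, and the two
`DR_NS*` variants), chosen to minimise homology across positions while
retaining processing activity. Position assignments are fixed per plex
level (1, 3, 4, 5, 6, 8, 10); every assignment starts with `WT` (fixed
in the expression vector) and ends with `DR8` (the vector's terminal
variant). Single-plex constructs are modelled as `WT + spacer + DR8`,
matching the vector whose 3′ repeat is the DR8 variant; an all-WT legacy
vector can be expressed through a custom assignment. No assignment is
published for 2-plex arrays, so 2-plex requires a custom assignment.

Spacer exclusion rules: any BsmBI recognition site (`CGTCTC` or its
reverse complement — the arrays are cloned by Golden Gate into a
BsmBI-cut vector), any run of ≥3 consecutive T (mimicking the RNA
Pol III terminator), an off-target annotation of `MAX` in any tier/bin,
or more than one tier-I bin-I genomic match. Each rejected spacer
carries exactly one primary reason code with precedence
restriction > polyT > off-target > efficacy. The polyT rule is
deliberately strict (canonical Pol III terminators are ≥4 T) but kept at
3 as the operative design rule; it is configurable. The rule applies to
spacer sequences only — the DRs themselves contain `TTT`.

Three library archetypes are generated:

- **TSS tiling (singles).** Candidates carry a `tss_offset` — the signed
  distance from the TSS to the PAM start (negative = upstream; the
  anchor choice is ours, stated here because upstream conventions vary).
  Candidates inside the window (default −50 to +300 bp, inclusive) that
  pass the filters each become a 1-plex construct.
- **Test/context 6-plex (positional).** Every (test spacer × test
  position × context set) triple yields one construct: the context
  set's spacer at the test position is replaced by the test spacer.
  All five context sets are used for every test spacer, so the library
  size is the full product `tests × 6 × 5`.
- **Combinatorial element-targeting 6-plex.** Five ordered 3-plex
  element groups (promoter, three enhancers, all-negative) fill
  positions 1–3; positions 4–6 take every 3-spacer combination from the
  15-spacer pool (unordered combinations by default; ordered
  permutations optionally), and every array is also emitted in reversed
  spacer order, with identical tuples collapsed. The unordered default
  yields 5 × C(15,3) × 2 = 4,550 arrays before collapse. No natural
  reading of this enumeration reproduces the historically reported
  total of 6,370 such arrays; the de-duplication/subsetting behind that
  figure is unspecified, so both enumeration modes are exposed and
  nothing downstream depends on the total.

Negative-control construct sampling draws each 6-plex combination
without replacement from a single pool (intergenic-targeting or
non-targeting; never mixed within a construct) and enforces unique
spacer tuples. Intergenic control regions are selected by excluding
everything within 10 kb of a gene or 3 kb of a DNase hypersensitive
site, tiling the remainder into 1-kb fragments, dropping fragments
containing ≥20 consecutive N and sampling ≤90 fragments per chromosome.
Non-targeting Cas12a spacers are derived from 20-nt Cas9-style spacers
by removing the 5′ G and appending a random 4-mer.

## Synthetic-data generator

The generator provides ground truth for every downstream stage. What it
emulates, and what it does not:

- **Screens.** Initial abundances are uniform or log-normal (default
  σ = 0.5, a typical post-cloning library skew). Growth is
  multiplicative per doubling: relative abundance is scaled by
  `2^(γ·D)` and renormalised, chosen so the fitness-score estimator is
  exactly unbiased — the log2 ratio of any construct to a γ = 0
  reference changes by exactly γ·D. Sequencing is a multinomial draw at
  the requested depth (default 10^6 reads/sample over D = 10 doublings,
  two replicates). Not modelled: clonal drift, bottlenecks, PCR
  amplification noise beyond multinomial sampling.
- **Array reads.** Paired reads (default 2×250) from staggered starts
  (0–8 nt, emulating staggered amplification primers), substitution
  errors only — read indels would be unmappable under the perfect-match
  contract anyway. Lentiviral chimeras swap the spacer suffix at a
  uniformly chosen DR junction with another construct (homology-driven
  recombination at the repeats); the swap is redrawn if it happens to
  reproduce a designed tuple, since such a molecule is physically
  indistinguishable from that construct. The true chimera rate in
  screens is low and uncertain; the default 0.01 is nominal and
  configurable. PCR by-products are random-sequence fragments at a
  configurable rate. Not modelled: quality-score structure, GC bias,
  intra-spacer breakpoints (config extension point).
- **Amplicons.** Every read spans the amplicon (default 340 bp, two cut
  sites ~112 bp apart); a read acquires an indel at each cut site
  independently with the site's frequency, centred at the site, sizes
  drawn from a small empirical-looking distribution favouring 1–5 bp
  deletions.
- **Flow cytometry.** Log-normal expression; knockdown scales the
  target population median by (1 − f) under the same multiplicative
  noise. Not modelled: autofluorescence floors, doublets, staining
  saturation.

Passing tests on these data demonstrate the *estimators and contracts*
(unbiasedness, exact-match strictness, calibration), not robustness to
real-data artefacts such as index hopping, jackpotting or
heteroskedastic noise.

## Read mapping

Mapping is exact-match by contract: the position-specific DRs are
located as exact anchors, the inter-DR segments are extracted as
candidate spacers and looked up per position, and the fragment is
**mapped** if the resolved spacer tuple is a designed construct,
**recombinant** if every segment is individually valid at its position
but the tuple was never designed, and **unmapped** otherwise. Anchoring
is position-local (`DR_p + segment + DR_{p+1}` anywhere in either mate)
rather than a sequential walk, so a corrupted DR only loses its
adjacent positions. Where both mates cover a position they must agree —
any disagreement, ambiguity or gap conservatively unmaps the fragment.
Both mates are required by default (`allow_single_mate` relaxes this
for short arrays). The implementation is validated read-by-read against
a brute-force oracle (exhaustive full-sequence matching for the mapped
class, exhaustive per-position vocabulary matching for the recombinant
class), which is exact for error-free reads; with errors, fragments
whose mates disagree are deliberately discarded rather than rescued.

## Screen statistics

Constructs below 1 RPM (before pseudocounting) in **any** replicate at
T0 are removed; survivors get a pseudocount of 1, RPM is recomputed and
γ evaluated per replicate as defined in the README, then averaged.
Normalising each timepoint by the *median negative-control RPM* makes
the control median γ exactly zero whenever the controls share a common
initial abundance and approximately zero (to sampling noise) otherwise —
the median of ratios is not identically the ratio of medians.

Hit calling uses linear-interpolation percentiles of the
negative-control distribution (default 5th) with a strict inequality,
so ties never count as hits. The metagene profile is a moving average
of scores over PAM positions relative to the TSS; the published-style
analysis states a moving average without a width, so the default is a
±25 bp window (configurable; the oracle test is width-agnostic), with
empty windows yielding missing values. Test/context aggregation takes
the mean of the k = 3 most-negative context scores per (test spacer,
position) on replicate-averaged γ (per-replicate selection would be a
config alternative); groups with fewer than k contexts are averaged
over all and flagged. Recall at a position is the percentage of truly
active spacers scoring below the 5th percentile of negative-control
aggregates *at the same position*. Gene-level summaries assign each
gene the TSS of its most negative crRNA (ties broken by lexicographic
TSS id) and summarise TSSs by the mean of their top-3 crRNAs.

Group-testing categories are the 2^4 = 16 presence patterns over
(promoter, e1, e2, e3); a construct sets a bit iff it carries ≥1 spacer
for that element. Category summaries report median, IQR and n over
replicate-mean γ, with empty categories reported at n = 0.

MOI is estimated from the transduced fraction under Poisson statistics,
`MOI = −ln(1 − f)`. Flow knockdown metrics are the median knockdown
percentage, `100·(1 − median(target)/median(control))`, and the percent
of target cells strictly below the control 5th percentile.

## Indel model

Per-base indel fractions count, at every amplicon base, the fraction of
reads with any indel interval overlapping that base; reads are assumed
amplicon-spanning (amplicon sequencing), so coverage is uniform, and
the profile is summarised by its maximum. The knockdown bound treats
the maximum per-base indel fraction as an allelic disruption
probability: each of the region's DNA copies is independently disrupted
with that probability, a disrupted allele contributes zero expression
(`full_loss`), and per-cell knockdown is `100 × disrupted/copies`,
summarised by the simulated mean and median plus the closed-form mean
`100 × freq`. This independent-allele full-loss model is this package's
assumption — it is deliberately an *upper* estimate (real indels are
often small, in-frame or non-disruptive), and the `effect_model` hook
exists for joint multi-site configurations. With low frequencies and
copies ≥ 2 the median sits far below the mean (most cells carry no
disrupted allele), which is why observed knockdowns of tens of percent
cannot be explained by percent-level indel frequencies.

## Numerical and interface choices

- Coordinates are 0-based half-open throughout; BED in/out unchanged.
- One explicit seed per stochastic operation; identical seeds give
  bit-identical outputs (numpy `default_rng`).
- Percentiles use numpy's linear interpolation.
- Simulation sizes in the test suite and acceptance script (200–4,550
  constructs, 10^6–5×10^6 reads, 5,000 fragments) were chosen as the
  smallest scales at which the estimators' sampling error is an order
  of magnitude below the effects being measured.
- Degenerate inputs fail loudly: empty libraries, zero-total samples,
  empty negative-control sets, zero-coverage regions and out-of-range
  fractions all raise with the offending record named where possible.

## Known limitations

- The mapper searches the delivered strand only; vector orientation
  fixes strand.
- No fuzzy or indel-tolerant matching — by design, but this means the
  mapped fraction underestimates library representation at high error
  rates.
- The recombination model only forms chimeras at DR junctions and at a
  single junction per fragment.
- The knockdown bound ignores allele-specific expression and partial
  loss-of-function indels (both push the bound further upward).
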