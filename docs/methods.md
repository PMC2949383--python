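# Methods

This note records the models, conventions and numerical choices behind
`tefp`, and what the synthetic validation does and does not demonstrate.

## Coordinates and digestion

All internal coordinates are 0-based half-open; printed coordinate pairs in
the packaged reference tables are imported as (start, end) half-open without
a +1 adjustment, because every printed fragment length in the source data
equals end − start (e.g. a 351 bp amplicon spanning 4761–5112).  The same
convention governs `amplicon_length`; note it is one less than inclusive
base counting would give, which is stated here once and prominently.

Chromosome arms are digested as linear molecules.  A cut is emitted at
i + cut_offset for every occurrence of the recognition sequence at index i;
overlapping occurrences all count; `N` never matches (strict matching, no
IUPAC expansion — HindIII's site is unambiguous and the strict rule is the
simplest testable one).  Fragments tile the sequence, so sizes sum to the
sequence length and the fragment count is cut count + 1.  Only HindIII is
built in (the single enzyme the workflow needs); the enzyme table accepts
additions at run time.

## Probe model

Probes are intervals on a TE family consensus.  In annotation mode an
insertion is hit iff its retained consensus span overlaps the probe interval
by at least `min_overlap` = 100 bp — a Southern probe needs substantial
duplex to produce a visible signal; the value is a documented knob, not a
measurement.  The hit's genomic interval is the linear, strand-aware image
of the overlapped consensus segment.  Default I-element probe intervals are
5′ = consensus 0–1800 and 3′ = 3600–5371 on the 5,371 bp consensus.  The
cloned probes the defaults stand in for have unpublished boundaries; the
defaults are config-overridable and were chosen to bracket the published
RT-PCR primer anchors (22–721 and 4761–5112) so that any full-length copy
hits both probes while a mid-truncated copy hits only the 3′ probe — the
property the analysis depends on.  Sequence mode uses exact k-mer seeds
(k = 12) on both strands, ungapped diagonal scoring trimmed of terminal
mismatches, thresholds min_len = 50 bp and min_identity = 0.85, with
overlapping candidates resolved by keeping the longer, then the leftmost.

## Band prediction and ladder matching

A fragment produces a predicted band iff some single probe hit overlaps it
by ≥ min_overlap; a hit spanning a cut site can light both flanking
fragments.  Fragments of identical exact size collapse into one band
(co-migration).  Observed gel estimates (kb) are compared to exact predicted
sizes in bp with relative error |obs − pred| / pred — the prediction is
exact, the gel estimate carries the error — at default tolerance 0.05,
comfortably above the largest well-paired discrepancy in the packaged
reference comparison (≈ 3.5 %).

Matching is greedy best-first: all within-tolerance pairs sorted by
ascending error (ties: larger predicted size, then input order), accepted
while both members are free.  A maximum-cardinality minimum-error
assignment (Hungarian) is available behind `method="optimal"`.  Greedy is
the default deliberately: on the packaged 18-vs-18 comparison it reproduces
the published "not detected" pattern exactly (16 pairs), whereas the
maximum-cardinality assignment reaches 17 pairs only by accepting visibly
worse pairings; exhaustive enumeration confirms that among 16-pair
assignments the minimum-total-error solution leaves exactly the same four
bands unmatched, i.e. the nd pattern is forced, not a greedy artifact.
Greedy is not guaranteed monotone in the tolerance; the exhaustive oracle
is, and the tests compare the two side by side on small ladders.

## Instability scoring

Band sizes from all lanes are clustered by single linkage on a log2 size
scale with linkage threshold `bin_tol` = 0.02 (log2 units, ≈ 1.4 % size
ratio); a bin's center is the geometric mean of its members.  The log2
scale was chosen so that the distance between the two closest distinct
observed bands in the reference table (4.26 vs 4.24 kb, 0.0068 log2 units)
falls between the default threshold and a finer 0.005 setting — the default
merges them (one gel's run-to-run variation), the finer setting resolves
them, mirroring the configurable resolution of real gel reading.

Lanes are compared as present-bin sets with Dice dissimilarity
(1 − 2|A∩B|/(|A|+|B|); 0 when both sets are empty).  Dice weights shared
bands more heavily than Jaccard, matching the band-sharing reading of gel
comparisons; Jaccard is exposed as an option.  A group is *stable* iff its
maximum pairwise dissimilarity is ≤ threshold, default 0: the underlying
call in the motivating experiments is visual and any reproducible lane
difference was treated as heterogeneity, so the formal default is the
strictest one.  Single-sample groups are *undetermined*.  Between groups,
consensus sets (bins present in ≥ 50 % of a group's lanes — robust to one
aberrant lane) are compared with the same threshold.

## Cytological sites

Addresses follow the Bridges polytene map: division 1–102 (X: 1–20,
2L: 21–40, 2R: 41–60, 3L: 61–80, 3R: 81–100, 4: 101–102), optional band
letter A–F, optional numeric subdivision.  Set comparison defaults to
`ignore_subdivision` (98B2 ≡ 98B) because FISH calls and genome annotation
mix resolution levels; counting defaults to `exact`, since an annotation may
genuinely resolve two subdivisions (98B2 and 98B8) that one FISH signal
cannot, and both are real sites.  Shared-site asterisk annotations in input
are parsed and stored but never used in computation, so the package's
intersections can be compared against an author's markings.  Under every
rule implemented here the three packaged reference lists intersect in three
sites (12F, 86A, 102A), one fewer than the prose claim that accompanied
them; the discrepancy is surfaced by the tests rather than forced.

## Relative expression

Densitometry normalization assumes semi-quantitative PCR in the exponential
regime (band area ∝ input), so the target/reference area ratio divided by
the calibrator's ratio is scale-invariant to lane loading.  The Livak
2^-ΔΔCt path averages replicate Cts *before* differencing (standard
practice and deterministic under unbalanced replication), fixes
amplification efficiency at 100 % (base 2), and reports an error range from
the combined replicate sd s = √(sd²_target + sd²_ref) as
[2^−(ΔΔCt+s), 2^−(ΔΔCt−s)]; single replicates get sd 0.  Samples whose
target is undetected in every replicate are omitted from the RQ output
(an RQ of zero is outside the model).

## Synthetic generator

The generator emulates the study design: a founder genome shared by three
groups of 5 individuals, 10 generations of independent evolution per
individual, and per-family event rates.  Specifics:

* **Families**: jockey-like (5,019 bp consensus, quiescent), I-element-like
  (5,371 bp, mobilized in one group at 0.6 insertions/genome/generation,
  p_full = 0.2), hobo-like DNA transposon (2,959 bp, 0.3 insertions and
  0.15 excisions per genome per generation in all groups).  Rates are
  arbitrary — no transposition-rate estimates exist for the motivating
  system — chosen once so that heterogeneity is detectable with 5
  individuals; only retroelements truncate (uniform 5′ truncation keeping a
  ≥ 500 bp 3′ tail, the product of incomplete target-primed reverse
  transcription) and only DNA transposons excise.
* **Genome scale**: three chromosomes totalling 2 Mb at GC 0.42 with 6 + 8
  + 4 planted full-length copies.  This is ~60× smaller than the real
  euchromatin, which would inflate the probability that two TE copies share
  a restriction fragment by the same factor; to keep the scaled-down genome
  faithful to the real system's band independence, insertion points keep a
  minimum spacing of 13 kb (just above the 12 kb gel detection limit), which
  provably prevents any two copies from sharing a *visible* fragment.
* **Gel noise**: multiplicative lognormal, decomposed into a per-filter
  size-calibration error (sd 0.02) shared by all lanes of one family's gel,
  and a per-band lane jitter (sd 0.002).  Absolute size estimates against a
  marker therefore carry ~2 % error (what the 5 % observed-vs-predicted
  matching tolerance absorbs), while lanes on the same filter are far more
  reproducible (what the 0.02 log2 binning tolerance absorbs) — the reason
  the original design runs individual flies side by side on one filter.
  The detection window (1.5–12 kb, the observed range of the reference
  table) is applied to the filter-level band size so all lanes agree on
  visibility; reported sizes are rounded to 2 decimals in kb.
* **Expression presets**: relative levels are fixed truths, Ct =
  base − log2(level) + N(0, sd) with a flat reference gene, densitometry
  areas ∝ level × lane factor.  The adult-female preset encodes Seattle at
  0.30 / 0.40 / 0.50 of Montpellier for the 5′ / internal / 3′ targets and
  a reactive-strain sample with no 5′ or internal transcripts (emitted as
  undetected) but residual 3′ signal (0.20); the internal-target and
  reactive-3′ values are not published quantities and were set once to
  plausible mid-range values consistent with the qualitative description.
  The gonad preset fixes the I-3′ ratio of the two dysgenic-cross
  conditions at 2.5 and orders both targets as
  Montpellier > dysgenic > non-dysgenic ≥ reactive, with the remaining
  levels (e.g. Montpellier 8× / 6× the Bari calibrator) chosen once as
  plausible magnitudes.
* **Determinism**: all randomness derives from the scenario seed through
  fixed stream constants (`default_rng([seed, stream, …])`, streams: 0
  genome, 1 evolution per group/individual, 2 gels, 3 expression), so any
  artifact regenerates bit-identically from its seed.

## What the synthetic validation shows — and does not

Passing tests show that the analysis chain recovers planted truths: digest
invariants, probe-overlap logic, the published band-pairing and site-count
fixtures, preset expression ratios (exactly at zero noise, within 5 % in
the mean under Ct noise of sd 0.2 with 6 replicates over 200 simulations),
and the qualitative instability pattern (one family unstable in one group,
the DNA transposon unstable everywhere, the control family stable).  The
generator does not model hybridization-intensity variation, partial
digests, nested or rearranged insertions, population structure within a
subline (individuals evolve independently from the founder), selection, or
piRNA-mediated repression dynamics; conclusions about real data rest on the
fixture-based checks, not on simulation realism.  Exact reproduction of the
in silico fragment sizes from a downloaded reference genome is
release-dependent (the original release is unstated) and is deliberately
out of scope, as are raw gel/FISH image processing and all wet-lab
protocol.

## Problem sizes

Defaults were sized for interactive use: 2 Mb genomes digest in
milliseconds, the full three-subline study (15 individuals × 3 families)
simulates and classifies in ~1 s, and the 200-simulation expression
recovery takes ~1.5 s.
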