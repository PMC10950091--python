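# Methods

## The scoring model

Species-informative amplicon panels exploit (near-)fixed nucleotide
differences among species. Each species-seq entry is a bi-allelic variant
with two disjoint association sets: the species expected homozygous for
allele 1 and for allele 2. Entries carry a positive weight `w`; the
convention used by the bundled salmonid panel is `w = 2` for variants whose
one allele is private to a single species ("diagnostic") and `w = 1`
otherwise. Tri-allelic positions are represented as two bi-allelic entries
sharing the variant position (distinct locus-id suffix); the scorer treats
them as independent entries, which slightly overweights such positions but
keeps the genotyping framework strictly bi-allelic.

Scoring assumes fixation: a homozygous genotype adds `w` to every species
associated with that allele and subtracts `w` from every species associated
with the other allele. Heterozygous and missing genotypes are inert
(counted, reported, never scored); genotypes carrying an allele outside the
entry's pair ("foreign", e.g. a third allele seen through the wrong entry of
a tri-allelic pair) are likewise inert but tallied separately. This is what
makes the system insensitive to low-frequency shared polymorphisms: an
allele at frequency `p` perturbs a score only through its `p²` homozygote
mass.

The decision rule has four tunables (all proportions, defaults in
parentheses):

| parameter | default | role |
|-----------|---------|------|
| `thresMS` | 0.5     | call gate on `S/M` (absolute-maximum proportion); with equal weights this is a genotyping-success floor |
| `buffMP`  | 1e-3    | absolute tie-buffer on `S/P` (possible-maximum proportion) for co-reporting candidates |
| `pruneMS` | 0.34    | multi-candidate prune on `S/M`: removes species whose perfect `S/P` rests on too few loci (e.g. 1 of 3 described loci gives 1/3 < 0.34) |
| `thresHET`| 0.06    | heterozygosity fraction (het / genotyped informative loci) above which calls are flagged `ReviewHET` |

Deliberate design points where the rule as stated leaves room:

* The gate uses `S/M`, ranking uses `S/P`. Negative proportions are legal
  and rank low. Species with `P = 0` (no scorable evidence) are excluded
  from ranking entirely.
* Pruning applies only when more than one candidate survives the buffer, as
  the rule is phrased. A consequence worth knowing: a species described by
  very few loci can, under adverse genotypes, be the *sole* candidate with
  a perfect `S/P` and therefore escape pruning — the dominant exclusion
  mode in the shared-polymorphism study below.
* Candidate order is descending `S/P` with alphabetical tie-break;
  `buffMP` is compared as an absolute difference.
* `ReviewHET` is suppressed when nothing genotyped (`G = 0`); the rendered
  suffix is `-ReviewHET`, the flag is also exposed structurally.
* The count string appended to output tables is `HET=<h>;GT=<g>`; the
  no-call sentinel is `NoCall`. Both are this package's documented
  spellings.

## Simulation studies

**Missing data.** For each species, expected homozygous profiles with `k`
informative loci omitted, `k = 1 .. n_informative`, a fresh uniform
`k`-subset per replicate, 1000 replicates per level at the operating size
(so `n_informative × 1000` calls per species, ~5.8×10⁵ for the bundled
panel — a few seconds, vectorised). Because any subset of expected
homozygous genotypes leaves the true species at `S = P`, its possible-score
proportion is exactly 1 and a made call always contains the truth before
pruning; the studies confirm exclusion stays *exactly* zero after pruning as
well. Results are pooled across species into 2-percentage-point
genotyping-success bins (success = retained / informative loci, per
species); ambiguity peaks just above the 50% gate and no-calls dominate
below it. Peak ambiguous-call percentages are reported per simulated
genotype in a bin (no-calls in the denominator); among ambiguous calls the
fraction with exactly one alternative is reported separately.

**Shared polymorphisms.** For each species, `k` affected informative loci
(uniform subset per replicate) at alternative-allele frequency `p`, with
genotypes drawn by Hardy–Weinberg sampling of two independent alleles:
expected homozygote `(1-p)²`, heterozygote `2p(1-p)`, alternative homozygote
`p²`. Only the allele frequency is specified by the study design; the HWE
genotype model is this package's choice of the simplest null — since
heterozygotes are inert, any genotype model with the same homozygote mass
gives equivalent results. Grids: `k ∈ {1, 2, 5, 10, 15}`,
`p ∈ {0.01, 0.05, 0.1, 0.2}`, 2000 replicates per scenario (40,000 per
species; species with fewer informative loci than a grid value skip it — the
three-locus species runs `k ∈ {1, 2}`, 16,000).

Outcomes partition every simulated call: exclusive-correct, true-included
(truth plus alternatives), true-excluded, no-call. Cross-species summaries
are means of per-species rates with percentile bootstrap CIs; since
replicates within a scenario are exchangeable Bernoulli draws, the bootstrap
resamples them parametrically (binomial), which is equivalent to resampling
replicates and much cheaper.

**Randomness.** One root seed; each (study, species, scenario) gets an
independent child stream (`SeedSequence` keyed on study/species/k/p), so a
scenario's result is bit-reproducible and independent of which other
scenarios run in the same process.

## The synthetic reference panel

`refpanel_synthetic` rebuilds the 13-taxon salmonid marker set at the
bookkeeping level, all of which is public: 19 amplicons with their variant
positions (51 positions, 53 entries after the two tri-allelic doubles at
Oki_106172-60-47 and Ots_ARNT-29), per-species diagnostic and total variant
counts (e.g. 51 informative entries for Chinook, 40 for Brown Trout, 3 for
Masu), the 2/1 weight scheme (34 weight-2 entries), and the dropped
associations at One_2.70711-39-43 (Coho polymorphic at discovery, Brown
Trout segregating at 0.125 in validation).

What is *not* public is the per-locus bipartition of species between the
two alleles. These are synthesised once, deterministically: species are
grouped into phylogenetic clades (Salmo, Salvelinus, pink/chum, and the
mykiss/clarkii complex as multi-member clades), each informative entry
assigns clades to alleles at random, and each multi-member clade is split
across the alleles with probability 0.2 — most informative variants
separate clades, a minority segregate within genera. Association omissions
beyond the required ones (cross-species amplification failures) are spread
at random to hit the per-species totals exactly.

Consequently: panel bookkeeping, the zero-exclusion property of the
missing-data study, and all scoring behaviour are exact; confusion
*percentages* (which species pairs collide, how often) depend on the
synthesised bipartitions and are representative rather than reproductions
of the deployed panel's operating points. On this panel the missing-data
ambiguity peak is ~2.5% (deployed panel: 7.45%), ~97% of ambiguous calls
carry one alternative (95.05%), and the adverse shared-polymorphism scenario
(`k = 15, p = 0.2`) excludes the truth in ~0.9% of calls on average
(0.38%) with ~99.1% exclusive-correct (99.25%) — same orders, same
qualitative structure, different digits. The worst-case species here is
Chinook (displaced by the three-locus Masu via the sole-candidate pruning
gap) rather than Brown Trout. The acceptance tests that assert the deployed
panel's digits are expected to fail against the synthetic bipartitions and
are retained as a record of that gap.

## Probe-based genotyping path

The amplicon module is honest plumbing so the FASTQ → genotypes → species
call path is testable offline: allele-specific 15-mer probes (7-base flanks
around the variant base), exact forward-orientation substring counting
against 77 bp single-end reads, and threshold genotyping (depth ≥ 10;
allele-1 ratio ≥ 0.9 / ≤ 0.1 homozygous, 0.2–0.8 heterozygous, otherwise
missing). The thresholds are configurable package defaults, not a
reproduction of any production pipeline. The synthetic read generator
embeds the expected probe at a random offset in random background sequence
with optional per-base error and optional locus dropout (to emulate the
reduced genotyping success of non-target species). It does not model real
amplicon context, PCR duplicates, paralogs, quality scores, or adapter
artefacts — passing the end-to-end test shows the counting and thresholding
logic is correct, not that real libraries will genotype this cleanly.

## Panel diagnostics

Per-sample genotyping success (non-missing fraction; the conventional
non-target screen is > 0.90) and observed heterozygosity (heterozygous /
non-missing; a genotype is heterozygous when its two characters differ).
For known-species collections, per-(species, entry) alternative-allele
frequencies — counting two alleles per homozygote, one per heterozygote,
excluding foreign genotypes — verify assumed fixation. The review cutoff
for dropping an association is an explicit parameter (default 0.1): in
practice frequencies of a few percent are tolerable (the simulations show
~0.05 at 10 loci barely moves accuracy) while ~0.125 warranted removal; no
hidden rule decides this.

## Limitations

* The synthetic reference panel reproduces bookkeeping, not the deployed
  association structure (above).
* The scorer is not a hybrid detector: F1s surface only as high-`ReviewHET`
  samples with near-tied parental candidates; later backcrosses are out of
  scope.
* Tri-allelic double entries are scored independently, ignoring the
  physical linkage of the two entries.
* The simulators draw loci independently; linkage within an amplicon
  (shared dropout of same-amplicon loci) is not modelled.
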