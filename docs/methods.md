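# Methods

`clsig` reimplements, as a tested pipeline, the detection and characterization
of CLL-like stereotyped immunoglobulin heavy-chain rearrangements (CLS-IG) in
B-cell repertoires sorted by donor, CD5 status, immunoglobulin light chain
(IGκ/IGλ) and B-cell subset (TR, N, MZ, MO, SM, DN). This note records the
models, parameter choices, numerical conventions and limitations.

## Preprocessing: UMI consensus

A sequenced molecule is one (UMI, sorted fraction) pair; UMIs are never merged
across fractions. The consensus is a per-position plurality vote over the
reads of the group, after dropping reads whose length deviates from the
group's modal length by more than 10% (`length_outlier_frac`, configurable;
guards against truncated or chimeric reads). Any positional tie emits N — ties
are never silently resolved — and the quality filter then rejects the group: a
consensus passes only with `min_reads_per_umi >= 2` reads and no N. The
conservation law (kept + rejected = UMI groups) is asserted in tests. Quality
scores are ignored: the filter contract is defined on read counts and
ambiguity, not on base qualities. UMI error networks (directional clustering)
are out of scope; one UMI within one fraction is treated as one molecule.

## Annotation

V and J genes are called by overlap alignment (free end gaps on both
sequences; match +1, mismatch −1, gap open −4, gap extend −1, all exposed in
`AnalysisParameters`) of each germline segment against the consensus; the
best score wins and score ties go to the lexicographically smallest gene name.
A V alignment covering less than 50% of the germline is an annotation failure.

V mutation percent is `100 x (mismatches + indel events) / aligned germline
positions`, counted over the aligned V region up to and including the 2nd-CYS
codon (IMGT codon 104); each gap run counts as one event. The junction
(non-templated nucleotides) is excluded from the denominator and the
numerator because it would otherwise inflate apparent mutation. Mutational
status is M at `v_mutation_pct >= 2.0` and U below — the standard CLL
threshold — applied to the clonotype representative.

The junction runs from codon 104 (mapped through the V alignment) to the
J-TRP/PHE codon (mapped through the J alignment), inclusive; the CDR3 is the
junction minus both anchors. Productive requires: junction length divisible by
three, C at the first and W/F at the last junction position, and no stop codon
in the V-frame translation through the junction. IMGT's additional
frameshift-in-V diagnostics are not reimplemented. D segments are called
optionally by longest exact match (>= 5 nt) inside the junction and never
affect downstream analysis. Isotype is tagged by exact constant-region motif
match when present; it enters no analysis.

## Clonotypes

A clonotype is the set of productive rearrangements with identical amino-acid
CDR3 using the same IGHV and IGHJ gene (allele suffixes stripped), partitioned
per donor by default (cross-donor sharing is public-repertoire information
and is never merged; a `global` scope is available). The representative is the
member with the highest read count, ties broken by lowest mutation percent,
then smallest sequence id. Everything downstream operates on representatives.
The table-level clonotyper (`cluster_frame`) is an optimized path for
cohort-scale frames and is tested for exact agreement with the object-level
implementation.

## Stereotyped-subset assignment

A subset definition carries the core features (IGHV clan; core mutational
status U/M/EITHER; CDR3 length), reference CDR3s, an anchored per-position
motif, the typical V genes, an optional predominant gene, a reference cohort
frequency and a light-chain bias. Clans follow the standard family grouping
(IGHV1/5/7 → I, IGHV2/4/6 → II, IGHV3 → III), shipped as an editable YAML
resource.

Assignment first applies the core prefilter (clan, status, exact CDR3
length), then computes amino-acid identity and physicochemical similarity
against each reference CDR3 and checks the motif at its offset. The residue
classes default to a six-class scheme — aliphatic {AILMV}, aromatic {FWY},
polar-uncharged {NQST}, positive {HKR}, negative {DE}, special {CGP} — chosen
so the classes are total and disjoint over the 20 residues, hence similarity
>= identity always; the scheme is configurable because no single scheme is
canonical. A candidate needs identity >= 50%, similarity >= 70% and the motif.

Confidence is our explicit operationalization of an ordinal
borderline/average/good/excellent scale: EXCELLENT at identity >= 90%, GOOD
at >= 70%, AVERAGE when identity and similarity both clear their thresholds
by at least 5 points, else BORDERLINE. Only assignments at `min_confidence`
(default AVERAGE) or higher make a clonotype a CLS-IG. The best subset by
(identity, similarity) wins; exact cross-subset ties yield no assignment and
an AMBIGUOUS flag, preserving the exclusivity invariant (at most one subset
per clonotype). Typicality is TYPICAL when the clonotype's V gene occurs
among the subset's typical genes, NON_TYPICAL for another gene of the same
clan.

Two definition resources ship with the package: a fully synthetic set of 19
subsets used by all tests and simulations, and a best-effort curated file for
the real major subsets whose reference CDR3s are synthetic placeholders
(clearly marked; the true sequences live in external curated resources and
are not redistributed).

### Reverse-status chimeras (rCLS-IG)

To test whether stereotypy depends on the mutational-status core feature, each
representative is rebuilt with the opposite status: an M sequence has its
aligned V region through codon 104 replaced by the unmutated germline (0%
mutation); a U sequence receives random substitutions at germline-matching V
positions — sparing the anchor codon, resampling any substitution that
creates a stop — until a 4% target (default; configurable, must exceed the 2%
threshold). The 4% default keeps chimeras unambiguously M. The junction amino
acids are preserved exactly, and the chimera is re-annotated rather than
patched. How the original analysis mutagenized unmutated sequences is not
specified anywhere we could find; this construction is our own and is recorded
as such.

## Frequencies and statistics

CLS-IG frequencies are per donor within a stratum (any combination of CD5,
light chain, B-subset, mutational status, subset, typicality). Denominator
keys partition all clonotypes; subset/typicality keys partition only the
numerator. A frequency is informative only with >= 2 CLS-IG in the stratum,
otherwise UNDEFINED; UNDEFINED strata are dropped from pairing, never imputed
as zero. Additivity of numerators and denominators over stratum refinements
is property-tested.

The paired Wilcoxon signed-rank test drops zero differences, midranks ties,
and computes the exact two-sided p-value by dynamic programming over doubled
midranks for n <= 25 (equivalent to enumerating all 2^n sign assignments;
verified against brute-force enumeration and, on tie-free data, against
scipy's exact method) with a continuity- and tie-corrected normal
approximation above. It is computed only when >= 3 donors have data on both
sides. The binomial test is scipy's exact two-sided test. Bonferroni families
are declared per comparison panel (e.g. the two within-status CD5 comparisons
form one family); p_adjusted = min(1, m·p). Stars: \*<=0.05, \*\*<=0.01,
\*\*\*<=0.001, \*\*\*\*<=0.0001, applied to adjusted p-values.

V-gene usage for a subset compares its CLS-IG against control clonotypes that
pass the same core features without being assigned; the typical-gene share
and predominant-gene share are tested binomially against the control share.

## Synthetic cohorts

The generator emulates the sorted-cohort structure: 9 donors x 24 fractions
(CD5 ± x IGκ/IGλ x 6 B-subsets). Study conditions, fixed as defaults:

- U-fractions per B-subset: TR 0.97, N 0.95, MZ 0.50, MO 0.12, SM 0.08,
  DN 0.15, shifted +0.15 (CD5+) / −0.15 (CD5−): transitional and naive cells
  are almost exclusively unmutated, memory compartments mutated, CD5+
  fractions skewed toward unmutated rearrangements.
- Optional compartment weights (`DEFAULT_B_SUBSET_WEIGHTS`) make the CD5+
  compartment naive/transitional-dominated and memory-poor, which is what
  produces the bulk CD5 contrast in real repertoires.
- Somatic mutation percent: uniform on [0, 2) for U and [2, 10] for M, with
  the substitution count clamped so a draw never crosses the 2% threshold.
- Spike-ins derive a CDR3 from a subset reference by 1–2 class-preserving
  substitutions (similarity stays 100%, motif intact). Zero-substitution
  spikes are excluded by default because byte-identical CDR3s collapse into a
  single clonotype per donor, making a molecule-level spike frequency
  unrecoverable by a clonotype-level pipeline; the bound can be widened.
  Spike rates can be expressed per molecule of the matching mutational status
  or per molecule overall, in the 0.005%–0.1% range typical of such cohorts.
- Reads: one molecule = one unique UMI (14–16 nt), 1 + Poisson(2) reads,
  iid per-base substitution errors at 0.002.
- N-regions are uniform random nucleotides with geometric length (mean 6),
  frame-corrected by trimming; stop-containing junctions are resampled.

All randomness flows from one integer seed; fixed seed gives byte-identical
outputs. Not emulated: SHM hotspot targeting (RGYW/WRCY), indel SHM, clonal
lineages, isotype switching, primer/chimera artifacts. Passing tests
therefore demonstrate correctness of the pipeline's logic on data with the
stated structure, not robustness to every artifact of real amplicon data.

The germline resource used by tests is a synthetic toy set (12 V across the
three clans, 2 D, 3 J) carrying IMGT-style names so the clan table applies;
sequences are generated, not real alleles. Real analyses should supply an
IMGT-gapped germline FASTA; mutation percentages are reference-release
dependent.

## Problem sizes in the test and acceptance runs

Chosen to exercise the published-scale behavior at desk scale: the
emergent-CD5-contrast property uses 20 replicates of a 9-donor cohort with
weighted compartments totalling ~1.7M clonotypes per replicate (the
multi-million-clonotype scale of real sorted cohorts) with within-status CLS rates
of 0.15% (U) and 0.02% (M) — a pre-run power analysis sized the cohort so the
bulk paired Wilcoxon at nine donors has adequate power while within-status
comparisons stay null. Frequency-recovery uses 100 replicates of ~151k
molecules with spikes at 0.02% and 0.005%. Sensitivity/specificity use 1,000
spike-ins and 1,000 core-feature-matched random CDR3s.

## Known limitations

- The confidence scale and the residue-class scheme are explicit
  operationalizations; external tools' internal scales will differ.
- The curated major-subset file contains placeholder reference CDR3s and
  permissive motifs; it is a schema demonstration, not a curated resource.
- Productivity checks are junction-centric (frame, anchors, stops); V-region
  frameshifts upstream of the junction are not separately diagnosed.
- Light chains are sort metadata only; light-chain rearrangements are not
  sequenced or analyzed.
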