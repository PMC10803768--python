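# Methods

## The marker model

A single piggyBac-family insertion is modelled as a fixed, single-copy,
neutrally decaying locus. The observable unit is one strain's
element-plus-flank sequence: 5' genomic flank, a TTAA target-site
duplication (TSD), the decayed element, the second TSD copy, 3' genomic
flank. Three integrity signals are annotated:

- **TSD status.** The 4-mers immediately flanking the element footprint.
  `canonical_TTAA` requires both to equal TTAA; equal non-TTAA 4-mers are
  reported as `other_duplication`; anything else is `absent`. The check is
  strand-symmetric (TTAA is its own reverse complement).
- **Inverted terminal repeats.** The longest prefix whose reverse
  complement matches a suffix of equal length with at most
  `itr_max_mismatch` mismatches (default 1). `intact` means length ≥
  `itr_min_len` (default 13 nt, the piggyBac ITR length); the repeat is
  discovered from the sequence, not hard-coded.
- **Reading-frame status.** Within the transposase ORF window (default
  nts 329–2113 of the reference, 1-based inclusive), the element is
  `frameshifted` if any single indel overlapping the window has
  in-window length ≢ 0 (mod 3) or the net indel length is ≢ 0 (mod 3);
  otherwise the mutated window is reconstructed and translated, giving
  `premature_stop` or `intact`.

The element footprint inside a genomic fragment is found by semi-global
alignment of the reference element (flanks free of end-gap penalties).
Excision removes the element plus exactly one TSD copy and concatenates
the flanks — reconstructing the pre-insertion locus — and is exactly
invertible.

## Alignment and mutation catalogues

Pairwise global alignment is Needleman–Wunsch with affine gaps
(match +5, mismatch −4, gap open −10, gap extend −0.5; a length-L gap
costs `open + extend·(L−1)`). The engine is Bio.Align.PairwiseAligner,
whose canonical first traceback makes outputs byte-reproducible; scores
are verified in the test suite against an exhaustive three-state
dynamic-programming oracle.

An alignment is reduced to a `MutationCatalog`: maximal gap runs become
single deletion/insertion events, mismatching gap-free columns become
substitutions, all in 1-based reference coordinates. Catalogues are exact:
applying one to the reference reconstructs the query byte-for-byte, which
is the invariant both the extraction code and the simulator are tested
against. Substitutions adjacent to indels are kept as separate events (no
merging). Percent identity is gap-excluded by default — matches over
columns where neither row is gapped, the convention of Clustal Omega's
percent-identity matrix — with a `count_gaps` flag for the
alignment-length alternative.

For multi-strain tables the pipeline either ingests a user-supplied MSA
(aligned FASTA or Clustal) or stacks the per-strain pairwise catalogues
onto reference coordinates (substitutions applied, deletions as gaps,
insertions relative to the reference dropped). This reference pivot is not
a progressive multiple alignment and every report flags it; with the
default decay regime insertions are rare and short, so the identity and
distance error introduced is well below the decision margins.

## Distances and the neutral clock

TN93 distances use the closed-form estimator with base frequencies pooled
from both sequences and pairwise deletion (columns with `-` or `N`
excluded). The two transition classes (A↔G, C↔T) and transversions are
inverted separately; any non-positive log argument raises a saturation
error rather than returning a number. The estimator collapses exactly to
Jukes–Cantor under equal frequencies with proportional classes, and is
checked against an independent numerical maximum-likelihood oracle that
never touches the closed form (matrix exponentials of the TN93 generator,
exact fit of expected to observed class proportions by Brent root finds).

Divergence time is `t = K/ν` with:

- ν = 0.0058 substitutions/site per million generations (direct
  *Drosophila melanogaster* mutation-rate estimate), so `t` comes out in
  millions of generations;
- ν CI = (0.0021, 0.0146): a *reconstruction*, back-solved so that
  K = 0.029 maps to the ~2–14 million-generation uncertainty band this
  clock is known to carry; it is a reporting device, not a measured
  quantity;
- 30 days/generation and 365.25 days/year to convert to Myr (the printed
  1-significant-figure values are insensitive to the year convention);
- `lineage_split = none` by default: the reference is treated as the
  observed ancestral state and all divergence is assigned to the
  descendant lineage. `half` splits K evenly across both lineages; the
  flag exists because either convention is defensible and the choice
  halves or doubles `t`.

## Trees

Neighbor joining is the Saitou–Nei algorithm with deterministic
tie-breaking (first row-major minimal Q pair), so identical inputs give
byte-identical trees. Negative branch lengths are clamped to zero with the
deficit moved to the sister branch, preserving path lengths through the
parent; zero-length internal edges are collapsed, so a signal-free matrix
degenerates to a star. On additive matrices the generating tree is
recovered exactly (tested).

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and labels each internal bipartition of the
full-data tree with the percentage of replicates containing it;
deterministic given the seed. Replicates whose distances saturate are
skipped and count against support.

GTR+Γ log-likelihoods are evaluated by Felsenstein pruning on a fixed
topology: eigendecomposition of the reversible generator (normalised to
one expected substitution per unit branch length), a mean-one
median-discretised Gamma mixture (defaults: 5 categories, shape 3.4437),
and gap/N cells marginalised as missing data. No heuristic topology search
is performed — the package reports the NJ topology with bootstrap support
plus its likelihood, optionally after coordinate-wise Brent optimisation
of branch lengths (tolerance 1e-6). The two-taxon case is tested against
the closed-form transition-probability product, and the likelihood is
invariant under rerooting, as it must be for a reversible model.

## The decay simulator

`simulate_decay` evolves the ancestral element along a strain tree whose
branch lengths are in generations, maintaining each lineage's state as a
reference-relative catalogue so ground truth is exact by construction.
Per branch of length *t* over *L* surviving reference sites:

- substitutions: Poisson(`sub_rate`·t·L) events, uniform target site,
  uniform new base among the three alternatives; a hit that restores the
  reference base removes the catalogue entry (back-mutation);
- indels: Poisson(`indel_rate`·t·L) events, deletion/insertion
  equiprobable, lengths geometric (p = 0.5) with an optional heavy-tail
  admixture (15% uniform 5–50 nt) motivated by the long deletions real
  decayed elements carry; deletions remove the next run of surviving
  reference sites and never re-delete; insertions anchor between
  surviving sites and are never themselves mutated afterwards. These
  simplifications keep every lineage's state a valid, non-overlapping
  catalogue — the property the whole test pyramid rests on.

Mutations on shared branches are inherited by all descendants, producing
the shared-signature structure the caller keys on. Defaults are the study
conditions: a 2472-nt ancestral element (random, with planted 13-nt ITRs
and a stop-free reading frame across the ORF window),
`sub_rate` = 5.8e-9/site/generation (= 0.0058 per million generations),
`indel_rate` = 3e-10/site/generation (about six indels along a
~10-million-generation root-to-tip path, matching the handful observed in
real decayed elements), flanks of 427 and 371 nt (the primer-delimited
analysis window, giving 802-nt concatenated insertion-site sequences).

Flanks evolve by substitution only, at `flank_rate_fraction` (default 0.1)
of the element rate, and the TSD copies are held fixed. Rationale: the
element's two deep haplotype lineages can far predate the sampled strains'
genomic coalescence at the locus, so insertion-site identity stays high
(>99%) even between element clades ~97% identical — the configuration the
caller is designed to separate. What the simulator does *not* emulate:
selection, multi-copy element families, horizontal re-invasion,
recombination within the locus, indels in the flanks, and sequencing
error. Passing tests therefore demonstrate correctness of the machinery
under the stated neutral single-locus model, not robustness to those
real-data complications.

Named fixtures: `tiny` (4 strains × 200-nt element, two clades, for
fast tests), `paperlike` (13 strains + ancestor, 2472 nt, a shallow
10-strain clade and a deeper 3-strain clade whose depths were chosen to
reproduce the observed identity regime: >99.6% within clades, ~97%
between, ~94–96% to the ancestor), and `saturated` (a deterministic
transversion-saturated pair for the error path).

## The conspecificity rule

For each strain pair: `site_shared` iff the excised, concatenated flanks
align globally with identity ≥ `flank_id_min` (the operational stand-in
for "the same primers amplify the same locus", which is not computable);
`conspecific` iff additionally element identity ≥ `element_id_min` and the
shared-signature fraction ≥ `signature_frac_min`; `divergent_lineage` iff
the site is shared but an identity test fails; `heterospecific_site` iff
the element exists but the flanks do not align; `not_detected` iff a
strain has no element record. The shared-signature fraction divides the
intersection of catalogue event sets by the size of the *smaller*
catalogue, making it robust to recent private mutations in the
more-derived strain.

Thresholds default to element ≥ 99.0%, flank ≥ 99.0%, signature fraction
≥ 0.9. The identity cut-offs sit in the empirically empty gap between
within-species observations (>99.5%) and between-lineage observations
(~97%); they are package policy, not measured constants, and are printed
in every report. The caller is rule-based, not inferential — there is no
test statistic and deliberately no multiple-testing correction. Verdicts
are symmetric in the pair, and tightening any threshold can only demote
verdicts (monotonicity, tested).

## Numerical and reporting conventions

All user-facing reference coordinates are 1-based inclusive; internal
string indexing is 0-based. One integer seed governs all randomness in a
run; simulator replicates derive per-replicate streams deterministically.
TSVs are written with fixed rounding (identities 4 decimals, distances 6)
so reruns are byte-identical. Problem sizes in the test suite and the
acceptance script — 100 alignment-oracle pairs, 50 TN93-oracle pairs, 100
decay replicates of a 2472-nt element, 200 bootstrap replicates on 6–14
taxa — were chosen as the smallest sets that pin each property down
statistically (e.g. the 5-million-generation recovery check uses the
analytic per-replicate SD of ~0.6 million generations, giving a standard
error of 0.06 over 100 replicates).

## Known limitations

- The reference-pivoted pseudo-MSA ignores insertions relative to the
  reference; identities between strains sharing an insertion are computed
  over reference columns only.
- TN93 assumes stationary base composition and no rate variation across
  sites in the *pairwise* distances (the Γ mixture applies only to tree
  likelihoods); saturated pairs are refused rather than extrapolated.
- The clock CI propagates only rate uncertainty, not the binomial
  sampling error of K itself.
- NJ support values are distance-based; they are not posterior
  probabilities and a full likelihood topology search is out of scope.
- With few catalogued events (very recent decay) the shared-signature
  fraction is coarse; the identity thresholds then dominate the verdict.
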