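# Methods

## Locus model and mining

The unit of detection is a polysaccharide utilization locus (PUL) anchored
on a tandem SusC/SusD gene pair. All neighborhood rules count **genes, not
base pairs**; gene coordinates are carried along but only the order index
on a contig matters.

**Anchor pairing.** A SusC call (TIGR04056) and a SusD call (PF12741,
PF12771, PF14322 or PF07980; Pfam/TIGRFAM version suffixes are stripped
before matching) form an anchor when they lie on one contig in either
order with at most `max_gap` (default 1) intervening genes, on the same
strand unless disabled. Candidate pairs are consumed greedily left to
right, closest pair first on ties, so each gene joins at most one anchor.

**Frame extension.** From each side of the anchor span the next `frame`
(default 7) genes are examined. If any carries a degradative CAZyme call
(any CAZy family except glycosyl transferases), the boundary jumps to the
farthest such gene and the scan repeats from the new edge; it stops when a
window holds no CAZyme or the contig ends. This *iterative* window is the
default because a single fixed window cannot produce long multi-enzyme
loci in which CAZymes chain outward; a `fixed` single-pass mode is
available. The final span is trimmed so each terminus is a CAZyme, SusC or
SusD gene. The implementation is checked against an independent
brute-force least-fixed-point oracle ("absorb any CAZyme within `frame`
genes of the span, repeat to convergence, then trim"), exhaustively over
every behaviour-class arrangement with up to six genes per anchor side
(all arrangements up to 14 genes — labels collapse to three behaviour
classes for this rule: CAZyme, terminus-eligible-only, inert) plus a
seeded random sweep of 15-gene arrangements. The enumeration bound is a
pragmatic choice: the raw five-letter alphabet at 15 genes (~10⁹ cases)
adds no behaviour not covered by the class collapse.

**Screen filter and merging.** Loci lacking GH26 (subfamilies count) are
dropped; the screen can alternatively be applied at assembly scope. Loci
whose spans intersect are merged into one locus with all anchors retained
and the merge recorded in provenance.

## Annotation

Domain hits follow the dbCAN parser semantics: e-value strictly below
1e-5 when the alignment exceeds 80 residues (1e-3 otherwise), profile
coverage strictly above 0.30, and per-protein overlap resolution (shared
envelope > 50 % of the shorter alignment) keeping the lower e-value. The
filter is idempotent. CAZy-family calls additionally require a
sequence-search hit with e-value ≤ 1e-20, query coverage ≥ 40 % and
identity ≥ 30 %. All "threshold of", "minimum" and "at least" wordings are
read inclusively: exact boundary values pass, one ulp beyond fails; this
is pinned by tests at `numpy.nextafter` resolution. Confirmation by
default demands **family agreement** between the HMM and search evidence;
a protein-level mode (any passing hit confirms all of a protein's calls)
and an HMM-only mode are provided. Tightening any confirmation threshold
can only remove calls, and confirmed-mode calls are always a subset of
HMM-only calls.

## Comparative layer

"Same modularity" is family-set equality after collapsing CAZy subfamily
labels (GH5_26 → GH5), ignoring multiplicity; extra families disqualify.
A superset mode relaxes this to containment. Co-occurrence fractions use
an inclusive ≥ 5 % retention screen. MAG repertoire matching ignores
genetic context entirely: `minimal` requires ≥ 1 SusC, ≥ 1 SusD and ≥ 1
GH26 anywhere in the genome; `full` requires every reference family.
Synteny maps pair genes by reciprocal best hit at e-value ≤ 1e-5, ties
broken by (e-value, subject id); the order score is the longest common
subsequence fraction of the matched pairs, computed by longest-increasing-
subsequence over target indices in reference order.

## Proteomics

%riBAQ divides each sample by its summed non-missing iBAQ and multiplies
by 100, so every sample's observed values sum to exactly 100 (to 1e-9
relative tolerance in tests); missing values stay missing. The detection
rule keeps proteins observed in at least 2 replicates of at least one
condition.

Testing operates on log2(%riBAQ) with missing values excluded pairwise (a
raw-scale mode exists). Welch's t statistic and Welch–Satterthwaite
degrees of freedom are computed per protein and cross-checked against
scipy's implementation in tests; both groups having zero variance and
equal means gives t = 0 by convention.

**Permutation FDR.** The null is built from distinct group-label
assignments of the samples, excluding the identity assignment and, for
balanced designs, its complement (which yields identical |t|); 3 vs 3
therefore gives 18 assignments, enumerated exhaustively whenever no more
than `n_perm` (default 250) exist, otherwise sampled with the run's seed.
Null statistics are pooled across proteins. For each candidate cutoff c
(the observed statistics), FDR(c) = [(1 + total pooled null statistics
≥ c) / (number of permutations + 1)] / max(1, number of observed
statistics ≥ c); the reported significant set is the largest one with
FDR ≤ α. The +1 terms are the Phipson–Smyth permutation correction: a
permutation estimate is never exactly zero, which removes the plug-in
estimator's anti-conservatism at the extreme observed statistics (without
it, the single largest observed statistic is declared significant whenever
it merely exceeds every pooled null value, inflating the realized
false-discovery proportion on all-null data well above the nominal level).

The ranking statistic defaults to the SAM-style moderated
|x̄_A − x̄_B| / (se + s₀) with s₀ equal to the median of the per-protein
standard errors. With n = 3 per group, per-protein variance estimates are
unstable enough that a few tiny-variance null proteins otherwise dominate
the pooled |t| null and destroy power at any useful α — the moderation
constant is precisely the fudge factor the SAM/Perseus procedure
introduces for this reason. s₀ = 0 (or `statistic="t"`) recovers the
unmoderated ranking. The null-control check measures the realized
false-discovery proportion over 200 seeded all-null repetitions against
the nominal level plus three Monte-Carlo standard errors; with the +1
correction it sits well below 0.05.

Fold-changes are ratios of raw-scale condition means of %riBAQ against a
reference condition; a zero denominator is reported as infinite with a
flag, and only ratios > 1 are marked positive.

## Arrays

Replicate spots are averaged per (extract, probe, treatment); cells with
fewer than two spots are flagged and excluded. Normalization scopes one
"dataset" as one treatment sub-heatmap (configurable to global) and
computes value/max × 100, which makes the dataset maximum exactly 100 in
floating point and the result invariant to any positive rescaling of the
raw signals. Deletion scores compare a treatment to the buffer control on
the same extract/probe cell: 100 × (1 − treated/control), floored at 0
with the raw ratio preserved; a zero control is undefined and flagged.
Because each treatment sub-heatmap is normalized by its own maximum,
untargeted cells can show ratios ≠ 1 when the dataset maxima differ; in
noise-free data with a shared maximum cell, scores equal the planted
deletion depths exactly.

## Synthetic data

The genome generator plants loci with the reference architecture
(GH26, GH130, regulator, SusC, SusD, GH26, GH26, GH5, GH27, transporter,
CE2 — regulator/transporter genes carry no annotation) and three decoy
kinds: a lone SusC/D pair with no CAZyme within seven genes, a CAZyme run
without an anchor, and a GT-only cluster around a SusC/D pair. Blocks are
separated by at least eight unannotated genes so planted features never
interact; coordinates sit on a fixed 1 kb grid. Hit tables encode the
intended pass/fail outcome of every generated hit (spurious hits may pass
the HMM stage but lack or fail search confirmation), with
`near_threshold_fraction` of scores placed within one decade of the
relevant threshold; a self-consistency checker verifies fields against
intent. Proteome intensities are lognormal around a per-protein baseline
(log10 baseline ~ N(7, 1)) with multiplicative noise of coefficient of
variation `cv`, effects multiplying the first condition, and uniform
at-random missingness — deliberately simpler than real data, which has
intensity-dependent missingness and correlated proteins; tests passing on
this model demonstrate procedural correctness, not real-data performance.
Array base signals are uniform on [20, 100] per (extract, probe) with
multiplicative lognormal replicate noise.

Default study-like sizes: three conditions × 3 replicates, 8-fold planted
effects on 22 of 1000 proteins at cv = 0.2; arrays with ≥ 2 spots per
cell. All generators are driven by `numpy.random.default_rng` seeds and
are byte-reproducible.

## Problem sizes and numerical choices

The acceptance script uses 100 two-contig genomes for recovery, ~1.2
million exhaustive arrangements plus 3000 random 15-gene cases for the
extension oracle, 200 all-null and 50 planted-effect proteome repetitions
(1000 proteins each), and 10 noise-free array datasets — sizes chosen so
the whole run completes in well under a minute per block on one CPU while
keeping Monte-Carlo error small relative to the margins tested.
Deterministic tie-breaks appear wherever order matters: anchor candidates
by (left index, gap), overlap resolution by (e-value, profile name),
best hits by (e-value, subject id). Degenerate inputs raise: all-zero
riBAQ samples, all-zero array datasets, unplaceable genome features
(capacity), unresolvable protein ids, and fewer than two distinct label
permutations.

## Known limitations

- Gene neighborhoods are modeled on order indices only; base-pair
  distances, operon structure and regulator binding sites are out of scope.
- The synthetic proteome's missingness is independent of intensity, so
  detection-filter behavior under censoring-type missingness is untested.
- The permutation FDR pools null statistics across proteins and assumes
  exchangeability under label permutation; strong variance heterogeneity
  between proteins is handled by s₀ moderation, not modeled explicitly.
- Sequence content is not simulated; search hits carry synthetic scores
  consistent with intent, not alignments.
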