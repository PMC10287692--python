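# Methods

This note records the models, defaults, numerical choices and known
limitations behind each analysis stage. All thresholds named here are keys in
`svscape.config.DEFAULTS` and can be overridden per run; the pipeline writes
the resolved mapping to `thresholds.json` alongside its outputs.

## Purity-adjusted SVAF

The SVAF estimates the fraction of tumor cells carrying a rearranged allele.
The raw supporting-read fraction `vaf = Rsv/(Rsv+Rref)` is diluted by normal
contamination and distorted by the local copy-number state, so it is rescaled
by purity and corrected in two regimes defined on the purity-adjusted copy
number `acn = 1 + (cnr - 1)/purity`:

* `acn < 0.75` (`loh_acn_max`): the locus has lost one allele; the tumor
  contributes roughly half the usual allele mass, giving
  `SVAF = (vaf/p)(2-p)/2`.
* `acn > 1.25` (`amp_acn_min`) with `vaf/p >= 0.60` (`amp_base_min`): the SV
  junction sits on an amplified allele; `SVAF = (vaf/p) * acn/(acn-0.5) / 2`
  deflates the read excess contributed by the amplified copies.
* otherwise `SVAF = vaf/p`.

Of the two breakpoints the one whose `acn` is closer to 1 is used (ties go to
the lower-coordinate breakpoint), reads are taken at that breakpoint, and an
SVAF is reported only when it carries at least 10 reads
(`min_breakpoint_reads`). Values are capped at 1, since SVAF is used as a
fraction against thresholds such as 0.4. A breakpoint outside every
copy-number segment is treated as copy-neutral.

Two properties of this map worth knowing:

* it is *not* globally monotone in `Rsv`: the amplification correction only
  switches on once `vaf/p` reaches 0.60, and the corrected value at the
  switch point is smaller than the uncorrected one, so the map steps down
  across that regime boundary. Within each regime it is monotone; the
  property tests check exactly that.
* the linear-scale adjustment `1 + (cnr-1)/purity` is the only purity
  adjustment used anywhere (the same form centers the 0.75/1.25 thresholds at
  the diploid level 1).

## Clustered regions and the 80-category classification

A sample's rearrangement breakpoints (both ends of every SV) are clustered
where their local density is at least 10-fold the sample's genome average
(`cluster_density_factor`). Operationally: maximal runs of consecutive
intra-chromosomal breakpoints whose gaps are all at most (mean
inter-breakpoint gap)/10, kept at `min_cluster_size >= 3` breakpoints. This
run-merging rule is deterministic and is verified exactly against a
brute-force oracle; it deliberately avoids piecewise-constant fitting, whose
parameters would be additional unstated degrees of freedom. The minimum
cluster size is a package choice (the smallest count that distinguishes a
cluster from a single SV's two ends plus a neighbor).

Categories combine base class (DEL/DUP/INV x six size bins, plus TRA and
TRANSPOSITION), clustered status, and chromatin state, for 80 labels in a
fixed, documented column order. Size bins are half-open with exact powers
assigned upward (a 1,000 bp event is "1–10 kb"). A translocation becomes a
transposition when either breakpoint lies within 1.0 kb
(`l1_transposition_dist`) of a LINE-1 element. Clustered and chromatin status
use either-breakpoint semantics: an SV is counted once, in the category its
first qualifying breakpoint supports, rather than fractionally.

## Signature extraction and rank selection

The samples x 80 catalog (samples with fewer than 10 SVs excluded) is
factorized by NMF under the Kullback–Leibler objective with multiplicative
updates — the convention of the mutational-signature literature — run to
convergence (`nmf_tol = 1e-6`, `nmf_max_iter = 5000`) from 100 random
restarts per candidate rank (`nmf_restarts`). Restart protocol: the pooled
L1-normalized restart signatures are clustered (k-means on unit vectors) and
the mean cosine silhouette of that clustering is the rank's *stability*;
cluster centroids are the consensus profiles, and exposures are refit against
them by non-negative least squares.

Rank selection was left open by the source method, so the package defines it:
among ranks whose reconstruction error does not exceed that of any smaller
rank, choose the most stable one (ties to the smaller rank). Restart
stability peaks sharply at the planted rank in simulation, while
reconstruction error keeps creeping down past it; a stability floor
(`rank_stability_min = 0.8`) is retained as a config key for diagnostics. At
rank 1 the silhouette is undefined and only the error curve is reported.

Subtypes come from consensus clustering of L1-normalized exposures: 1,000
resamplings (`consensus_resamplings`) of 80% of samples
(`consensus_subsample`), each clustered hierarchically with cosine distance
and Ward linkage applied to unsquared distances (the "ward.D2" convention).
The number of subtypes is chosen where the relative change in the area under
the consensus CDF drops most sharply — the point where adding a cluster stops
improving consensus; the final assignment cuts a Ward tree built on
(1 − consensus). A cohort with no pairwise structure (all exposures
identical) short-circuits to a single subtype at the minimum k.

## SV clusters and mechanism classes

SVCs are built by union-find over breakpoint–region incidence: every SV with
a breakpoint in a clustered region joins that region's cluster, and any SV
whose two breakpoints fall in different regions — a translocation or a large
intra-chromosomal junction — merges them into one SVC with multiple
footprints. (The merge must include intra-chromosomal bridges: an assembled
amplicon's junction connects two clustered regions megabases apart on the
same chromosome.)

An *amplified segment* is a maximal run of copy-number segments with adjusted
CN above 4.0 (`amp_mean_cn`) entered and exited through boundary steps above
1.5 (`amp_boundary_delta`); a chromosome end counts as a satisfied boundary.

A *fold-back inversion* must (1) lack an opposite-orientation partner with
both breakpoints within 5 kb (`foldback_reciprocal_window`), (2) show a
significant copy-number change at a breakpoint, and (3) span under 30 kb
(`foldback_max_span`). Criterion 2 is a two-sample comparison of 10 flanking
5 kb read-depth bins per side with Benjamini–Hochberg adjustment across all
candidate inversions (q < 0.01) when per-bin depth is supplied; without
depth, a segment-based fallback requires |dACN| > 0.5 at a breakpoint
(`foldback_dcn_min`). The q-value semantics of the original criterion were
not fully specified; this operationalization is the package's own.

Classification evaluates rules in fixed precedence — CFS-like, L1
transposition, NAHRD, BFBC, self-joining amplicon, assembled amplicon — and
the first match wins; mechanism classes precede amplicon classes, mirroring
the two-pass description of the source method. Key operational choices:

* *stepwise* copy-number change means at least 2 successive same-sign steps
  of magnitude > 0.2 (`stepwise_min_steps`, `cn_drop_min`) across ordered
  member breakpoints; a cluster can be stepwise in both directions (a
  deletion pileup descends into and ascends out of its valley), so the
  CFS rule tests the descending flag specifically;
* duplication *spacer* overlap is measured against 90%
  (`spacer_overlap_frac`) of the shorter spacer; a *nested pair* requires
  strict containment with the outer duplication at higher SVAF;
* "high-SVAF" membership means the top 30% (`top_svaf_frac`) of the SVC by
  SVAF (at least one member);
* junction breakpoints match footprint/amplified-segment boundaries within
  50 kb (`amplicon_boundary_tol`); assembled amplicons require the matched
  segments to be distinct and separated by more than 2 Mb
  (`assembled_min_gap`) or to lie on different chromosomes;
* the L1 rule requires the clustered-side translocation breakpoints of more
  than half the members to fall inside one footprint within a 500 bp window
  (`l1_concentration_window`) and within 0.1 kb (`l1_svc_dist`) of a LINE-1
  element.

A *reintegration* SV — the trace of an ecDNA amplicon re-entering a
chromosome — has exactly one breakpoint in a self-joining/assembled SVC
footprint, its other breakpoint outside every clustered region with
|dACN| < 0.5 (`reintegration_dcn_max`) across it, and spans over 2 Mb
(`reintegration_min_span`) or is a translocation.

## Hotspots

Tandem duplications and inversions are counted in 500 kb windows advancing
450 kb (`hotspot_window`, `hotspot_step`; adjacent windows share 50 kb); an
SV counts in every window containing either breakpoint, and chromosomes
shorter than a window get a single whole-chromosome window. Calling requires:

1. SV-positive cases in more than 5% of the cohort (`hotspot_case_frac`);
2. no overlap with the common-fragile-site track, and not transposon-driven
   (a window is dropped when more than half of its SV-positive cases carry
   only LINE-1-proximal translocations — an operational rule mirroring the
   L1 SVC definition);
3. at least five cases (`hotspot_min_high_cases`) with an SV of SVAF > 0.4
   (`hotspot_high_svaf`);
4. higher length-weighted mean adjusted CN over the window in SV-positive
   than SV-negative cases: one-sided Mann–Whitney U with BH FDR < 0.05
   (`hotspot_fdr`) across the windows passing conditions 1–3. The test and
   level are the package's choice (robust to non-normal CN ratios; multiple
   testing handled explicitly). The comparison universe is every profiled
   sample, including SV-free ones.

Overlapping passing windows merge into one hotspot. A hotspot is *singular*
when some sub-interval is covered by the per-case SV footprints of at least
70% (`singular_share_frac`) of its positive cases (sweep-line maximum over
footprint endpoints) and the median per-case SV count is at most 2
(`singular_max_median_sv`); otherwise *multiple*.

Note that condition 4 is not a pure null filter: a random tandem duplication
genuinely elevates the copy number of its own window for its own sample, so
wherever conditions 1–3 pass by chance, condition 4 has real signal. The
specificity of the caller therefore depends on conditions 1–3 being
demanding relative to the cohort's per-window breakpoint density, as they are
at realistic densities.

## Association testing

Each subtype is compared one-vs-rest per feature — the only design that
yields one p-value per subtype x feature cell — with two-sided Welch's t for
continuous features and two-sided Fisher's exact for categorical ones.
Samples can be excluded per feature (hypermutators are the canonical case
for mutation counts). P-values are reported raw by default, matching the
usual presentation of such tables; BH adjustment is available. The summary
retains rows with p <= alpha (0.05, inclusive at the boundary) with
direction arrows. A continuous feature with no variance anywhere reports
p = 1.

## Synthetic cohorts

The generator emulates the *tables* such a study consumes, not reads: on a
miniature genome (three 50 Mb chromosomes) it draws purity ~ U(0.3, 0.95),
exposures ~ Dirichlet(0.6), per-sample SV counts ~ negative binomial
(mean 80, size 5 in the standard cohort), and SV categories from the
exposure-weighted mixture of six sparse, near-orthogonal planted profiles
(small deletions; small duplications; large active-chromatin duplications;
large deletions; translocation/transposition; clustered super-large SVs).
Placement respects the category: sizes are log-uniform within the bin,
clustered categories gather around reserved per-sample cluster seeds,
chromatin-dependent categories are placed inside/outside a periodic active
track covering 17% of the genome, and transpositions anchor at LINE-1
elements. Deletions and duplications perturb a per-sample copy-number
profile (clamped at adjusted CN 0.25); archetype and hotspot loci override
it with their planted levels; the emitted segments are that piecewise
profile re-attenuated to the raw scale via `cnr = 1 + (acn-1)*purity`.

Read counts follow the SVAF model in reverse: the planted true SVAF is
pushed backwards through the regime map given local `acn` and purity to an
expected `vaf` (capped at 0.97, with the realized truth recorded), depth is
Poisson(80), and supporting reads are Binomial(depth, vaf). Applying the
forward SVAF computation to noiseless expected counts recovers the truth to
numerical precision in all three regimes.

SVC archetypes are constructed to satisfy their class rules with margin —
e.g. BFBC is four same-orientation 12 kb inversions whose left breakpoints
sit exactly on an adjusted-CN staircase 1 -> 4.5 -> 6 -> 7.5; an assembled
amplicon is two CN-8 segments 3 Mb apart joined by a 0.92-SVAF junction with
low-SVAF internal and connecting SVs. Planted loci, per-sample cluster
seeds and translocation far-ends are reserved through a block allocator with
generous margins so that unrelated planted structures cannot chain into one
detected cluster; that separation is what makes per-archetype truth labels
meaningful. CFS-like archetype loci are added to the synthetic fragile-site
track.

Two preset cohorts exist beside the standard one. The *archetype* cohort
(one archetype of each class per sample, sparse uniform-ish background)
keeps each sample's genome-average breakpoint density low so archetype loci
are unambiguously clustered. The *hotspot* cohorts (planted and null) use a
uniform non-clustered background profile (type mix DEL 0.45 / DUP 0.23 /
INV 0.17 / TRA 0.15, chromatin 17:83) at 5 SVs per sample, the density at
which the expected number of chance high-SVAF co-occurrences per 500 kb
window is far below the calling conditions — the property that makes a
cohort without planted hotspots a true null for the caller (see the note on
condition 4 above).

What the generator does *not* emulate: sequence context and microhomology at
junctions, mappability structure, caller-specific artifacts, subclonal
copy-number mixtures, or correlated noise between read depth and purity.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the pipeline's logic under its own generative assumptions,
not calling performance on real sequencing data.

## Problem sizes used in tests and the acceptance script

Signature recovery uses 60-sample catalogs at 200 SVs/sample with planted
rank cycling 4/5/6 over 10 replicates, rank range 2–7 and 30 NMF restarts
per rank; subtype recovery uses 90 samples from three separated Dirichlet
components with the default 1,000 consensus resamplings; SVC classification
uses 40 archetypes per class (240 clusters); hotspot studies use 100-sample
cohorts with three planted loci of 12 cases each, and five independent null
cohorts. These sizes keep a full run around one minute on a single CPU while
leaving comfortable statistical margin on every recovery criterion.

## Known limitations

* Classification precedence resolves rule overlaps deterministically but
  greedily; a cluster satisfying two mechanism rules is reported only under
  the first.
* The L1-concentration window is checked per footprint side; a transposition
  cluster whose source element splits across two adjacent regions may be
  missed.
* Hotspot condition 2's "active transposon" exclusion is an operational rule
  (the source text names no procedure), and condition 4's test/level are
  likewise package choices.
* The SVAF amplification guard introduces a discontinuity (see above); SVAFs
  just below and above `vaf/p = 0.6` at amplified loci are not comparable at
  fine resolution.
* The generator's truth category for an SV reflects its intended placement;
  detection-side category assignments can differ near region boundaries, so
  category-level comparisons between truth and detection are correlational,
  not exact.
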