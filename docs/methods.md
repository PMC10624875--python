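# Methods

`cryomethyl` reimplements, as a tested pipeline over synthetic data, the
downstream analysis of a paired sperm-cryopreservation RRBS experiment:
12 males, each assayed fresh and after freezing with three cryoprotectants
(DMSO, methanol, glycerol), compared per cytosine for differential DNA
methylation. This note records the models, the defaults and their
justification, and the places where the design was genuinely open.

## Coordinate and counting conventions

Internal coordinates are 1-based and strand-resolved, the convention of
Bismark cytosine reports; BED/bedGraph export converts to 0-based half-open
at the boundary. A CG dinucleotide exposes one assayable cytosine per
strand, and both are kept as distinct sites throughout — the genomic
denominator for representation percentages is therefore **twice** the number
of CG dinucleotides in the reference. The redundancy is deliberate: whether
cryopreservation alters a CpG symmetrically on both strands is exactly the
kind of question that collapsing the strands would erase. Methylation
percent columns in input files are never trusted; the ratio is always
recomputed from the two counts.

Records from the strand-less 6-column coverage dialect get strand "." unless
a reference FASTA is supplied for resolution; such records are kept in all
analyses as distinct sites but excluded from strand-specific invariants.

## The paired differential test

The experiment's pairing is within male: a cytosine enters the comparison of
one male only if it was read (depth >= 1) in both that male's fresh and
treated sample. No information is borrowed from neighbouring cytosines — at
these methylomes almost every site is fully methylated or fully
unmethylated, so smoothing would add bias, not power. Sites paired in at
least 6 of 12 males are tested.

The test is a self-contained paired Wald test on the arcsine-square-root
(variance-stabilizing) scale. Per male *m*, with counts (k, n):

    p̂ = (k + 0.5) / (n + 1),   y = arcsin(√p̂)
    d_m = y_treated − y_fresh
    v_m = 1/(4(n_t + 1)) + 1/(4(n_f + 1))

and the site-level statistic pools males by inverse variance:

    D = Σ(d_m/v_m) / Σ(1/v_m),   z = D·√Σ(1/v_m),   p = 2Φ(−|z|)

The +0.5/+1 pseudocounts keep the transform and its variance finite at
ratios 0 and 1 even at depth 1, which the depth >= 1 inclusion rule makes
common. Monte Carlo calibration (10⁴ null sites, depths 10–40, 12 males,
intermediate ratios) puts the rejection rate at α = 0.001 inside the
binomial 99% band, and the p-values rank-correlate > 0.9 with an exact
sign-flip permutation test at 6 males. On the strongly bimodal null
(ratios 0/1) the test is conservative — most sites give d_m = 0 exactly and
p = 1 — which is why calibration is measured on intermediate ratios.

DMCs are sites with p < 0.001 (strict), the only threshold the study
design prints; no multiplicity correction is applied by default (an optional
Benjamini–Hochberg mode exists). A DMC is hyper- or hypomethylated when
strictly more than half of the males possessing the site move in that
direction (zero deltas count toward neither); otherwise unclassified. The
majority denominator is the informative males, not the full cohort — a male
without the site has no trend to contribute.

## Regions

Two definitions, deliberately different in stringency:

* **DMR** — a sliding window of at least 50 bases anchored at each tested
  CpG, holding >= 5 tested CpGs of which >= 75% are DMCs. Overlapping
  qualifying windows merge; the merged span is reported with its CpG/DMC
  counts. On sparse toy data this rule rarely fires, as in the emulated
  study.
* **Potentially sensitive region** — >= 2 DMCs whose consecutive spacing is
  <= 100 bp (the read length), chained transitively (single linkage). The
  pairwise phrasing of the rule is extended to its transitive closure, the
  natural maximal clustering; regions are tagged "sensitive to" each
  cryoprotectant contributing >= 2 DMCs.

Annotation builds strand-aware feature intervals per gene — promoter
(5 kb upstream of the TSS), first exon, other exons, first intron, other
introns, 1 kb downstream of the TES — and labels a region with **every**
feature it overlaps, from every overlapping gene, with no precedence;
"intergenic" only when nothing overlaps. Promoter/downstream windows are
clipped at chromosome edges.

## Quality correlation

"DMC number per male" is not uniquely defined for cohort-level DMCs; the
default reconstruction counts the called DMCs at which the male is
informative and shows a nonzero delta (alternatives: all informative, or
direction-concordant only). Correlation is Spearman with midranks and a
two-sided permutation p: exhaustive over all n! pairings for n <= 8, seeded
Monte Carlo (20,000 draws, observed pairing included) otherwise — full
enumeration at n = 12 (4.8 × 10⁸ pairings) is not worth its cost next to a
20k-draw estimate whose standard error at p ≈ 0.05 is ~0.0015. Constant
vectors (e.g. fertilization after glycerol, identically zero) are flagged
degenerate rather than dropped.

## The synthetic world

The generator emulates the statistical structure the analysis assumes, not
sequencing mechanics (no reads, no alignment, no quality errors).

* **Genome** — uniform-random A/C/G/T chromosomes scrubbed of spontaneous
  CCGG, with CCGG motifs planted as a Poisson process (default 4/kb), so the
  MspI site count has a known distribution; background CpGs (~1/16 per
  dinucleotide) supply the assayable sites. In-silico digestion cuts C^CGG
  and size selection keeps 40–220 b fragments; only cytosines on retained
  fragments are observable.
* **Methylation truth** — per CpG dinucleotide (shared by both strands,
  males and conditions): fully methylated with probability 0.86, fully
  unmethylated 0.12, otherwise intermediate ~ U(0.05, 0.95); analytic mean
  87.0%, matching a strongly bimodal, highly methylated sperm methylome.
* **Counts** — depth ~ negative binomial (mean 30, dispersion 4) with a
  per-sample mean factor ~ U(0.65, 1.35) so sample median depths span the
  high-teens to ~40; methylated calls ~ Binomial(depth, r′) with
  r′ = r + (1 − r)(1 − 0.996): an unmethylated cytosine that escapes
  bisulfite conversion reads as methylated. Over-conversion of methylated
  cytosines is 0 by default (configurable) — only the conversion rate of
  unmethylated cytosines is characterized in the emulated protocol.
* **Partial representation** — per-sample site presence uses a propensity
  shared across all 48 samples: each dinucleotide draws a keep probability
  from a two-component Beta mixture (48% "well-sequenced", mean 0.88,
  concentration 15; the rest poor, mean ≈ 0.05), overall mean 0.45. This
  reproduces two facts of the emulated data at once: per-sample
  representation is about half the per-condition union (the dropout ratio),
  and the distinct paired cytosines concentrate in many males (~88% shared
  by >= 6 of 12, mode at 8–10) — independent per-sample dropout cannot do
  both. The absolute representation percentages cannot match a real
  vertebrate genome: a uniform-random toy genome is far denser in CpGs and
  MspI sites, so the ratio, not the absolute level, is the emulated
  quantity.
* **Injected DMCs** — per cryoprotectant, 300 observable sites by default
  shift their true ratio by ±0.5 (clipped to [0, 1]) in a random
  ⌈0.75 × 12⌉ = 9-male subset. The direction is random at intermediate
  baselines but forced away from saturation (baseline 1 → hypo, 0 → hyper):
  a hyper shift at ratio 1 would clip to nothing and record an untestable
  truth. Injection is restricted to sites with capture propensity >= 0.7 so
  every recorded truth is discoverable by the >= 6-male analysis. Because
  86% of baselines sit at ratio 1, injected DMCs are predominantly
  hypomethylations — a property of the stated bimodal world, not a bug.
* **Quality table** — per-male percentages drawn around condition means that
  encode the cellular-response hierarchy (membrane/mitochondria:
  DMSO >= glycerol >= MeOH; motility/fertilization: DMSO > MeOH >
  glycerol = 0), independently of the methylation truth, so quality–DMC
  correlations are null by construction.

Randomness fans out from one seed into named substreams (genome, propensity,
truth, counts, genes, quality), so regenerating one stage never perturbs the
others and fixture sets are byte-identical across runs with equal seeds.

### What a green test does and does not establish

The generator has no fragment-level depth correlation, no neighbour
correlation in methylation state beyond strand symmetry, no PCR duplicates,
no mapping artifacts, and quality values with no real link to methylation.
Green tests therefore establish that the pipeline computes its statistics
correctly and recovers known effects of the stated size under the stated
noise — not that the emulated study's biological findings would replicate.
In particular, at toy scale the injected-DMC density (~300 in ~15k tested
sites) is orders of magnitude higher than in a real methylome, so the
injected hypomethylation is visible even in the global mean; the real
study's contrast (hundreds of DMCs, no global shift) lives at a site count
no desk-scale simulation reproduces.

## Numerical choices

* Histogram bins are left-closed, 20 × 0.05, with [0.95, 1.00] closed so
  ratio-1 cytosines land in the top class.
* PCA is complete-case (sites with data in every included sample), centered
  per site, by SVD; component signs are fixed by making the
  largest-magnitude loading positive. Imputation-free intersection is the
  only reading consistent with comparing samples "at every sequenced
  cytosine".
* Global means are unweighted means of per-cytosine ratios over depth >= 10
  records — the cytosine, not the read, is the analysis unit; the depth
  filter is exposed as a flag since the original filter for the global
  averages is not documented.
* Even-count medians are the mean of the central pair.
* Kruskal–Wallis (midranks) with Mann–Whitney pairwise follow-up; all-equal
  degenerate input returns p = 1 rather than an error.

## Known limitations

* The paired Wald test approximates the beta-binomial paired machinery of
  dispersion-shrinkage DMC callers with a pseudocounted arcsine transform;
  it matches an exact permutation test in rank but is not the original
  implementation.
* Whether the original analysis collapsed strand-less records, imputed the
  PCA matrix, or used 12 or the informative males as the majority-rule
  denominator is not documented; this package's choices (keep ".", 
  intersect, informative males) are recorded here and configurable where
  sensible.
* Sensitive-region chaining is transitive; a strictly pairwise reading
  would split some long chains.
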