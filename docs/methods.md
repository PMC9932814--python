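# Methods

## The mapping model

The panel consists of ~26 recombinant-inbred strains, each homozygous for a
mosaic of two parental genomes, genotyped at markers with known genetic (cM)
and physical (Mb) positions.  The trait is a per-strain mean over replicate
retinas (cells/retina).  At every marker the strain means y are fit by
weighted least squares against the haplotype indicator x ∈ {0 (B), 1 (A)}:

- null model: y = μ + ε,
- full model: y = μ + βx + ε,
- LOD = (n/2)·log₁₀(RSS₀/RSS₁), n = strains with a non-missing call.

With equal weights and complete genotypes this reduces exactly to
−(n/2)·log₁₀(1−r²) with r the Pearson correlation of indicator and strain
means; the implementation is verified against that closed form to 1e-9 and
against an independent weighted-least-squares route (statsmodels).

**Weights.** Within-strain variability is carried into the fit as
w = 1/SEM².  Strains with a single replicate (no SEM) receive the median
panel weight.  Inverse-variance weighting is a documented standard choice;
the exact weighting used by the original mapping service is not published,
so the printed LOD values of the source study are a parameter regime here,
not a bit-exact target.

**Effect convention.** The reported additive effect is the full
homozygous-class difference mean(A) − mean(B) (positive ⇒ A raises the
trait), not the half-difference convention, because RI panels contain only
the two homozygous classes.

**Numerical guards.** Monomorphic markers get LOD 0 with a `monomorphic`
flag; a perfect fit (RSS₁ < 1e-12·RSS₀) is capped at (n/2)·12 with a
`separation` flag rather than reported as infinite, preserving peak
ranking.  Peak ties are broken toward the lowest Mb position.  U (missing)
calls drop a strain at that marker only.

## Permutation thresholds

Each of the (default) 2,000 permutations shuffles the (mean, weight) pairs
jointly across strain labels and rescans every marker; the genome-wide
maximum LOD is recorded.  The suggestive threshold is the 33rd percentile of
the maxima (genome-wide p < 0.67) and the significant threshold the 95th
(p < 0.05), both under the "higher" empirical-quantile rule so thresholds
are attained values.  With 2,000 permutations the Monte-Carlo scatter of the
significant threshold between seeds is typically below 0.1 LOD on a
26-strain, 200-marker null panel; the suite asserts < 0.15.

## Composite interval mapping

Control-marker indicators enter both the null and full designs (solved by
least squares on the √w-scaled design, tolerant of collinearity), so the
LOD at each position measures linkage of the residual variation after the
controlled QTLs are absorbed.  Positions within 10 cM of a same-chromosome
control marker are flagged `near-covariate` but never dropped, so the
controlled chromosome remains inspectable.  An empty control list reduces
exactly to the simple scan.

## Support intervals

For a chromosome, threshold = peak LOD − drop (default 1.5).  Runs of
markers at or above the threshold become sub-intervals; boundaries are
linearly interpolated in Mb between the two markers straddling each
crossing and clamped to the first/last scanned position.  Sub-intervals
closer than `merge_gap_Mb` (default 10; chosen because a single-strain
recombination event producing a ~5 Mb dip should not split one locus) are
merged, with `merged_from` recording the count.  Intervals whose peak falls
below a supplied suggestive threshold are flagged `sub-threshold`, never
suppressed.

## Variant prioritization

Rules are pure functions of annotated records (consequence terms, domain
flags, TSS distance, conservation, microRNA-site flags are consumed as
inputs; no sequence analysis is performed):

- F1 frameshift / stop gained / stop lost;
- F2 missense with a side-chain-group change or inside an annotated
  domain/membrane-spanning region.  Groups: nonpolar {A,V,L,I,M,F,W,P},
  polar {S,T,N,Q,Y,C}, positive {K,R,H}, negative {D,E}, special {G}; any
  cross-group change (special ↔ anything included) counts;
- F3 in-frame indel inside a domain;
- F4 any splice_region/donor/acceptor consequence;
- R1 SNP/INDEL within 500 bp (unsigned) of a TSS or in a 5′/3′ UTR, **and**
  inside an evolutionarily conserved region.  The conjunctive reading is
  the default; `ecr_mode="or"` preserves the alternative reading in which
  promoter/UTR location alone suffices;
- R2 structural variant anywhere within a gene, inside an ECR;
- R3 3′UTR variant disrupting or creating a predicted microRNA site
  (treated as sufficient on its own).

An ECR means the 100-bp window centred on the variant (±50 bp) intersects a
conserved interval in ≥2 distinct species' tracks (BED, 0-based half-open).
Gene ranking assigns each gene a Venn region over {≥1 high-priority
variant, retinal/AII expression, relevant function}; top candidates meet
all three and are sub-ranked by variant count, then gene id.

## Expression, eQTL, qPCR

Expression values are log₂-normalized (one unit = one doubling), with
values above 7 considered above background.  Expression–trait association
is a Pearson correlation over strains shared pairwise (never imputed).
The eQTL scan feeds probe values through the same scan engine with unit
weights (array values carry no replicate SEMs); a cis-eQTL is called when
the genome-wide peak lies on the probed gene's chromosome within 10 Mb of
the gene and clears the suggestive threshold.  The 10 Mb window is a
deliberate, generous default for a panel whose mapping resolution is
coarse; it is configurable.

qPCR quantities assume perfect doubling (efficiency 2.0, no correction):
quantity = 2^−Cq averaged over triplicates, normalized by the geometric
mean of the two reference genes, which makes the result invariant to a
common plate Cq offset.  The truncated/full transcript ratio is a plain
quotient of two normalized quantities.

## Reporter assays

Luciferase: technical repeats are averaged per channel, firefly/Renilla per
well, and each pathway-stimulated well is folded over the mean ratio of the
unstimulated wells of the same plate *and* condition (plates hold different
cell passages, so normalization never crosses plates).  "Abnormally low
Renilla" has no published numeric rule, so a k-fold-below-plate-median flag
(k = 10, configurable) is provided as an explicit advisory proxy —
flag-then-decide, never silent exclusion.  The ACL fraction is
100·ΣACL/Σ(ONL + outer INL + ACL) over sections, depending only on sums.

## The synthetic panel

`SimConfig` defaults are the study conditions: 26 strains; five chromosomes
including 9, 11 and 19; markers every 5 cM; three additive QTLs with
class-mean differences 11,139 (Chr 9, A high), 13,585 (Chr 19, A high) and
13,252 cells (Chr 11, B high); baseline 67,000 cells; between-strain
residual SD 2,000 cells (a small polygenic background standing in for the
"other loci of smaller effect"); within-strain CV 0.05; 4 replicates per
strain.  Genotypes follow a founder draw (P(A) = ½) plus a first-order
switch process with the sib-mating RI map expansion R = 4r/(1+6r) (Haldane
r), rather than a breeding-forward simulation — this matches RI-panel
theory at a fraction of the cost and is validated against the analytic
expected-breakpoint count.  QTL positions snap to the nearest marker so
planted and mapped positions are commensurable; replicate noise is
proportional (CV-based).

**What the generator does and does not emulate.**  It reproduces the
additive genetic architecture, allele frequencies, RI linkage structure,
and within/between-strain variance structure; it does not model
segregation distortion, strain non-independence from shared breeding
history, genotyping error, or non-additive (epistatic/parent-of-origin)
effects — the F1 heterosis seen in the real panel is outside the additive
model by construction.  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to those departures.

**Heritability under the defaults.**  The three planted class-mean
differences alone contribute genetic SD ≈ 11,000 cells while CV-scale
replicate noise contributes ≈ 3,350, so realized replicate-level h² on the
default panel sits around 0.83–0.95 — above the 0.74 reported for the real
panel.  This is expected: published marker-regression effect estimates from
a 26-strain panel are upward-biased (the Beavis effect), so planting them
as generative truth overstates the genetic variance.  The defaults
deliberately keep the published effect sizes rather than deflating them to
hit a target h².

Heritability is estimated by one-way random-effects components with
unweighted expected mean squares, the harmonic-mean replicate count for
unbalanced panels, and a negative between-strain component truncated at 0,
so h² ∈ [0, 1]; it is invariant to affine transformation of the trait.

## Problem sizes in the test-suite and acceptance script

The suite validates statistical behavior at sizes chosen to make the checks
sharp yet quick: 200 random small panels for the closed-form identity,
2 × 2,000 permutations on a 200-marker null panel, 100 single-QTL panels of
100 strains for parameter recovery, 50 two-QTL panels for composite-mapping
behavior, 1,000 random traces for interval geometry, and a ≥200-case
cross-product for the rule table.  The acceptance script mirrors these
sizes and completes in seconds.

## Known limitations

- Scan positions are genotyped markers only (no pseudomarker imputation);
  peaks are reported at markers, as RI panels are densely genotyped
  relative to their resolution.
- No multi-QTL model selection, epistasis scans, or kinship correction —
  a 26-strain RI panel does not support them.
- Annotation provenance (consequences, domains, conservation, microRNA
  sites) is external; the classifier audits rules, it does not predict
  biology.
- GeneNetwork accessions (phenotype 10179, expression GN210/GN302) are
  supported only as locally exported files; nothing is fetched.
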