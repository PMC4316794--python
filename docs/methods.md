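# Methods

## The problem

A draft plant genome usually arrives as scaffolds: contigs ordered and
joined across N-gaps, but not assigned to chromosomes. Anchoring turns
scaffolds into chromosome-scale pseudomolecules by mapping genetic
markers that are (a) placed on scaffolds by sequence position and (b)
placed on chromosomes by linkage analysis of a segregating population.
This package implements that workflow for an F2 intercross genotyped at a
targeted codominant SNP panel, in the configuration used for the melon
genome: markers deliberately concentrated at scaffold extremes so that
anchored scaffolds can also be oriented, a ~140-individual population,
LOD-10 grouping into 12 linkage groups, chimeric-scaffold correction, and
a Marey-map recombination landscape whose suppressed regions co-localize
with centromeric satellite arrays.

## Two-point estimation

For two codominant loci with known phase, an F2 individual is the fusion
of two independent gametes; a gamete is parental with probability
(1 − r)/2 per type and recombinant with probability r/2. The nine
genotype classes then have probabilities that depend on the data only
through four sufficient statistics: double parental homozygotes
((1 − r)²/4 each), opposite homozygotes (r²/4), single-heterozygote
classes (r(1 − r)/2), and the double heterozygote, which sums its two
phase configurations to ((1 − r)² + r²)/2. The MLE of r is computed by
EM — the double-heterozygote class contributes 2r²/((1 − r)² + r²)
expected recombinant gametes — run as vectorized array updates over all
marker pairs simultaneously (one-hot matrix products give all pairwise
class counts). The EM estimate agrees with a 0.0005-step grid search of
the same likelihood to well within 0.001 (checked over 200 simulated
pairs per run). LOD is the base-10 likelihood ratio against r = ½;
individuals missing at either locus are excluded; pairs with fewer than
10 informative individuals are flagged unreliable.

## Grouping, binning, ordering

Linkage groups are connected components of the marker graph with edges at
LOD ≥ 10 (networkx). Within a group, individuals missing >10% of the
group's genotypes are pruned and pairwise fractions re-estimated.

Markers separated by fewer than 3 observed recombination events in the
whole population (r̂ · 2n < 3, single linkage) collapse into
*cosegregation bins* mapped at a single position. This is the map's
effective resolution: at n = 139 with a realistic ~0.1% genotyping-error
rate, smaller separations are dominated by error-induced phantom events,
and ordering such markers individually produces arbitrary order and
spurious cumulative distance — most visibly across
recombination-suppressed regions, where dozens of markers genuinely
cosegregate. Classical mapping software makes the same choice by
assigning cosegregating loci one position. `bin_max_events` is
configurable; `None` orders every marker individually.

Bins are ordered to minimize the sum of adjacent recombination fractions:
greedy insertion seeded by the most distant pair, then 2-opt segment
reversals to a local optimum; the output direction is canonicalized and
either direction is considered correct downstream. Positions accumulate
Haldane distances by default (d = −50 ln(1 − 2r)), consistent with the
simulator's no-interference meiosis; Kosambi is available. Adjacent
r ≥ 0.5 is capped at 50 cM with a warning.

## Anchoring, orientation, chimeras

A scaffold inherits the linkage group of its mapped markers. When a
second group intrudes: a single stray marker against ≥3
recombination-separated majority markers is dropped (a mapping/placement
artifact); two genuine blocks (≥2 markers each) make the scaffold a
chimera candidate, with the boundary interval between the blocks in
scaffold coordinates. The split point is the N-gap whose midpoint lies
nearest the boundary midpoint — misjoins happen at assembly joins, which
are bridged by N-tracks — falling back, flagged, to the boundary midpoint
when no gap exists. Children (`<parent>_split1/2`) replace the parent;
total bases are conserved and the assembly version gains a patch level.

Orientation is the sign of the Spearman correlation between marker bp and
cM. Two guards produce "?" instead: fewer than two distinct cM values,
or fewer than 2 *directly observed* recombination events between the
scaffold's outermost markers. The second guard exists because cumulative
map positions drift apart inside suppressed regions without any real
recombination separating the markers, which would otherwise turn
orientation there into a coin flip; requiring direct two-point evidence
mirrors the conservatism of map-based anchoring practice (the original
melon anchoring likewise left dozens of suppressed-region scaffolds
unoriented). A prior-anchoring table may supply orientations for "?"
scaffolds (provenance recorded; marker evidence always wins when both
exist).

Scaffolds order within a group by median marker cM (robust to a retained
slightly-off marker); ties break by mean cM — which sorts scaffolds
straddling a suppression-region edge toward the correct side — then prior
assembly order, descending length, id. Unanchored scaffolds concatenate
into chromosome zero by descending length. Components join with 1,000-N
spacers; AGP v2.0 uses W rows for components and U/1000/scaffold/yes/map
for spacers; "?" scaffolds are written with orientation "?" and used in
forward sense. Feature lift-over is exact coordinate arithmetic: forward
components shift by the offset; reverse components mirror
(p′ = L − p + 1) and flip strand; 1-based inclusive throughout.

## Recombination landscape

Marey maps plot each marker's genetic position against its physical
position on the pseudomolecule. Duplicate positions collapse to mean cM;
isotonic regression enforces monotonicity; points deviating >2 cM from
the pooled trend are dropped one at a time (worst first, re-pooling after
each) — such points are local ordering noise, e.g. a scaffold placed at
an arbitrary position within a suppression region where anchor positions
are tied. The cumulative curve is a monotone cubic (PCHIP) interpolant;
the local rate at window center c is (S(c + w/2) − S(c − w/2))/w with
w = 1 Mb, step 0.1 Mb, clamped at zero. A GCV-smoothed cubic spline is
available (`method="spline"`), but at ~45 markers per chromosome it
rounds the sharp arm/plateau transition so strongly that plateau rates
can exceed the suppression threshold; since the window difference already
smooths at the 1-Mb scale, the interpolating monotone cubic is the
default. Average rates are plain ratios: per chromosome, map length over
physical Mb; genome-wide, the totals' ratio (equivalently the
length-weighted mean). Suppression zones are maximal runs of windows
below 0.5 cM/Mb spanning ≥2 Mb between outer window edges.

## Centromeres and rDNA

Satellite alignment hits pass at identity ≥ 0.80 and coverage ≥ 0.80
(inclusive, per "80% or more"). Hits cluster per pseudomolecule by single
linkage with a 500-kb maximum gap; a cluster is a centromere call iff it
contains ≥2 distinct centromeric families (pSat107, CentSpA/B/C), with a
stricter mode requiring pSat107 specifically (`require_psat107`; off by
default, since either reading of "pSat107 and any of CentSp" is
defensible). 18S/5.8S/26S rRNA annotations within 100 kb merge into 45S
(NOR) intervals; 5S separately. The overlap report gives, per call and
rDNA locus, the best-overlapping suppression zone with bp overlap and
Jaccard index.

## The simulator

The generator manufactures the study's conditions, scaled down
physically but not genetically:

* **Genome**: 12 chromosomes of ~8 Mb (vs ~30 Mb real — sequence volume
  is irrelevant to the tested logic and this keeps a full run near 10 s),
  each with a piecewise-linear monotone Marey curve: ~95 cM per
  chromosome (so crossover counts per meiosis match the real mapping
  regime at n = 139), a 3.2-Mb centromeric plateau at 0.05 cM/Mb, and
  slightly asymmetric arm slopes. The plateau occupies 40% of the
  chromosome; proportionally, real melon suppression regions are as large
  or larger (one documented zone spans ~16 Mb of a ~25 Mb chromosome). A
  plateau much below ~3 Mb cannot express a 2-Mb suppression zone once
  scaffold-end marker gaps and the 1-Mb window are taken into account.
* **Repeats**: each centromere carries pSat107 plus 1–2 CentSp families,
  interleaved family-by-family across dense core slots with a
  pSat107/CentSp pair abutting the exact midpoint — the families
  genuinely co-localize, survive the uncertain scaffold order inside
  suppression regions, and flank the midpoint. 45S components
  (18S/5.8S/26S) sit pericentromerically on two chromosomes, a 5S array
  on another; decoy hits (low identity, or isolated single-family arm
  arrays) exercise the filters. Sequences are random nucleotides with
  tandem repeat monomers planted at array positions; realized lazily.
* **Scaffolds**: lognormal lengths (mean 0.5 Mb) tile each chromosome;
  half are assembled in reverse orientation; contigs of ~350 kb meet at
  100-N gaps placed with small jitter. Chimeras splice two
  similar-length (ratio ≥ 0.92) scaffolds from different chromosomes
  across a 1,000-N junction; similar lengths put the junction near the
  marker-block boundary midpoint, which is what makes the documented
  nearest-midpoint cut rule identify the true junction gap.
* **Cross**: 139 F2 individuals; per gamete and chromosome a
  Poisson(map length in Morgans) crossover count with uniform cM
  placement (Haldane, no interference). Segregation distortion is
  viability selection by rejection sampling at two loci skewed against
  one homozygote (echoing the SC-allele skew observed on two linkage
  groups in the real cross) — strong enough to flag (p < 0.05), not to
  trigger the p < 10⁻⁴ removal. Genotyping error 0.1% (array genotyping
  with curated clusters), missingness 3%, per-marker cluster-quality
  scores with a small contaminated fraction for the QC thresholds to
  catch.
* **Panel**: candidate variants every ~15 kb with a quality mixture,
  Poisson(22) depth, occasional planted flank violations; per-scaffold
  targeted selection by the size schedule, topped up to the 580-SNP panel
  from the largest scaffolds — interior positions for ≥2 Mb scaffolds
  (large internal marker gaps blur the Marey map; the real study suffered
  multi-Mb gaps inside its largest scaffolds), extra end-window markers
  otherwise.

What the simulator does **not** model: realistic sequence evolution or
composition, read-level data, crossover interference, assay-failure
chemistry (validation percentages for the real panel are recomputed from
the published counts, not simulated), and real repeat homology (hit
tables are generated from truth, not by alignment). Passing tests
therefore demonstrate the correctness and robustness of the analysis
logic under the study's statistical conditions — not performance on raw
sequencing artifacts.

## Numerical choices

EM tolerance 1e-10 (≤600 iterations), with exact snapping to r = 0 when
no recombinant classes are observed; likelihood terms use 0·log 0 = 0.
The chi-square p-value uses the scipy survival function, which equals the
df = 2 closed form exp(−χ²/2) to machine precision (asserted to 1e-12 in
tests). Ordering ties break deterministically (designability, then
position, then id in selection; lexicographic markers elsewhere), so a
config + seed pair reproduces every artifact bit for bit; the run
manifest records the SHA-256 of every output. Problem sizes in the test
suite (3-chromosome worlds for unit tests, one full-scale run plus a
20-seed mapping sweep for the end-to-end checks) were chosen to keep the
suite in a few minutes while leaving every statistical check
well-powered.

## Known limitations

* Marker order *within* a cosegregation bin is unrecoverable by design;
  order-concordance is accordingly measured over the map's distinct
  positions.
* Scaffolds anchored entirely inside a suppression plateau have tied
  anchor positions; their relative order on the pseudomolecule is
  arbitrary (the real study reported the same uncertainty), which is why
  the Marey fitter tolerates and trims locally discordant points.
* The two-group chimera logic handles the single-misjoin case the study
  corrected; scaffolds hitting ≥3 groups fall back to
  majority-assignment with the rest dropped and flagged.
* Percentage columns are computed against the synthetic assembly total;
  the published percentages depend on an assembly denominator the
  original table never printed exactly and are not recomputed.
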