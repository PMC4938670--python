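# Methods

`salmap` rebuilds, at desk scale, the analysis chain behind a
high-density sex-specific SNP linkage map for a pedigreed salmonid
population: genotype quality control, two-point linkage mapping with
separate male and female distances, integration of the genetic map with
a physical assembly (marker placement, contig anchoring, discordance
flagging), a windowed recombination landscape folded by distance to the
nearest telomere, and positional/coding variant-effect annotation.
Because the original genotypes are not redistributable, every stage is
exercised on synthetic data with generation-time truth; this note
records the models, the estimation choices, and what the synthetic
results do and do not demonstrate.

## Synthetic study generator

**Genome.** Random A/C/G/T chromosomes (default 5 x ~20 Mb).  A
configurable fraction of sequence (default 22%) is excised into
"unplaced contig" records; the excised spans are N-masked in the
chromosome records so that placed and unplaced sequence are disjoint,
coordinates stay stable, and exact flank matches are unique.  The carve
target accounts for the N-masked double counting so that
unplaced/total matches the requested fraction.

**Recombination landscapes.** Piecewise-constant crossover intensity
(cM/Mb) per chromosome and sex.  The female track is flat; the male
track has interior rate 1 cM/Mb (default) elevated 10-fold over the
outer 10% of the chromosome at each end ("subtelomeric" zone; no
centromeres are modelled, so the fraction is taken per chromosome end).
Unless set explicitly, the female rate is derived so the female:male
total genetic length is exactly the configured ratio (default 1.5).
Crossovers are a Poisson process on the genetic axis (count ~ Poisson of
the Morgan length; positions by inverting the cumulative map) — no
interference, consistent with the Haldane map function used downstream.

**Pedigree and genotypes.** Nuclear families with shared sires (default
10 sires / 20 dams / 8 offspring per family, round-robin sire
assignment).  Founder haplotypes are drawn from per-marker allele
frequencies (MAF uniform on a configurable range, default 0.05–0.5,
with the alt allele randomly the minor or major one); offspring
genotypes arise from simulated meioses under the sex-specific
landscapes.  Markers sit uniformly at random on chromosome coordinates;
a marker falling inside an excised span belongs to that contig (flank
read from the contig record) while its inheritance is still simulated at
the true chromosomal position — this is what makes contig anchoring
testable.  Genotyping error is a symmetric state flip at rate 0.5% per
call (default) applied to founders and offspring alike; 1% of calls are
set missing.  Flanks are exact 71-mers centred on the SNP site; markers
whose flank would cross a sequence end or an N are resampled.

**Gene models.** Non-overlapping genes (1–4 exons, 1–3 transcript
variants) whose exonic sequence is rewritten in place so the spliced
canonical transcript carries exactly one longest ORF (ATG, 100–220
sense codons, stop).  Stop codons are planted in all three frames at the
3' end of the 5'UTR so no upstream start reads through, and a brute-force
longest-ORF scan at generation time verifies uniqueness (regenerating
the codons otherwise).  Transcript variants are UTR truncations sharing
the CDS; expression values are lognormal.  Truth effect labels are
computed by an independent brute-force path (per-base feature painting
plus full mutant-CDS translation through Biopython) and serve as the
oracle for the annotation pipeline.

**What the generator does not emulate:** linkage disequilibrium between
founders, allele-frequency ascertainment beyond the MAF range,
per-marker or per-individual error-rate heterogeneity, crossover
interference, genotype-calling artifacts correlated with sequence
context, and assembly errors other than the ones the discordance tests
engineer.  Passing recovery tests therefore shows the estimators are
consistent under the stated generative model, not that they are robust
to every artifact of real array data.

## Genotype QC

Trio Mendelian checks use the 27-state legality table (a trio counts as
checked iff all three calls are non-missing).  Individuals are filtered
before markers at the same >1% threshold (offspring are dropped
individually; a parent above threshold removes its nuclear families so
the pedigree stays resolvable), then marker rates are recomputed and
markers above threshold dropped.  MAF < 0.05 (computed over all
non-missing calls; strict inequality) and segregation distortion at
p < 0.001 follow, the latter as family-wise chi-square goodness-of-fit
(1:1 for backcross-type, 1:2:1 for intercross-type matings) summed over
families with summed degrees of freedom.

## Two-point linkage model

For one marker pair and one nuclear family the likelihood conditions on
the parental genotypes, sums over the phase configurations of each
doubly-heterozygous parent with equal priors, and treats offspring
meioses as conditionally independent given phase.  Transmission follows
the standard two-locus model: a parent passes a parental haplotype with
probability (1-θ)/2 and a recombinant one with θ/2.  An optional
genotype-emission error rate ε makes each observed genotype a mixture of
the true genotype (1-ε) and the other two states (ε/2 each).

Estimation choices that the implementation settled on, and why:

* **Joint sex-specific estimation.** θ_male and θ_female are maximised
  jointly by coordinate ascent (grid argmax per coordinate, initialised
  at the pooled estimate).  Conditioning the other sex at θ = 0.5 is
  misspecified in families where both parents are doubly heterozygous —
  their transmissions are entangled through the offspring genotypes —
  and in simulation it deflated θ by 30–50%.  Only families whose
  that-sex parent is observed doubly heterozygous inform the estimate.
* **Parent-mistype marginalisation.** Adjacent-pair likelihoods
  marginalise over the observed parental genotype class and its eight
  Hamming-1 neighbours, weighted by ε: a single mistyped founder call
  (true homozygote read as heterozygote) otherwise converts half of a
  deep family into apparent recombinants.  Candidate classes never
  *recruit* families — informativeness is judged on the observed class.
* **Residual error rate.** ε is estimated by single-locus maximum
  likelihood pooled over every (family, marker) cell, with the same
  emission model and parent-mistype marginalisation.  Profiling ε inside
  the two-point likelihoods is nearly flat (each pair's free θ absorbs
  the signal); the single-locus fit pools on the order of 10^6 trio
  checks and resolves ε to ~1e-4.  The estimate is taken **before** QC:
  the Mendelian filters select on visible (trio-inconsistent) errors
  while leaving the silent, recombination-mimicking error rate of the
  retained calls unchanged, so a post-QC fit underestimates exactly the
  component that matters for map inflation.  There is no multipoint
  error correction anywhere.
* **LOD screening.** All-pairs LODs for clustering are evaluated on a
  fixed θ grid (dense near 0), vectorised by grouping (pair, family)
  combinations into parental mating-type classes; θ-free families cancel
  in the LOD and are skipped.  Within linkage groups the grid is refined
  (0.0025 near 0) before ordering, since neighbour spacings sit below
  the screening resolution.

Clustering is single-linkage transitive closure at a LOD threshold; the
threshold is chosen by the plateau criterion — the widest run of
thresholds giving a constant non-singleton group count (singletons are
not counted as groups; at high thresholds weakly informative markers
drop out individually rather than fragmenting groups).  Leftover singles
join the group holding their best-LOD partner if it clears the join
limit (default: half the cluster threshold) and beats the second-best
group by ≥1 LOD.  Ordering minimises total sex-averaged map length
(greedy nearest-neighbour from random restarts, refined by 2-opt segment
reversals and single-marker reinsertion; per-restart lengths are kept so
order consistency can be assessed; orientation is normalised so the
smallest marker id sits in the first half).  Sex-specific cM tracks
re-estimate adjacent-pair θ on the fixed order and accumulate Haldane
distances d = −50·ln(1−2θ) (Kosambi available behind a flag); pairs with
no informative meioses for a sex contribute 0 cM with a flag, and
θ ≥ 0.5 caps the increment at 50 cM with a flag.

## Physical integration

Placement is exact full-length matching of the 71-bp flank with the SNP
base wildcarded, on both strands of every record — the dependency-free
equivalent of keeping only complete, exact alignment hits.  A 12-bp
2-bit-packed seed immediately 5' of the SNP screens candidate positions
in one vectorised pass per record; candidates are verified by full
comparison.  Multi-hit markers keep the hit on their linkage-derived
chromosome (majority vote of uniquely placed markers maps linkage groups
to chromosomes) when exactly one hit lies there, else stay unresolved
and are excluded from positional statistics.  Unplaced contigs anchor to
the chromosome whose linkage group claims a strict plurality of the
contig's placed markers (default minimum support 1).  Discordance is the
complement of the longest monotone subsequence of genetic order along
physical position; maximal runs of ≥3 discordant markers become flagged
segments.  Marey correlations are Pearson |r| between cM and bp
(Spearman behind a flag), undefined below 3 co-placed markers.

## Windowed landscape

Each chromosome is tiled into 50 windows of 2% physical length; the
window rate is (cM at end − cM at start)/(Mb span) from a
piecewise-linear Marey interpolation with constant extrapolation beyond
the terminal markers.  The genetic axis of each Marey map is
re-estimated along the concordant markers in physical order
(`marey_tracks`) rather than read off the cumulative map: markers
excluded as discordant would otherwise leak their out-and-back map
inflation into local rates.  A window is *defined* when ≥90% of its span
lies inside the mapped marker span — partially covered windows report
rates diluted by the zero-rate extrapolation zone.  Folding maps window
k to distance bin min(k, 51−k); bin means are unweighted over defined
windows across chromosomes, per sex; undefined windows are excluded
rather than zero-filled.  The male subtelomeric fold statistic divides
the mean rate over bins inside the configured subtelomeric fraction
(outer 10% → bins 1–5) by the mean over the innermost five bins.

## Variant annotation

Per gene, the most highly expressed transcript is canonical (ties: the
longest predicted ORF, then lexicographic id).  Its ORF is the longest
ATG-initiated, stop-terminated reading frame with ≥100 codons before the
stop on the spliced sequence, ties to the 5'-most start; genes without a
qualifying ORF are treated as non-coding.  Categories are assigned by
precedence CDS > UTR > splice region (intronic bases within 8 bp of a
junction) > intron > intergenic, relative to the canonical transcript;
positions outside it are intergenic.  Codon effects use the standard
genetic code, strand-aware: a changed start codon or a gained/lost stop
is `start_stop_change`, otherwise amino-acid change decides
synonymous/nonsynonymous.  SNPs on unanchored contigs are classified but
flagged off-chromosome and excluded from per-chromosome tables.

## Run designs and what they showed

The numbers below are produced by the test suite and
`scripts/acceptance.py`; sizes were chosen for statistical power, since
chained two-point interval estimation needs far more informative meioses
per interval than the multipoint analyses such maps are usually built
with.

* **Karyotype recovery:** 29 chromosomes x ~3 Mb, 60 markers per
  chromosome, the default 10/20/8 pedigree.  The plateau criterion
  recovers 29 non-singleton groups matching the true chromosome
  partition.
* **Landscape recovery:** chromosomes of 20 Mb under the default
  heterochiasmic landscape, ~0.4 Mb marker spacing, deep shared-sire
  pedigrees (28 sires / 60 dams / 90–100 offspring per family), MAF
  0.3–0.5.  The acceptance script averages the folded-profile statistic
  over five replicates of 8 chromosomes each; the recovered male
  subtelomeric fold averages ≈9 against the configured 10 (the residual
  shortfall is interpolation bleed across the subtelomere boundary plus
  the small positive truncation bias of near-zero interior intervals;
  single-replicate spread is ≈±1.5, driven by occasional error clusters
  in interior intervals).  The female:male map-length ratio lands within
  10% of the configured 1.5 once markers are dense enough to capture the
  male-rich chromosome ends (the ratio check runs at 600 markers over
  5 chromosomes).

Known limitations: per-sex totals remain sensitive to the balance of
end-capture loss (male-biased, because male cM concentrates
subtelomerically) against truncation noise in near-zero intervals;
two-point ordering cannot resolve marker order below the per-interval
noise scale, so fine-scale order is partly arbitrary even when group
assignment and the landscape are recovered; and all recovery statements
are conditional on the generator's homogeneous error model.
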