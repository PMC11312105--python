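# Methods

## The gene-depth statistic

The central quantity is the marker-normalized gene depth

GeneDepth = Σ_{q∈Q} RPKM_q / Σ_{c∈C} RPKM_c,

with Q the set of contigs carrying the gene of interest, C the set of
contigs carrying *rpsB*, and RPKM_i = reads_i·10⁹/(length_i·N_mapped).
Q and C are *sets of contigs*, not genes: a contig carrying both the gene
and the marker contributes to both sums, and a contig carrying two copies
of the same gene still counts once. Under the assumptions that (i) every
genome carries exactly one *rpsB* copy and (ii) expected per-contig RPKM is
proportional to the genome's relative abundance (true for uniform read
sampling regardless of contig length, since length cancels in RPKM), the
expectation of the ratio is the abundance-weighted mean copy number of the
gene per genome. The statistic is invariant to overall sequencing effort
(scaling every read count by k cancels), which is why only the marker
denominator — not the per-million scaler — matters for cross-sample
comparability.

Degenerate inputs are explicit: an empty Q yields 0.0 (an absent gene is a
reportable result, as for pathway arrows drawn dashed when no gene was
found), while an empty or zero-RPKM C raises — the statistic is undefined
without its denominator. The marker's own gene depth is exactly 1.0 by
construction, which the tests assert as an identity, not an approximation.

jgi-style depth tables carry mean per-base depth, not read counts; counts
are reconstructed as round(depth·length/read_length) with read_length
defaulting to 150 (paired-end 150 bp sequencing). An explicit read-count
table, when available, takes precedence. Both the mapped-read and
cleaned-read "per million" scalers are representable through the sample
metadata; the default uses mapped reads.

## MAG depth

MAGRawDepth is the plain sum of member-contig mean depths, implemented
literally; it is therefore sensitive to how finely a MAG is fragmented
(two 5 kb contigs at 10× contribute 20, one 10 kb contig contributes 10).
A `length_weighted=True` alternative computes the length-weighted mean
member depth instead. MAGDepth divides by MAG size in bp and by sample
read pairs in millions. The absolute scale of MAGDepth is convention-bound
(bp × millions); only ratios across MAGs and samples are interpreted, and
within-sample relative abundances are reported alongside.

## Catalog and complex rules

The nitrogen-gene catalog ships as an editable TSV (gene symbol, KEGG KO,
enzyme complex, subunit role, process). All logic keys on gene symbol so a
KO revision never touches code. Processes are the seven canonical ones plus
two auxiliary categories ("marker", "organic_nitrogen_utilization" for
glnA/gltBD/gdhA) so that the categories partition the catalog exactly.
Multi-subunit membrane complexes NarGHI and NorBC are scored only when
every subunit is present (the both-subunit convention); all other enzymes
count on any subunit, with the catalytic subunit (napA, nirB, nrfA, nasA,
nirA) carrying the signal in practice. Hits labeled nxrA/nxrB are relabeled
narG/narH before any counting, because nitrite oxidoreductase and
membrane-bound nitrate reductase are homologs sharing the same KOs and
cannot be separated by annotation alone.

Enzyme "type groups" for co-occurrence counting are configurable schemes:
nitrate reductases {Nar, Nap, Nas}, ammonium-forming/assimilatory nitrite
reductases {NirBD, Nrf, NirA}, and the NO-forming denitrifier pair
{NirK, NirS}. Whether "three types of nitrite reductase" should include
NirK/NirS is left to the scheme choice rather than hard-coded.

## Threshold semantics

All retention and presence thresholds follow the printed inequality
directions exactly: quality retention is completeness ≥ 50 **and**
contamination < 10 (tree inclusion: ≥ 70 and < 7); taxon-level presence is
carrier fraction **strictly** > 0.25 **or** a carrier **strictly** > 90%
complete. The high-quality clause additionally requires the carrier to pass
the contamination ceiling, since only retained MAGs exist downstream. The
boundary grid (completeness ∈ {49.9, 50, 69.9, 70, 90, 90.1} ×
contamination ∈ {6.9, 7, 9.9, 10}) is asserted exhaustively in the tests.
Report percentages round half-up at the printed precision (Python's
banker's rounding would flip exact-half cases).

## ANI species clustering

Pairwise ANI triples are symmetrized by the maximum of the two directions
(conservative toward merging at a fixed threshold, and deterministic); the
diagonal is 100. The clustering algorithm behind published species counts
is generally unstated when only pairwise values are released, so the
default is greedy best-quality-first representative clustering: seeds
ordered by completeness − 5×contamination (ties by MAG id), each MAG joins
the first representative at ANI ≥ threshold (default 95%), else founds a
cluster. This matches common dereplication practice, is deterministic, and
is permutation-invariant by construction. Single-linkage components are
available behind `method="single"` (it merges chains the greedy form
splits).

## The simulator

The generator emulates the statistical structure the estimators assume,
not sequence content: no reads, no assembly graph, no real ANI from
alignments.

- **Abundances**: per-sample lognormal draws (σ = 1.0 by default),
  renormalized. A dominance switch pins one designated genus at an exact
  community share per sample, emulating the 17–80% single-genus dominance
  regime observed in the lake samples; it defaults to off because the
  simulator's primary role is the recovery oracle, and the dominance regime
  is a scenario to opt into (the analysis drivers use 0.5).
- **Gene content**: carriage is drawn per enzyme complex (so subunits
  co-occur) from a prevalence table qualitatively mirroring an oligotrophic
  saline lake — nitrite reduction, fixation and assimilatory nitrate
  reduction common; nitrification and anammox rare; vnf/anf absent so their
  absence is reportable. Carried genes get 1 + Poisson(0.2) copies; *rpsB*
  is fixed at exactly one copy per genome.
- **Fragmentation**: contiguous non-overlapping fragments (equal 10 kb by
  default; optionally variable), with trailing fragments under the 2 kb
  assembly floor dropped together with any gene copies placed on them.
  Gene copies land at uniform offsets; the truth set counts *distinct
  contigs* per gene, which is exactly what the contig-set statistic can
  see (two copies colliding on one contig are one observable unit).
- **Coverage**: reads_c ~ Poisson(a_g · n_genomes · mean_coverage ·
  len_c / read_length), so `mean_coverage` (default 20×) is the coverage of
  a genome at the average community share. Negative-binomial overdispersion
  is available via a single gamma-mixing parameter, default off.
- **Binning**: completeness is simulated as the emitted fraction of each
  genome's contigs, contamination as misbinned-in fraction of the bin —
  crude, but monotone in the right direction, which is all the threshold
  logic needs.
- **Truth**: expected gene depth per (gene, sample) is
  Σ_g a_g·contigs_g(gene) / Σ_g a_g·contigs_g(rpsB), the abundance-weighted
  mean copy number under contig-set semantics.

What passing recovery tests therefore shows: the estimator correctly
inverts the coverage model it assumes. What they do not show: robustness to
GC/mappability coverage bias, inter-genome read mis-mapping, chimeric
contigs, or annotation error — none of which the generator produces.

## Recovery protocol and its power analysis

The recovery experiment runs 50 seeded simulations (20 genomes, 5 samples,
1 Mb genomes in equal 10 kb contigs, 20× mean coverage) and requires every
(gene, sample) pair with true value ≥ 0.35 to be estimated within 5%
relative error, in ≥ 95% of seeds. The 0.35 floor is derived, not tuned:
at these conditions a gene with abundance-weighted copy number T collects
≈ 26,667·T expected reads in its numerator, so pure Poisson counting noise
has relative σ ≈ √((1+T)/(26,667·T)) — about 2% at T = 0.1, where a 5%
band is only ~2.4σ and an all-pairs criterion would fail for a *perfect*
estimator. Requiring the 5% band to sit at ≥ 4σ gives T ≥ ~0.32; the floor
is set at 0.35. Below it, accuracy is still exercised, just at the looser
tolerances the counting noise dictates (see the coverage-doubling test).

Problem sizes throughout (genome size, contig length, sample counts,
replicate counts) are chosen so the full suite runs in seconds while
keeping every per-pair counting noise term well inside the asserted bands.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney U)
test: exact null for small untied samples, normal approximation with
continuity correction otherwise. An independent full-enumeration oracle in
the test suite checks the exact branch for every group-size pair up to 5×5.
Benjamini–Hochberg adjusted p-values are emitted alongside raw ones,
clearly labeled as a convenience — the primary report is raw p-values.
Pathway abundance defaults to the sum over member-gene depths, which
preserves the copies-per-genome reading when member genes occupy distinct
loci; max and mean are exposed and recorded in the output metadata.

## Known limitations

- The literal MAGRawDepth sum is contig-count sensitive (documented above).
- A contig carrying several copies of one gene contributes once; gene
  depth is thus a lower bound under heavy tandem duplication.
- GTDB "unknown" means an empty rank suffix; assigned-but-unnamed
  placeholder species (alphanumeric epithets) count as known in novelty
  summaries — they are assigned, just not named.
- The per-assembly scope forms Q and C within one depth table; co-assembly
  profiles across samples share one contig space by construction.
- MAG-depth *ordering* recovers true abundance ordering only for pairs
  whose abundances are resolvable above counting noise; the tests use a 5%
  separation margin.
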