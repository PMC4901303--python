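# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `baculokit`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and topology

All feature coordinates are 0-based with an explicit span (never an end
coordinate), so features wrapping the origin of a circular genome are
unambiguous: `start + span > length` means the feature continues past the
origin. Conversion to 1-based inclusive coordinates happens only in the GFF3
and GenBank layers; origin-spanning features are written to GFF3 as two
location lines joined by a shared `ID` and rejoined on read. Minus-strand
extraction returns the reverse complement of the plus-strand span, the
universal convention. `N` bases are accepted in input (real GenBank records
contain them), never produced by the simulator, and never count as a match in
palindrome or primer comparisons.

## ORF calling

An ORF is a maximal ATG-to-stop reading frame: among in-frame ATGs sharing a
stop codon, only the most upstream is reported. Calls are made on both
strands and are wrap-aware: on a circular genome, frames continue through the
origin, and an open frame longer than the genome (wrapping onto itself) is
not a complete ORF — the most upstream ATG within one genome length of the
stop wins. The protein-length threshold is ≥ 50 aa, i.e. ≥ 153 nt including
the stop codon; the alternative 150-nt convention differs by one codon once
the stop is counted, and the protein criterion governs here. Overlap
resolution is a stated deterministic rule: ORFs are kept longest-first, and a
candidate is discarded when its overlap with any kept ORF exceeds 25% of the
shorter of the two (ties break by lower start, then plus strand). Homology
evidence does not rescue discarded ORFs — the rule is pure so results are
reproducible without external databases. Naming assigns `prefix` + zero-padded
ordinals clockwise from an anchor ORF (by convention the polyhedrin gene in
NPV genomes); without an anchor, from the leftmost start.

Correctness is checked against an independently written six-frame enumeration
oracle on random circular and linear genomes, and by rotation invariance.

## Homologous-region detection

Palindromicity of a window is self-complementarity: the fraction of positions
`i` that Watson–Crick pair with position `L−1−i`. It is computed on the
window against itself, not against a fixed motif, because the hr consensus is
an output of the analysis, not an input. The scanner scores every window
start (vectorized, wrap-aware), keeps windows at or above `min_score`
(default 0.6 for 38-bp units), and resolves overlapping qualifying windows by
greedy non-maximum suppression — highest score first, ties to the leftmost
start. Plain chain-merging is wrong here for a structural reason: between two
tandem copies of a palindrome `P = L·rc(L)`, the straddling window
`rc(L)·L` is itself palindromic, so qualifying runs chain across unit
boundaries and would fuse adjacent units into one.

Units cluster by single-linkage on circular gap distance (default
`max_gap = 500` bp, `min_units = 2`); clusters are labelled `hr1..hrN`
clockwise from the origin, and each region's interval is the minimal hull of
its units, so reported hr sizes can differ from conventions that include
flanking context — comparisons should use a tolerance. The consensus is a
column-wise majority over the equal-length units (ties to the alphabetically
first base) with per-column conservation fractions.

In silico PCR requires the forward primer on the plus strand and the reverse
primer's reverse complement downstream, inward-facing, within `max_product`
(products may wrap the origin). Mismatch tolerance defaults to 0 and the 3′
terminal base must always match exactly: PCR is used here as confirmation, so
specificity is maximized. Primer tables are screened for duplicated sequences
across loci (`check_duplicate_primers`) rather than silently assuming a typo.

## Promoter motifs

The four canonical baculovirus promoter elements — late TAAG, TATA-box, CAGT
initiator, GATA — are matched as exact literals in a fixed window (default
200 bp) immediately 5′ of the start codon, on the coding strand only,
matching early/late promoter orientation logic. Degenerate motifs may be
supplied with IUPAC codes. Offsets are 1-based distances upstream of the ATG
(offset 1 = motif abutting the start codon). No PWM scoring: the published
motif conventions these screens follow are literal, and a probabilistic model
would imply precision the data do not support.

## Restriction digestion

Recognition sites and cut offsets ship as a small editable table (BamHI
G^GATCC, EcoRI G^AATTC, PstI CTGCA^G, plus a few spares); they are constants
of record. Sites are found on both strands wrap-aware; on a circular genome
`n ≥ 1` cut sites give exactly `n` fragments whose sizes sum to the genome
length (the conservation law the tests enforce). Profile comparison walks
both size lists largest-first, pairing heads whose relative error is within
`tol_frac` (default 5%) and reporting unmatched sizes on both sides.

## Orthology, uniqueness, synteny, hr proximity

Protein pairs are aligned by optimal Smith–Waterman with affine gaps
(BLOSUM62, open 11 / extend 1) via Biopython's `PairwiseAligner`; a
hand-written memoized-recursion oracle cross-checks scores in the tests.
Identity is matches over aligned columns (gap columns included).
Significance uses the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with fixed
published gapped constants (`K = 0.041`, `λ = 0.267`), `m` the query length
and `n` the summed subject-proteome length. Database-scale BLAST statistics
cannot be recomputed offline, so these constants are configuration, not
estimates. Orthology is reciprocal best hit (best by raw score; ties by
identity, then lexicographic subject name); one-way best hits stay in the
table flagged non-reciprocal. An ORF with no hit at `E ≤ 10⁻³` in any subject
genome is classified unique.

Synteny reduces shared orthologs to a signed permutation of genomic ranks
(sign = strand agreement). Maximal runs of strictly increasing rank with
positive sign are collinear blocks; strictly decreasing with negative sign,
inverted blocks. Strand sign participates so an inversion is detectable even
where order alone stays monotone. Runs of length 1 are reported separately as
singletons so the decomposition covers every shared ortholog exactly once;
blocks proper have length ≥ 2. The scan is linear in the plus-strand order,
so a block may split at the origin of a circular genome — a known limitation.

The hr-proximity statistic is the mean circular distance from each unique-ORF
midpoint to the nearest hr boundary (0 inside an hr). The null repositions
midpoints uniformly; the one-sided p-value is `(1 + #{null ≤ obs}) / (n_perm
+ 1)`, which is valid (never anti-conservative) by construction. Calibration
is verified by a KS test of null p-values against uniformity.

## Phylogeny

Per-gene protein alignments (alignment itself is an input — MAFFT or similar;
no aligner is re-implemented here) concatenate into a supermatrix with exact
partition bookkeeping; taxa missing a gene are gap-padded (policy `pad`) or
dropped (`intersect`). Distances are Poisson-corrected p-distances
`d = −ln(1 − p)` over pairwise non-gap columns, with `p` clipped at 0.999
(`d ≈ 6.9`) in degenerate cases. Neighbor joining uses the standard
Q-criterion with a stated tie rule (lexicographically smallest active-index
pair) and clamps negative branch lengths to zero. No heuristic ML topology
search (NNI/SPR), no rate heterogeneity, no MCMC: the claims this package
exercises — group placement and the sign of a constrained-placement lnL
difference — do not require one, and NJ plus likelihood evaluation keeps the
whole stack exactly testable.

Likelihoods come from Felsenstein's pruning algorithm with per-node rescaling;
gaps and unknown characters are missing data (all-ones partials). Models are
reversible with expected rate scaled to 1 substitution/site: Poisson (uniform
exchangeabilities and frequencies — the oracle-test model, since exhaustive
ancestral-state enumeration is feasible under any reversible model) and JTT,
whose exchangeabilities and frequencies ship as a static data table of the
published constants. Transition matrices use the symmetric eigendecomposition
`Π^{1/2} Q Π^{−1/2} = U Λ Uᵀ`, so `P(t) = Π^{−1/2} U e^{Λt} Uᵀ Π^{1/2}`;
likelihood is invariant to rerooting (checked to 1e-8). Branch lengths are
optimized round-robin by bounded scalar minimization per edge (accepting only
improvements, so lnL is monotone non-decreasing) until the per-sweep gain
falls below `tol`.

The constrained comparison builds the NJ backbone without the focal taxon,
reroots at a leaf outside the target group so the group's MRCA edge is well
defined (with a warning, and a root graft as fallback, if the group is not
monophyletic), grafts the focal taxon as sister to that clade, optimizes
branch lengths, and reports `(lnL_A, lnL_B, ΔlnL = lnL_B − lnL_A)`. Swapping
the groups negates ΔlnL exactly. Bootstrap supports resample columns with
replacement, re-distance and re-join, and map internal-edge bipartition
frequencies onto the full-data tree.

## The synthetic-data generator

The generator emulates a group I alphabaculovirus genome: defaults are a
120-kb circular genome, 134 ORFs of ≥ 50 aa (153–1200 nt including the stop,
both strands), seven hrs each a tandem array of 3–8 copies of one 38-bp
perfectly palindromic master unit independently mutated at `unit_divergence`
(default 10%), the four promoter motifs planted in the 200-bp windows of 12
designated ORFs, three planted sites each for BamHI/EcoRI/PstI, and 42% GC —
all chosen to mirror the genome organization these analyses assume. Every
output is a pure function of the config (including its seed).

Two design choices make exact-count assertions possible. First, an in-frame
stop codon is planted immediately 5′ of every ORF's ATG, so the planted start
is provably the maximal start for its stop. Second, the i.i.d. background is
*scrubbed*: chance ORFs above the calling threshold, chance restriction-site
occurrences and chance palindromic windows (away from planted hrs) are
destroyed by single-base edits that never touch planted truth — edits inside
planted ORFs are codon-aware (no stop creation, start/stop codons fixed), and
edits inside repeat units are a last resort that writes back into the unit's
truth sequence. The scrub iterates to a fixed point; chance qualifying
palindromic windows are common enough in 120 kb of random sequence (the
binomial tail at 38-bp/0.6 is small per window but the genome offers ~10⁵
windows) that without scrubbing, exact hr counts would not be testable.
Junctions adjacent to hr blocks get a 600-bp minimum spacing so distinct
planted loci cannot merge under the 500-bp clustering gap. The master
palindrome is drawn free of ATG/CAT triplets and of planted enzyme sites.

Derived genomes apply inversions, translocations, gene loss and gain
(coordinates validated so no op bisects a planted feature), then per-base
substitution at a stated rate that protects motif/primer footprints and keeps
planted ORFs translatable; the truth table records source coordinates, strand
flips and the op list, giving synteny and orthology a replayable oracle.

What the simulator does *not* model — and hence what passing tests do not
show about real data: no indels, no codon/amino-acid usage bias, no
transcriptional architecture beyond the planted motifs, no repeat families
other than the hr palindrome, no sequencing error or assembly artifacts.
Recovery rates measured on it are upper bounds for real genomes.

## Problem sizes used in validation

The acceptance script and test suite run at desk scale by choice: full-scale
(120-kb) genomes for annotation/hr/digestion checks; 30–40-kb genomes with
15–20 ORFs for derivation, orthology and synteny; 50 random 5-kb genomes for
the ORF oracle; protein pairs ≤ 30 aa for the alignment oracle; 5-leaf trees
with 6 sites for the likelihood oracle; 6-taxon supermatrices of 2000 sites
(50 replicates) for NJ consistency; 8-taxon, 250-site alignments (20–50
replicates) for placement-sign accuracy; 200 null datasets at 499
permutations for p-value calibration. These sizes give the statistical checks
enough replicates to be meaningful while keeping a full run to minutes.

## Known limitations

- No GTG/TTG alternative start codons; no splicing; no coding-potential
  statistics.
- Unique-ORF classification depends on the fixed Karlin–Altschul constants;
  it is a stated criterion, not a re-implementation of any particular BLAST
  pipeline's statistics.
- Synteny blocks may split at the circular origin.
- The placement comparison evaluates two constrained topologies only; it is
  not a tree search, and ΔlnL is reported without a significance test (an
  approximately unbiased or bootstrap test would be the natural extension).
- Rearrangement ops require non-wrapping segments.
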