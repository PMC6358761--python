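# Methods

This note documents the models, parameter choices, and numerical decisions
behind each pipeline stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Profile search and E-values

The family profile is a position-specific log-odds model: per column,
emission odds are `(counts + w·bg) / (total + w)` over the background with
pseudocount weight `w = 1`, reported in bits.  Columns with more than 50 %
gaps are excluded from match states, the common practice when building
profiles from partial alignments.  Scoring is Smith–Waterman local alignment
with affine gap penalties (defaults: open 4 bits, extend 1 bit).  These
penalties matter little for well-conserved domains — optimal hits on
synthetic families are gapless — but keep scores finite and comparable for
degraded matches.

Full profile-HMM machinery (forward algorithm, multi-domain envelopes) is
deliberately **not** reproduced: the survey logic needs ranking and
thresholding of the single best domain per protein, which the local
Viterbi-style score provides.  Significance uses the extreme-value behavior
of optimal local alignment scores: a Gumbel distribution is fitted by
maximum likelihood (`scipy.stats.gumbel_r.fit`) to the scores of random
background sequences (default 1000 decoys of length 300, i.i.d. from the
profile background), and `E(s) = N · P(S ≥ s)` with `N` the number of
database sequences.  The per-sequence E-value convention (best hit per
protein) matches how family surveys count candidate genes.  A degenerate
score distribution (zero variance) aborts calibration with an error
recommending more decoys.

The two-pass scheme mirrors iterative family searches: a permissive first
pass (default `E < 5`) collects hit segments re-threaded onto model
coordinates; these rebuild a species-specific profile which is recalibrated
and used for the final pass at `E < 0.01`.  "Complete domain" verification
is operationalized as model coverage ≥ 0.8 (configurable): the original
check delegated to Pfam/InterPro web lookups, which have no offline
equivalent.  The first-pass threshold is a knob, not a reproduction target —
the upstream study reports candidate counts without stating it.

Tie-breaks in the aligner are deterministic: among equal-scoring cells the
smallest sequence position, then model position, wins, and the traceback
prefers match over deletion over insertion.

## Catalog

Protein length from an ORF annotated with its stop codon is `ORF/3 − 1`.
Molecular weight uses average (not monoisotopic) residue masses plus one
water, the ExPASy convention; the mass table ships as an editable TSV.  The
isoelectric point solves `Q(pH) = 0` by bisection on pH ∈ [0, 14] to
`|Q| < 10⁻⁴`, using the Bjellqvist pKa set (N-terminus 7.5, C-terminus 3.55,
side chains D 4.05 / E 4.45 / C 9.0 / Y 10.0 / H 5.98 / K 10.0 / R 12.0),
also shipped as data.  `Q` is strictly decreasing in pH, so bisection always
converges; because the charge curve is nearly flat between well-separated
pKa values, the |Q| stopping rule can leave a few millipH of slack —
documented rather than tightened, since printed pI values carry two
decimals.  Subcellular localization is always a pass-through input column;
no predictor is bundled because the original analysis names none.

The transcribed catalog fixture carries one internal inconsistency from its
source: gene OsMSL37 prints a 1492-bp ORF against 483 aa (which implies
1452 bp), and 1492 is not divisible by 3.  The length rule flags this row;
the other 40 rows satisfy `L = ORF/3 − 1` exactly.

## Duplication, synteny, Ka/Ks

Tandem events are maximal same-chromosome clusters in which consecutive
family genes start within 200 kb (the survey's window); each cluster of ≥ 2
genes emits one event per adjacent pair.  Anchor pairs come from all-vs-all
local protein alignment (BLOSUM62, gap open −11 / extend −1, BLASTP-like),
keeping each query's top 5 non-self matches above a 60-score threshold —
comfortably above the random-protein null (median ≈ 30 for length-100
pairs) and below genuine homology.

Collinear blocks are longest chains (by anchor count, then score) of
anchors whose gene-order ranks are strictly monotone on both chromosomes —
same or inverted orientation — with rank gaps bounded by `max_gap`; chains
are extracted greedily so each anchor joins at most one block per
chromosome pair, and chains shorter than `min_anchors = 5` are discarded.
The library default `max_gap = 25` is the MCScanX setting, appropriate for
real chromosomes carrying thousands of genes.  The pipeline's synthetic
default is `max_gap = 3`: the toy genome holds ~25 genes per chromosome, so
the gap bound must scale with gene density or chance rank-adjacency of
unrelated family members produces spurious chains.  This is a property of
the method at small scale, not a tuning of the method itself.

Family pairs co-anchored in a block are segmental; pairs in tandem clusters
are tandem; tandem wins when both apply (a single local event explains the
pair more parsimoniously).

Ka/Ks is Nei–Gojobori (1986) exactly: per-codon synonymous site fractions
(changes to stop codons count as nonsynonymous), sites averaged over both
sequences, pathway-averaged difference counting for codons differing at
2–3 positions (pathways crossing a stop codon are excluded unless all do),
and Jukes–Cantor correction.  `p ≥ 3/4` is flagged saturated and capped at
the value just below the pole instead of returning NaN; `Ks = 0` flags the
ratio undefined rather than dividing.  Pairs are aligned by their protein
translations (global, BLOSUM62) with codons back-threaded and gapped codon
columns dropped — standard practice when the original aligner is unstated.
Maximum-likelihood (codeml-style) estimation is out of scope.

## Phylogeny

Distances are Poisson-corrected, `d = −ln(1 − p)`, with pairwise deletion
(p computed over mutually ungapped columns only); saturated pairs (`p = 1`)
are capped at distance 10 and flagged.  Trees are Saitou–Nei neighbor
joining with a deterministic tie-break (lexicographically smallest cluster
pair, clusters named by their smallest leaf); negative branch lengths are
clamped to zero with the deficit moved to the sister edge.  NJ is exact on
additive matrices, which the test suite verifies against randomly generated
additive trees.

The upstream study pairs "maximum likelihood" with "Poisson correction;
pairwise deletion" — settings that belong to distance methods, an
internally inconsistent combination.  This package implements the printed
parameters faithfully as Poisson-distance NJ with bootstrap; ML tree search
is explicitly out of scope.  Bootstrap resamples alignment columns with
replacement (default 100 replicates at desk scale; the survey setting is
1000 and is one config key away) and reports the percentage of replicates
containing each original bipartition, computed unrooted.

Subfamily assignment is unrooted-clade based: for each unlabeled leaf, the
smallest bipartition side containing it and at least one marker determines
the label if all its markers agree; mixed sides fall back to the nearest
marker by patristic distance and are flagged ambiguous.  Markers stand in
for previously classified genes from the literature.

Alignment inputs are expected pre-aligned; the identification stage's
model-coordinate hit segments serve as the alignment in the pipeline (for
real data, any external aligner such as MAFFT can produce the input FASTA).

## Cis-elements and motifs

Promoters are the 1500 bp upstream of the gene start: plus strand
`[start−L, start−1]`, minus strand the reverse complement of
`[end+1, end+L]`, truncated with a flag at chromosome edges.  Scanning is
exact IUPAC set-membership at every position on both strands (the PLACE
convention is strand-symmetric; reverse hits are reported in forward
coordinates).  The five-element library ships as an editable TSV keyed by
PLACE identifiers; consensus strings are data, not code, so users can
extend or correct them.

The motif discoverer is a ZOOPS (zero-or-one occurrence per sequence)
mixture fitted by EM over a uniform 0.25 background: E-step posteriors over
site positions plus a no-site component, M-step PWM update with 0.25
pseudocounts, site-prior γ re-estimated and clamped to (10⁻³, 1−10⁻³).
Starting points use subsequence seeding: every observed window (subsampled
above 1500 windows) is ranked by its one-step ZOOPS likelihood — reducible
to Hamming-match counts — and full EM runs from the top seeds plus one
random start.  After each motif converges, called sites (posterior > 0.5)
are masked with random bases before the next motif is fitted.  No parity
with MEME is claimed; its E-value model is not reproduced.

## Expression and qPCR

Binning follows the survey legend verbatim: > 6 extremely high, (4, 6]
high, (2, 4] medium, (0, 2] low.  The legend leaves 0 itself unclassified;
values ≤ 0 map to a distinct `none` category so the printed bins stay
untouched.  Group clustering is average-linkage agglomerative clustering of
Euclidean profile distances cut at k = 5 groups (mirroring the five heatmap
groups); rows are processed in id order so the partition is deterministic
and permutation-invariant.  Group identity (which cluster is "group I") is
not meaningful and not asserted anywhere.

ΔΔCT uses per-replicate ΔCT = Ct_target − Ct_reference, referenced to the
mean baseline ΔCT of the same gene (the printed formula is scalar at time
zero; replicate handling is unstated, and the mean is the natural choice).
Fold change is `2^(−ΔΔCT)`.  Significance is a two-sided equal-variance
Student's t-test of replicate ΔCT values against baseline replicates
(* p < 0.05, ** p < 0.01); two zero-variance groups with equal means give
p = 1 by convention.  Primer-efficiency (Pfaffl) correction and
multi-reference normalization are out of scope.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure* each stage consumes:

- domain-bearing proteins among i.i.d.-background decoys, with subfamily
  structure created by independently diverged consensi (default 5
  subfamilies, 30 % consensus divergence, 5 % member noise);
- a genome in which family genes are interspersed among decoy genes
  (intergenic gaps 250–500 kb, beyond the tandem window), tandem clusters
  are contiguous near-identical copies, and segmental blocks are contiguous
  ordered runs copied to another chromosome; duplicate copies diverge under
  an acceptance-rejection codon process with ω = 0.2, emulating the
  purifying selection real duplicates show;
- codon pairs evolved from a random ancestor with a kappa = 2 transition
  bias and nonsynonymous acceptance probability ω;
- promoters with elements implanted at recorded positions (either strand),
  and element words also implanted upstream of family genes in the genome;
- expression matrices as group archetypes on the 0–8 scale plus Gaussian
  noise, and Ct tables whose noiseless ΔΔCT equals −log₂ fold change with
  per-well Gaussian noise.

It does **not** emulate realistic intron-length or gene-density
distributions, repeat content, codon-usage bias, base composition skew,
alternative splicing, or sequencing noise.  Consequently, passing tests
demonstrate that each algorithm recovers the structure it claims to detect
under its stated model — not that the pipeline is robust to every artifact
of real annotation.  Default scales (100-protein proteome, ~120-gene
genome, 300-codon pairs, 1500-nt promoters, 100 bootstrap replicates,
200-replicate simulation suites) keep a full run in tens of seconds; they
are the package's chosen desk scale, with survey-scale settings one config
key away.

## Known limitations

- E-value calibration assumes the Gumbel regime holds for profile scores of
  background sequences; very short profiles or compositionally biased
  backgrounds would need per-length calibration.
- Greedy block extraction is optimal per chain but not a global block
  partition; MCScanX's exact scoring differs in detail.
- NG86 undercounts at high divergence even with the JC correction; the
  saturation flag marks, but does not rescue, such pairs.
- The NJ tie-break and negative-branch policy are one defensible convention
  among several; topologies on non-additive data can differ from other NJ
  implementations at ties.
- The ZOOPS EM discoverer handles ungapped, fixed-width motifs only.
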