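# Methods

## Data model

A genotype table holds one row per male: a sample id, a population label,
and one cell per locus. Y-STR alleles are repeat numbers with an optional
one-digit microvariant fraction (e.g. `19.2` = 19 repeats + 2 bases); they
are stored internally as integer tenths of a repeat (`19.2` → 192) so that
allele equality and haplotype identity are exact, never float comparisons.
Microvariant digits are restricted to .0–.3 and repeat numbers to the open
interval (0, 100), which covers every allele nomenclature the supported
panels use.

Multi-copy loci (DYS385a/b, DYF387S1a/b) are modeled as a single locus
carrying an unordered allele multiset; `a`/`b` column pairs in input files
are merged on read. The same representation absorbs the rare duplicated
alleles at single-copy loci (e.g. `15,17` at DYS19), which are flagged
`DUPLICATED_SINGLE_COPY`. Flags (`NULL_ALLELE`, `INTERMEDIATE_ALLELE`,
`DUPLICATED_SINGLE_COPY`) are always recomputed from the calls, so a
profile restricted to a marker subset reflags itself correctly.

The five named marker subsets are nested: MHT (9 markers) ⊂ EHT (11) ⊂
PPY12 (12) ⊂ Yfiler (17) ⊂ Yfiler Plus (27). The Yfiler and Yfiler Plus
locus lists follow the kits; for the three historical subsets we use the
community-standard definitions (MHT = DYS19, DYS385a/b, DYS389I/II,
DYS390–393; EHT adds DYS438/DYS439; PPY12 adds DYS437), which respect the
nesting and give monotone haplotype counts.

## Forensic parameters

With allele frequencies p_ai at a locus and haplotype frequencies p_hi over
a marker subset, all obtained by direct counting:

- GD = N/(N−1)·(1 − Σ p_ai²) (Nei's unbiased gene diversity),
- MP = Σ p_hi² (random match probability),
- HD = N/(N−1)·(1 − MP),
- DC = distinct haplotypes / N.

The haplotype multiplicity spectrum {m → #haplotypes seen m times} is a
sufficient statistic for MP, HD and DC, which is what lets the generator
below reproduce published values exactly from printed spectra. At
multi-copy loci (and for duplicated single-copy genotypes) the countable
unit for GD is the whole allelic combination, consistent with how such
loci are reported. DC has no universally printed formula; we use the
standard distinct-haplotypes-over-N. Profiles with null alleles remain in
the haplotype counts (the null is part of the haplotype); they are removed
only before distance computation.

Reports round MP/GD/fractions to 4 decimals and HD to 9 for display; raw
doubles are kept in CSV/JSON output.

## AMOVA Φ-statistics

Pairwise population distances are Φ_ST from a two-level
Excoffier–Smouse–Quattro AMOVA over the matrix of squared inter-individual
distances d_ij:

    SSD_total = Σ_{i<j} d_ij / N          (over the pooled pair)
    SSD_within = Σ_g Σ_{i<j∈g} d_ij / n_g
    MSD_among = (SSD_total − SSD_within)/(k−1),  MSD_within = SSD_within/(N−k)
    n' = (N − Σ n_g²/N)/(k−1)
    σ²_among = (MSD_among − MSD_within)/n',  σ²_within = MSD_within
    Φ_ST = σ²_among / (σ²_among + σ²_within)

Two distance kinds are provided. `IDENTITY` (0/1 haplotype mismatch,
including multi-copy combination keys) yields the frequency-based Fst
analog. `SQUARED_REPEAT` (Σ over loci of squared repeat differences)
yields the Rst analog; multi-copy loci are excluded there by default
because a repeat difference between allele multisets is not well defined
(the `include_multicopy` flag re-includes them for users who want the
per-copy convention). Two policies handle microvariants in
the repeat metric: `FRACTIONAL` (default; 19.2 − 19 counts 0.2 repeats)
and `EXCLUDE_LOCUS` (drop loci carrying any microvariant in the dataset,
resolved once so all pairs share a locus set). `dys389_adjust`
(default off) subtracts DYS389I from DYS389II before differencing, for
the convention in which DYS389II is the combined fragment.

Profiles with duplicated single-copy alleles or null alleles are removed
before distances — they have no defined repeat distance — and the removals
are logged on the results object. Negative Φ estimates (possible for the
unbiased estimator when true differentiation is ~0) are kept raw in
`phi_raw` and clamped to 0 in the reported `phi` matrix, the usual
reporting convention. If both variance components are zero (all distances
equal) Φ is defined as 0.

P-values permute profile-to-population labels within each pair and use the
add-one estimator (1 + #{Φ* ≥ Φ}) / (B + 1), which cannot return 0 and is
valid for any B. All permutation draws come from one seeded NumPy
generator, so a (data, seed, B) triple is fully reproducible.

## Ordination and phylogeny

PCA operates on one-hot-encoded genotypes: one 0/1 column per
(locus, allele-or-combination), zero-variance columns dropped, columns
centered but not scaled (scaling is exposed upstream by encoding choice,
not applied by default since allele indicators share a scale). The
decomposition is a thin SVD; signs are fixed by making each component's
largest-magnitude loading positive, so results are order-independent.

Classical (Torgerson) MDS double-centers the squared distance matrix,
B = −½ J D² J, and embeds on the top-k non-negative eigenpairs; negative
eigenvalues — a non-Euclidean input, common for Φ matrices — are dropped
and recorded as a warning on the result. Non-metric MDS is deliberately
not implemented; only recovered-distance fidelity is asserted, never
quadrant/sign conventions of any particular plotting tool.

Neighbor joining follows Saitou–Nei with the Q-criterion
Q_ij = (n−2)d_ij − r_i − r_j. Ties in Q break on the lexicographically
smallest pair of subtree labels (each subtree tagged by its smallest leaf
label), making the output invariant to input ordering. Additive matrices
are recovered exactly — topology and branch lengths — which the tests
verify against random trees and against an independent NJ implementation.
Negative branch lengths (non-additive input) are kept in the Newick
output. Trees are scikit-bio `TreeNode` objects; Newick serialization
rounds branch lengths to 6 significant digits.

## Synthetic data

The simulator is a test harness, not a demographic model. Each population
founder sits `divergence_generations` below a common ancestral haplotype
(defaults: modal Yfiler Plus alleles); each sampled male hangs
`within_generations` (default 150) below his population founder in a star
genealogy. Mutation is single-step symmetric SMM: per generation and
marker copy, with per-locus rate μ, the allele moves ±1 repeat (reflected
at 1 repeat to stay positive). Defaults are μ = 2.5×10⁻³ for ordinary
loci — the typical Y-STR per-meiosis rate — and 1.2×10⁻² for the six
rapidly mutating loci (DYF387S1, DYS449, DYS518, DYS570, DYS576, DYS627),
an order of magnitude hotter, as published rate compilations show. Under
this geometry the expected squared repeat difference is 2μ·G_within within
a population and 2μ·(G_div + G_within) between, so Rst grows
monotonically with divergence time — the property the recovery tests
check on the grid {0, 50, 200, 800} generations.

What the star genealogy does not emulate: coalescent genealogy within
populations (haplotypes are exchangeable around the founder, with no
deep lineage structure), migration, population growth, multi-step
mutations, or locus-specific allele ranges. Passing tests therefore
demonstrate the correctness of the statistics and their monotone response
to divergence, not calibration of Φ values against real demographic
histories.

`spectrum_constrained_dataset` reproduces a printed haplotype multiplicity
spectrum exactly: distinct haplotypes are enumerated by offsetting two
single-copy counter loci from the founder (distinctness by construction,
up to 3600 haplotypes), multiplicities assigned per the spectrum, and the
profile order shuffled with the seed. Since MP/HD/DC depend only on the
spectrum, these datasets reproduce published forensic statistics exactly
regardless of seed. Artifact injection converts single-copy calls, with
per-call seeded probabilities, into duplicated two-allele calls, nulls, or
x.2 microvariants, to exercise validation and the distance filter.

## Numerical and design notes

- Problem sizes in the test suite (populations of 8–25 for permutation
  calibration and divergence-grid checks; 200 null replicates with 99
  permutations each) are chosen as the smallest sizes at which the
  discreteness of the permutation distribution and sampling noise do not
  mask the tested effects.
- The AMOVA oracle in the tests recomputes every variance component with
  explicit loops and its own distance code; the package path is vectorized
  (einsum over the allele matrix) and must agree to 1e-10 on all instances
  with N ≤ 12.
- Duplicating every profile k times changes the unbiased Φ estimate only
  through finite-sample corrections; the tests bound that drift rather
  than asserting exact invariance.
- Degenerate inputs: N < 2 rejects diversity estimates; populations
  emptied by the artifact filter raise with the population named; rank-0
  matrices reject PCA; asymmetric matrices reject MDS/NJ; fewer than 3
  taxa reject NJ.
- The pipeline writes a manifest with SHA-256 checksums of inputs and
  outputs; identical configs reproduce identical checksums because every
  stochastic stage draws from the single configured seed.

## Known limitations

- No hierarchical (3+ level) AMOVA, Slatkin linearization, or exact tests
  of differentiation.
- Rst conventions differ slightly between published tools (locus
  weighting, microvariant handling, DYS389 adjustment); the flags above
  expose the main choices, but byte-level agreement with any specific
  online tool is not guaranteed.
- No kinship/likelihood-ratio calculus and no mutation-rate estimation
  from pedigree data.
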