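# Methods

This note documents the models and procedures `nifsip` implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic data do and do not establish about real samples.

## Reference database curation

Raw *nifH* candidate records (assumed already keyword-harvested from a
public nucleotide archive) pass three filters, applied in order for
rejection attribution:

1. **Identified organism.** A record is *unidentified* if its organism name
   contains any of `uncultured`, `unidentified`, `unclassified`,
   `environmental sample`, `metagenome` (case-insensitive substring — the
   naming conventions for anonymous sequences), **or** its lineage has no
   genus-rank entry.
2. **Length.** Ungapped length in [200, 1000] bp, both bounds inclusive
   ("1 kb" is read inclusively; the boundary convention is a package
   decision, not an upstream fact).
3. **Codon flanks.** Starts with one of {ATG, GTG, TTG} (bacterial
   alternative starts are common in *nifH*), ends with one of
   {TAA, TAG, TGA}, and has length ≡ 0 (mod 3) so the two codons close a
   reading frame. Without the frame condition "flanked by start and stop
   codons" is ill-defined.

Sequences containing non-IUPAC characters are rejected at the record level
(`malformed`) before any filter. Curation is idempotent, the rejection
counts partition the input, and disabling a filter can only grow the kept
set — all property-tested. Amplicon-side, merged *nifH* reads are kept when
their ungapped length lies in the inclusive window [330, 370] bp.

## Built-in placement

External placements (SEPP/EPA/pplacer) are ingested via jplace v3,
including the `{N}`-numbered Newick dialect (parsed by a small dedicated
reader, since no general Newick library accepts it). The built-in placer is
a deterministic distance-based substitute, not a likelihood method:

- Pairwise **Jukes–Cantor** distances between the aligned query and every
  reference leaf, with pairwise deletion of gap/ambiguous columns and a
  saturation cap at 5.0 substitutions/site (the JC logarithm is undefined at
  observed divergence ≥ 3/4).
- For each tree edge, the attachment (distal position `x` along the edge,
  pendant length `p`) is fitted by **box-constrained weighted least
  squares**: predicted distance to leaf *i* is `p + path_i(x)`, residuals
  weighted 1/d² (Fitch–Margoliash weighting, as in distance-based placement
  tools). The two-variable QP is solved exactly by active-set enumeration —
  no iterative solver, hence bit-reproducible.
- The edge with the smallest weighted residual wins; ties break to the
  smallest postorder edge index.

The 1/d² weighting makes the zero-distance case exact: a query identical to
a reference leaf attaches to that leaf's terminal edge with pendant length
at solver precision (~1e-12). Placement scores are invariant under
re-rooting because only path lengths enter. The placer is verified against
a brute-force (edge × distal × pendant) grid oracle on small trees, and
recovers the generating edge exactly when distances are additive.

Only the best placement per query (maximum likelihood-weight ratio; ties to
the smallest edge number) feeds taxonomy; alternatives are retained in the
jplace output.

## Conserved-rank host inference

For a placed query, the patristic distance to a leaf is
`pendant + distal-side path`, computed exactly and cross-checked against an
independent graft-and-path-sum oracle to 1e-9. The neighbourhood is
`{leaf : d < k}` with **strict** inequality — a nearest reference at 0.49
with *k* = 0.48 leaves the query unclassified.

The assignment is the longest rank prefix (domain → species) on which **all**
neighbours agree; a rank absent in any neighbour truncates agreement at the
shallower depth (preventing deep assignment through lineage gaps), and
neighbours without any lineage are excluded with a warning. A query is
*annotated* when unanimity reaches the annotation rank (default phylum).
Unanimity is what gives the HGT guard its one-sided failure mode: a single
misplaced foreign-phylum *nifH* in the neighbourhood can only withhold a
phylum call, never produce a wrong one.

*k* is chosen on a grid (default 0.01–1.00, step 0.01, matching the
two-decimal resolution at which thresholds in this literature are reported)
as the argmax of annotated queries; ties resolve to the smallest
(most conservative) *k*. The annotated-count curve is returned for
inspection — it is not monotone: too-small *k* finds no neighbours,
too-large *k* imports cross-lineage references and unanimity collapses.

Two reports support manual review: nearest-reference percent identity
(matches / aligned non-gap columns) with mean ± sd and minimum, and an
inspection table for unclassified queries listing neighbours within a looser
radius `k_loose` and whether they form a single-phylum cluster (the
situation where a lineage is plausibly real but under-represented among
references).

## SIP incorporator detection

Inputs are taxa × fraction count tables with per-fraction buoyant densities
for a paired control (unincubated) and treatment (¹⁵N₂-incubated) gradient,
plus unfractionated counts per condition. Two pre-filters remove taxa whose
abundance was reshaped by incubation rather than labeling:

- unfractionated relative-abundance ratio (max/min across the pair, with a
  1e-8 floor) must be ≤ 10;
- the taxon must be present (nonzero) in ≥ 3 fractions with density
  > 1.69 g ml⁻¹ in **both** conditions.

Within each of the four overlapping heavy windows (closed intervals, with a
1e-9 g ml⁻¹ tolerance so boundary fractions are never lost to float
representation), counts are aggregated per condition and normalised by
**median-of-ratios size factors** computed over taxa nonzero in both
conditions (the standard negative-binomial-engine normalisation; it is
robust to the labeled minority, whereas total-count normalisation lets the
labeled DNA arriving in heavy windows deflate every labeled taxon's fold
change), falling back to total-count scaling when fewer than 10 taxa are
shared. The moderated statistic is

```
lfc = log2((t + 0.5) / (c + 0.5))        (size-normalised counts)
z   = (lfc − 0.25) / SE,  one-sided upper-tail p
```

with SE from the delta method on the normalised counts times an
**overdispersion factor φ** estimated by the method of moments from
fraction-to-fraction variability: control and treatment fractions in the
window are paired by density rank, each pair's pooled proportion gives a
per-fraction expectation (so a taxon's systematic density profile cancels),
and φ is the df-corrected median Pearson statistic across adequately covered
taxa, floored at 1. Under a pure multinomial simulation φ ≈ 1.00; real
biological replication noise raises it and widens the test accordingly.

BH correction is applied **within each window** across taxa; a taxon is an
incorporator iff q < 0.05 in at least one window, and supporting windows are
reported. Raising the null threshold can only shrink the incorporator set,
results are invariant to fraction order, and incorporators are always a
subset of the pre-filtered taxa — all tested.

## Gradient simulator

Each taxon bands at

```
ρ(GC, at%) = 1.660 + 0.098·GC + 0.016·((at% − 0.37)/100)/(1 − 0.37/100)  g ml⁻¹
```

— the Schildkraut GC dependence plus a linear ¹⁵N shift reaching
0.016 g ml⁻¹ at full labeling, zero at the 0.37 at% natural background.
Reads spread around ρ with a Gaussian kernel (σ = 0.006 g ml⁻¹,
diffusion/mixing) discretised onto fraction bins; mass beyond the gradient
accumulates in the terminal fractions. Fraction counts are one multinomial
draw per condition at the configured library depth (so counts conserve depth
exactly), and unfractionated counts are a separate multinomial over relative
abundances. All randomness flows through explicit seeds.

Defaults emulate the study conditions this method targets: 200 taxa, 10%
labeled at the 40.4 at% mass-balance estimate, library depth 5×10⁴ per
condition, and **24 fractions** over 1.66–1.78 g ml⁻¹. The fraction count is
deliberately 24, not fewer: the four detection windows are 0.015 g ml⁻¹ wide
and each must hold ≥ 3 fractions, which requires the ≤ 0.005 g ml⁻¹ spacing
that 100 µl fractions give in practice. Community knobs kept deliberately
simple: lognormal rank abundances (σ = 1.0) and truncated-normal genomic GC
(mean 0.50, sd 0.07, bounds 0.30–0.70), typical of sediment communities.

The specificity estimator re-labels the community's labeled subset at each
at% on a grid, simulates, runs the full detection pipeline, and reports the
false-positive rate (false calls / unlabeled taxa tested) per grid point,
plus the arithmetic mean over the 20–50 at% band — a factor of two around
the mass-balance estimate, reflecting its uncertainty.

**What the simulator does not capture:** genome-fragment length and GC
heterogeneity within a genome, gradient compression/wall effects, PCR and
primer bias, biological replicate noise (φ > 1), partial community turnover
between control and treatment, and cross-feeding of label. Detector error
rates measured here are therefore best-case floors for real experiments, not
guarantees; the detection *procedure* (windows, threshold, sidedness,
pre-filters, FDR control) is exercised exactly as it runs on real tables.

Sensitivity is reported over the labeled taxa that pass the pre-filters —
the set the detector actually tests. Taxa excluded by the pre-filters are a
property of the filtering design (they are reported separately with
reasons), not of the window test.

Known intrinsic limits the simulator makes visible: taxa rarer than ~10⁻³
relative abundance yield too few heavy-window reads to clear the null
threshold at 5×10⁴ depth, and taxa with GC ≳ 0.65 band inside the heaviest
window even unlabeled, so the published window set cannot see their shift.

## Mass balance

The labeled-biomass enrichment solves the exact two-pool mixing equation
`total = f·x + (1−f)·background` with `f = labeled_community_fraction ×
(1 − dead_fraction)`; it is the algebraic inverse of the forward mixing
formula (property-tested to 1e-9). With bulk 0.422 at%, 98.7% dead organic
N, 10% labeled community and 0.370 at% background it gives 40.4 at%. The
0.370 background is the package default chosen for internal consistency
(air-N₂ 0.3663 at% would give ≈ 43 at%); `f = 0` is rejected as undefined.

## Synthetic labeled trees

Taxonomy tests use star-of-clades trees: each "phylum" is a clade whose
leaves hang 0.10–0.15 from the clade root, clades hang 0.30 from a central
node — within-clade patristic diameter ≤ 0.30, between-phylum leaf distance
≥ 0.80 ≥ 0.6. Lineages are rank-consistent down to genus, with unique
species, so the expected assignment depth is genus. In-clade queries attach
along leaf branches (pendant 0.01–0.03); "divergent" queries attach on clade
stems 0.15 above the clade root with pendant 0.05, putting their nearest
reference at ~0.30–0.35 and their nearest foreign-phylum reference at
~0.62 — which is what gives the annotated-vs-*k* curve its interior maximum
(recovered *k*\* ≈ 0.33–0.35) instead of a degenerate plateau from 0 up.
Optional HGT leaves carry a foreign phylum's lineage inside another clade to
exercise the unanimity guard.

## Numerical and degenerate-input conventions

- JC distances: cap 5.0; zero-overlap pairs excluded from the fit (an
  all-gap query is an `UnplaceableError`).
- Placement weights: 1/max(d, 1e-6)²; per-edge score comparisons use a 1e-12
  tolerance before the smallest-edge tie-break.
- All-zero taxa: pseudocounts give lfc = 0 and p ≈ 1 (never NaN); SE is
  floored at 1e-12 only to avoid division by zero in the same degenerate
  case.
- Windows with < 3 fractions in either condition are skipped with a warning
  rather than tested.
- Trees are treated as unrooted internally (rooting is presentational);
  branch lengths must be ≥ 0 and leaf labels unique.
- TSV outputs use fixed `%.6g` float formatting; reruns with the same config
  and seed are byte-identical, and the run manifest records the config hash,
  seed and per-file SHA-256.
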