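# Methods

## Scope and model

`adenosig` quantifies single-base-substitution (SBS) mutational
signatures in colorectal adenomas and carcinomas from consensus somatic
variant calls, aimed at detecting base-excision-repair deficiency:
biallelic MUTYH loss (marker: SBS18 + SBS36, C>A-dominated) and biallelic
NTHL1 loss (marker: SBS30, C>T-dominated). Mismatch-repair (MMR)
deficiency is modelled as a confounder: it adds SBS15/SBS44 mutations and
inflates burden, diluting the marker proportion, which is why
MMR-deficient samples are excluded from the biallelic-MUTYH carcinoma
comparison group by default.

The pipeline consumes VCFs; read alignment and the callers themselves are
out of scope, as are germline variant classification, LOH calling and
indel/doublet signatures.

## Catalogue construction

- One record per ALT allele of each PASS/unfiltered VCF row. Depth and
  VAF derive from the genotype AD field (VAF = alt reads / depth), else
  FORMAT or INFO DP + AF; rows with neither are excluded with a logged
  warning. Variant type follows allele lengths (SNV, INS, DEL, MNV).
- Consensus keeps keys called by both callers. Depth/VAF are taken from
  the first caller's record — the published analyses intersect *call
  sets*, not genotyping evidence, so a deterministic convention is
  required; the first-caller choice is arbitrary but fixed and documented.
- Filters are inclusive (`depth >= 50`, `vaf >= 0.10`): "minimum" names
  the smallest admissible value. They are applied after intersection.
- SNVs are classified into the 96 pyrimidine-centred classes using the
  closed 1-based window [pos−1, pos+1]; purine-reference sites are
  reverse-complemented. A REF/FASTA mismatch is an error (it indicates
  build confusion); contig-edge SNVs are excluded with a warning; MNVs
  are excluded from both the catalogue and TMB with a logged count.
- TMB = (SNV + indel count) / capture size, default 67 Mb;
  hypermutation at ≥ 10 mutations/Mb. Both surface as config fields.

## Exposure refitting

Let `P` be the 96 × K signature matrix (columns on the simplex) and `v`
the sample's catalogue normalised to proportions. The exposure estimate is

    e* = argmin_{e in Δ_K} || v − P e ||_2 .

Refitting proportions rather than counts makes the result scale-invariant
(a catalogue and its tenfold duplicate give identical exposures) and
matches the convention of reporting exposures as percentages of a
sample's mutations.

**Optimiser.** Simulated annealing over the simplex: a proposal moves
mass δ ~ Uniform(0, 0.1) from one random signature to another (clipped at
zero), accepted by the Metropolis rule with geometric cooling (T₀ = 0.01,
factor 0.995 per step, 10,000 steps), best of 5 restarts (uniform start,
then Dirichlet(1) starts). Because the objective is quadratic, each
proposal's Δf is computed in O(K) from the precomputed Gram matrix PᵀP.
The returned point is then polished by pairwise projected coordinate
descent (the optimal mass transfer between any two signatures has a
closed form; sweeps repeat until no pair improves), which in practice
lands on the constrained optimum to numerical precision. All randomness
flows from one explicit seed (default 1337); outputs are bit-reproducible.

An exhaustive simplex-lattice search (`refit_oracle_grid`, step 0.01,
K ≤ 4, lexicographically-first tie-break) serves as an independent oracle:
on noise-free mixtures the annealer's objective must match the lattice
optimum to 1e-3, and the test suite enforces this on 50 random instances.

**Alternatives and guards.** A cosine-distance objective is available
behind a flag for sensitivity analysis. Samples with zero SNVs cannot be
refit (proportions undefined) and are reported as such; samples with
< 50 SNVs are refit but flagged low-confidence — the multinomial
bootstrap (`bootstrap_exposures`) shows interval widths shrinking with
burden, and 50 is a pragmatic floor, not a published constant.

**Reference set.** The published analysis used a reduced set of 16
signatures previously observed in colorectal tissue, whose full identity
lives in supplementary material that is not reproduced here. The bundled
matrix (`synthetic_signature_matrix`) is therefore an explicit synthetic
stand-in: 16 columns with COSMIC-style names, including the clock-like
SBS1/SBS5, the markers SBS15, SBS18, SBS30, SBS36, SBS44, and filler
signatures, each concentrating 85 % of its mass (55 % for broad
clock-like ones) on qualitatively appropriate channels with seeded
Dirichlet weights. It is deterministic, distinct enough for the 16-way
refit to be identifiable, and must not be mistaken for COSMIC v3. Real
analyses should load a genuine reference TSV via
`load_signature_matrix`, which accepts both bracket-notation and
Type/Subtype COSMIC dialects and renormalises columns within 1e-3 of
unit sum.

## Hotspot diagnostics

Matching is by exact genomic key on a named build; the shipped registry
carries GRCh37/GRCh38 keys for KRAS c.34G>T and PIK3CA c.1636C>A
(convenience values — verify before clinical use) plus keys derived from
the synthetic genome for testing. PPV = 100·tp/(tp+fp) and
NPV = 100·tn/(tn+fn) are kept at full precision with explicit `None`
when undefined; reports round half-up to one decimal. Both a Fisher
exact p and a Welch t on the 0/1 indicators are reported, because for
small case-control tables neither is canonical; the implementation's
Fisher p is tested against an exhaustive hypergeometric enumeration.

## Cohort statistics

- Group summaries use the sample SD (n−1); SD is undefined for n = 1 and
  such groups are summarised but never tested.
- The t-test is Welch's by default: recomputing p from published group
  summaries under Welch reproduces the published magnitudes
  (e.g. 3.4 × 10⁻⁴ for the adenoma marker comparison), whereas the
  pooled-variance Student's variant does not; the pooled variant remains
  available via `equal_var=True`. Summary-based and raw-value calls share
  one formula path and coincide exactly.
- Cohen's d uses the pooled-SD denominator
  s_pooled = sqrt(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)), sign = first minus
  second argument; this reproduces published effect-size columns at
  one-decimal precision from the printed summaries.
- Bonferroni: adjusted p = min(1, m·p), default m = 35 (the number of
  hypotheses in the published comparison tables), configurable.
- One-way ANOVA is the classical between/within F; an all-constant input
  returns F = 0, p = 1, and zero within-variance with real separation
  returns F = ∞, p = 0 (documented convention for degenerate inputs).
- Report rounding: means/SDs one decimal (half-up), p two significant
  figures (scientific below 0.01), d one decimal.

## Synthetic cohort generator

The generator emulates the study design, not any patient: seven groups
(biallelic MUTYH adenomas and carcinomas, two MMR-deficient MUTYH
carcinomas, biallelic NTHL1 adenomas and carcinomas, control adenomas
and carcinomas) with

- **exposures** e_true ~ Dirichlet(α₀ · mean vector). Group mean vectors
  place the published marker mass (e.g. 0.66 SBS18+SBS36 in MUTYH
  adenomas, 0.745 SBS30 in NTHL1 adenomas, 0.08 marker in control
  adenomas) and spread the remainder over clock-like and filler
  signatures. α₀ per group is calibrated once so the marker SD matches
  the published group SD via Var = p(1−p)/(α₀+1) (e.g. α₀ ≈ 1.6 for the
  very dispersed MUTYH adenomas, ≈ 100 for the tight NTHL1 carcinomas).
- **burden**: SNV and indel counts are log-normal with natural-scale
  (mean, SD) equal to the published group summaries (e.g. 91.1 ± 56.8
  SNVs in control adenomas, 494.3 ± 197.5 in MUTYH carcinomas); the
  MMR-deficient group's mean is set so TMB clears the 10 mutations/Mb
  hypermutation threshold.
- **placement**: class counts are Multinomial(m, P·e_true); each SNV is
  placed at a reference position whose trinucleotide context matches its
  class (positions pre-indexed per context; purine-centred sites emit the
  reverse-complemented alleles), so cataloguing the VCFs recovers the
  drawn class counts exactly.
- **sequencing**: depth ~ Poisson(357.9) (the published median tissue
  depth), VAF ~ Beta(7, 13) (mean 0.35, ~all true calls pass the 10 %
  filter); a contamination fraction (default 5 %) forces calls below the
  depth or VAF threshold to exercise filtering; each caller additionally
  reports private false calls at a 10 % discordance rate, removed by the
  consensus step.
- **hotspots** are planted per group at the published prevalences
  (0.667 / 0.074 in MUTYH vs control adenomas; 0.692 in MUTYH
  carcinomas, reproducing the published carcinoma PPV/NPV structure),
  overwriting one drawn SNV so burden totals stay as drawn.

The global seed fans out through a `SeedSequence` to per-sample seeds;
the same seed reproduces the cohort directory byte for byte.

**What a green test does not establish.** The generator produces clean
VCFs with idealised noise: no FFPE deamination artefacts, no alignment
error structure, no germline leakage, no copy-number or LOH effects, no
subclonality beyond the Beta VAF spread, and per-sample published values
are not reproduced — only group-level structure. End-to-end passes
therefore validate the pipeline's arithmetic and statistical behaviour,
not caller accuracy on real tumours.

## Numerical and design choices

- Annealing hyperparameters are not published for the original analysis;
  the schedule above is this package's own oracle-verified default.
  Whether the original refit used counts or proportions is likewise
  unstated; proportions were chosen for scale invariance.
- The intersection-then-filter order follows the narrative order of the
  method description and is configurable in code.
- The printed adenoma hotspot association p (3.1 × 10⁻²) is not
  reproducible from the printed counts by Fisher or chi-square, so the
  package reports both of its tests without asserting equality.
- Exposure percentages in the features table are 0–100 to mirror the
  published tables; the exposures TSV keeps raw proportions.

## Limitations

Hotspot matching is build-literal (no liftover, no HGVS resolution);
signature refitting assumes the reference set is correct and complete
for the tissue (missing processes are absorbed by the closest available
columns); Bonferroni is the only multiple-testing procedure; no support
for indel (ID) or doublet (DBS) signatures or de novo extraction.
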