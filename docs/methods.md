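# Methods

## The question and the quantity

`goconverge` asks whether a convergently evolved lifestyle — plant carnivory
— leaves a detectable signature in genome-wide functional annotation. The
unit of measurement is the **representation** of a function f in a genome:

    r_f = 1000 · (number of genes carrying ≥1 GO code of f)
               / (number of genes with ≥1 GO code of any kind),

genes per thousand function-assigned genes. The function set is a fixed,
literature-curated list of 36 carnivory-associated molecular functions
(digestive enzymes, nutrient transporters, trap-related activities), each
mapped to one or more Gene Ontology codes; codes listed together on one
entry are aliases (equivalent or deprecated forms of the same term) and a
gene matching any alias counts once for that entry. Matching is by literal
code — there is no ontology-graph propagation, so a gene annotated only with
a child term of a reference code does not count. A gene matching k distinct
entries contributes to all k, and the **carnivory total** is defined as the
*sum* of the 24 tested per-function values (not the count of distinct
carnivory genes); this is the convention under which the total can be
recomputed from adjusted per-function values and decomposed additively into
per-function shares. The alternative distinct-gene convention would give a
slightly smaller total whenever multi-function genes exist.

## Ingestion and the simple format

Curated annotations are harvested from GenBank flat files: every gene/CDS
feature becomes a gene, and its codes are all `GO:\d{7}` tokens found in any
qualifier value. Token matching rather than qualifier whitelisting is
deliberate: GenBank GO encoding varies by submitter (`/db_xref`,
`/GO_function`, `/GO_process`, `/GO_component`, free-text notes), and the
token pattern is dialect-robust. Mapped annotations arrive as tabular
exports (sequence name, then GO tokens) and are parsed the same way.
Both routes emit a minimal one-gene-per-line text format
(`gene_id<TAB>code;code;…` under a `#taxon=… method=…` header) that
round-trips exactly and is the interchange format for all downstream stages.
Genes with no codes are retained in tables but excluded from the
representation denominator.

Gene prediction and similarity search themselves (ORF calling, BLAST,
GO mapping) are out of scope: the pipeline starts from their outputs.

## Cross-method calibration

The two annotation routes do not detect functions equally well. One taxon
annotated by *both* routes calibrates the rest: for each function,
factor_f = r_f(curated) / r_f(mapped), computed on per-mille proportions.
Mapped-method profiles are multiplied function-wise by these factors; curated
profiles pass through unchanged. When either route detected zero genes for a
function the quotient is undefined ("nullset"); such functions are flagged,
their values pass through unadjusted by default (a `zero` policy is
available), and they are excluded from testing. Applying a taxon's own
factors back to its mapped profile reproduces its curated profile exactly —
a machine-precision identity the tests enforce at 1e-12 — and on synthetic
data with a known detection bias b_f the estimated factor is consistent for
1/b_f with error shrinking as 1/√(gene count).

Functions entering testing are those with a defined adjustment factor and a
nonzero count in at least one taxon; with the packaged reference set and the
study data this leaves 24 of the 36 entries, plus the total, for 25 criteria.

## Statistical tests

**Group analysis.** Carnivorous (n=4) vs. control (n=6) taxa are compared
per criterion with an upper-tailed two-sample t-test. The *unequal-variance*
(Welch) form is the default even though such analyses are often labelled
"Student's": the published p-values this package reproduces are consistent
with fractional Welch degrees of freedom (e.g. t = 3.14 → p = 0.011 at
df ≈ 5.6) and not with pooled df = 8 (p = 0.007). A pooled option is exposed
(`--pooled-t`).

**Per-taxon analysis.** Each carnivorous taxon is tested per criterion
against a reference normal distribution with location = *median* and scale =
sample (n−1) standard deviation of the six control values; p is the standard
normal upper tail of Z = (value − location)/scale. The median guards the
location against skewed control values; the denominator convention (n−1) is
a package choice. The reference parameters are treated as *known*: with only
six controls the Z-test is anticonservative in absolute terms (if the test
value were drawn from the same population as the controls, the realized size
at nominal α = 0.05 is ≈ 0.09, the tail of √(7/6)·t₅). The calibration test
in the suite therefore verifies the p-value transform against the fitted
distribution; the finite-control inflation is a known limitation of the
method itself, not of this implementation.

**Multiple testing.** Each family (the 25 group tests; each taxon's 25
Z-tests) is corrected with Storey q-values. π₀ is estimated as
π₀(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05, 0.10, …, 0.90, smoothed by a
natural cubic smoothing spline with 3 effective degrees of freedom
(penalty calibrated by bisection on the trace of the smoother matrix; the
implementation agrees with R's `smooth.spline(df=3)` to 5+ decimals) and
evaluated at λ = 0.90 — the grid of the original q-value software, which on
the published group p-values yields π₀ ≈ 0.31 and reproduces the published
q-values; extending the grid to 0.95 would drop the estimate to ≈ 0.18 on
these 25 p-values and is available via `StoreyConfig`. Estimates are clamped
to (0, 1]; families smaller than 10 p-values fall back to π₀ = 1, i.e.
Benjamini–Hochberg, and with π₀ fixed at 1 the q-values equal BH exactly
(property-tested against statsmodels). Ties in p share their maximum rank.
Significance is coded in six levels with strict thresholds — NS (q > 0.10),
"." (q < 0.10), "*" (< 0.05), "**" (< 0.01), "***" (< 0.001),
"****" (< 0.0001) — with boundary values falling in the less significant
bin. The adjusted-vs-raw comparison counts level changes per paired test,
flagging moves of more than one level.

**Power.** The design's detectable effect size is reported by the
normal-approximation formula d = (z₁₋α + z₁₋β)·√(1/n₁ + 1/n₂): 1.06
control-SDs for 50% power and 2.12 for 95% at α = 0.05 in the 6-vs-4
design. Monte-Carlo recovery of these numbers in the test suite simulates
the known-variance statistic the formula describes; the finite-sample Welch
t-test at the same effect sizes has lower power (≈ 0.42 and ≈ 0.90 by
noncentral-t calculation), which is worth remembering when interpreting
non-significant group results.

## Synthetic data

The generator produces annotation tables with the statistical skeleton the
analysis assumes and nothing more: per-gene, per-function Bernoulli code
assignment at rate baseline × class-enrichment × lognormal per-taxon jitter
× method bias (mapped route only), plus Poisson filler codes from a
synthetic non-reference pool (`GO:8000000+`) so summary tallies are
non-trivial. Multi-function genes arise by independence. Defaults mirror
the study dimensions: 6 controls, 4 carnivores, 20k genes, 55% assignment
fraction (midpoint of the 23–97% observed across real genomes), baseline
rates log-spaced over 2×10⁻⁴–6×10⁻³ so expected carnivory totals land in
the observed few-percent range, and jitter SD 0.25 giving right-skewed,
strictly positive between-taxon variation of roughly the magnitude the
reference distributions presume. The closed-form expectation
E[r_f] = 1000·rate_f (jitter at its median) is the generator's oracle.

What the generator does *not* emulate: ontology structure (no parent/child
code correlations), gene-length or assembly-quality effects on annotation,
correlated detection failures across functions, and phylogenetic
autocorrelation among taxa. Passing tests on synthetic data therefore
validate the arithmetic and the statistical calibration of the pipeline,
not the biological adequacy of the independence assumptions on real genomes.

## Reproduction of the published analysis

The deposited per-taxon profile tables behind the original ten-taxon
carnivorous-plant comparison are not redistributable here. Instead the
package ships the *printed* summary statistics (group t, per-taxon Z, p, q
per criterion) as data, and `goconverge.reconstruct` algebraically inverts
them: for each criterion, control values are written as location + scale ×
a standardized six-value set (median exactly 0, sample SD exactly 1, mean δ)
and carnivore values as location + Z × scale; δ is recovered from the
printed group t via t = (mean(Z) − δ)/√(var(Z)/4 + 1/6). Location and scale
cancel out of every statistic and are set to arbitrary plausible magnitudes,
except for the total column, which is anchored to the published carnivorous
range (3.1–5.0% of assigned genes). The recovered δ values are all ≈ 0.001
— i.e. the printed statistics are mutually consistent to rounding precision
— and the printed p-values re-emerge from the Welch degrees of freedom the
reconstruction induces, which is the evidence for the unequal-variance
reading above. All reconstructed tables are synthetic stand-ins: one
consistent solution, not the original measurements. Totals in deposited or
reconstructed tables are read as their own column and not recomputed from
the (scale-arbitrary) per-function columns.

## Numerical conventions and problem sizes

Per-mille values are kept at full precision internally; rounding (statistics
to 2 decimals, p and q to 3 significant figures, scientific notation below
0.001) happens only in report writers. Degenerate inputs raise typed errors
rather than returning NaN: zero assigned genes (undefined profile),
all-equal controls (zero reference scale), double adjustment, p-values
outside (0, 1]. The test suite's Monte-Carlo checks use 4,000 replicates
for size/power calibration, 10⁵ genes for factor consistency, and 10⁴ genes
for the brute-force counting oracle — sizes at which the tested tolerances
(±0.01 on test size, ±0.05 on power, ±0.25 on individual factors) are
several standard errors wide.
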