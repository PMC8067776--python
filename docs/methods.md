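# Methods

## The inference problem

Competing endogenous RNA (ceRNA) regulation posits that a long noncoding
RNA (lncRNA) sharing miRNA response elements with an mRNA competes for
the shared miRNAs and thereby derepresses the mRNA. Two observable
signatures follow: the pair shares more targeting miRNAs than expected
by chance, and the two transcripts are positively coexpressed. The
pipeline operationalises both, then studies the resulting per-group
lncRNA–mRNA networks.

## Shared-target screen

For a pair with `L` miRNAs targeting the lncRNA, `M` targeting the mRNA,
`x` targeting both, out of a background of `N` miRNAs, the evidence
against chance overlap is the hypergeometric survival probability

    P(X >= x) = sum_{k=x}^{min(L,M)} C(L,k) C(N-L, M-k) / C(N,M).

A pair is a candidate when `x >= min_shared` (default 4, i.e. strictly
more than 3 shared miRNAs) and `P < alpha` (default 0.05, uncorrected).
Both readings of the shared-count rule ("more than 3" vs "at least 3")
are common in screens of this type, so `min_shared` is configurable; the
default is the strict reading. Benjamini–Hochberg adjustment is
available behind `correction="benjamini_hochberg"`; the adjusted family
is the set of pairs that meet the shared-count floor, since only those
tests are ever performed. Survival probabilities are evaluated in log
space (log-gamma), so universes of thousands of miRNAs pose no overflow
risk. Pair enumeration is a single boolean matrix product over an
inverted miRNA index, keeping all-vs-all screening tractable at database
scale.

The background `N` is deliberately configurable because interaction
databases disagree on their miRNA totals: `union` (default) counts every
miRNA appearing in either map — the most inclusive reading of "all
miRNAs" — while `intersection` and `explicit` support sensitivity
analysis and reproduction of published analyses whose database-wide
totals are known. Any mode whose `N` is smaller than the largest single
target set is rejected as inconsistent.

## Expression filter and coexpression screen

Genes are kept when their expression is nonzero in strictly more than
half of the samples (`min_fraction=0.5`, `strict=True`). "Expressed" is
decided as value > 0; the cutoff fraction and strictness are
configurable because expression units (counts, TPM) vary between
studies.

Surviving candidates are tested for Spearman correlation within each
sample group separately (`scope="per_group"`), yielding group-specific
edge lists and hence per-group networks; a pooled mode exists for
designs without meaningful grouping. An edge is retained when
`rho > 0.5` and `p < 0.01`. The threshold is applied to *signed* rho by
default: ceRNA theory predicts positive lncRNA–mRNA coexpression.
`sign="absolute"` is available.

Two p-value methods are provided:

- `asymptotic_t` (default): `t = rho * sqrt((n-2)/(1-rho^2))` against a
  t distribution with `n-2` degrees of freedom, two-sided (via
  `scipy.stats.spearmanr`).
- `exact_permutation`: the full `n!` permutation null, enumerated
  exactly for `n <= 9`. For tie-free vectors the null distribution
  depends only on `n` and is cached; with ties the observed midranks
  are permuted directly.

The exact method exposes a hard floor: with `n = 4` samples the smallest
achievable two-sided exact p is `2/24 ≈ 0.083`, so a `p < 0.01` screen
can never retain an edge in a 4-sample group. At clinical cohort sizes
(e.g. 7 disease vs 4 control samples) only the asymptotic approximation
can produce a nonempty small-group network — a power limitation the
test suite demonstrates rather than hides. The asymptotic method is the
default for exactly this reason; results from groups this small should
be treated as exploratory.

Ties are handled by average (mid-)ranks throughout; vectors with zero
rank variance have no defined rho and are reported as an error
(`ConstantInputError`), never silently as 0.

## Networks, degree structure, hubs, triads

Each group's retained edges define a strictly bipartite lncRNA–mRNA
graph (checked, not assumed); nodes carry their class, edges the full
evidence chain (`x`, hypergeometric p, rho, correlation p, shared miRNA
ids). Isolated nodes cannot occur because the network is edge-defined.

The degree histogram is fitted by least squares on log10–log10 axes
over nonzero-count bins; the negated slope is reported as the power-law
exponent together with r². Fewer than 3 usable bins yields a flagged
no-fit result rather than a fabricated exponent. Histogram least
squares is the conventional presentation for degree distributions of
biological networks and is what the fit is meant to reproduce;
maximum-likelihood (Clauset-style) estimation is intentionally out of
scope, and the `method` field leaves room for it. Two caveats follow
from this choice and are documented rather than patched: zero-count
bins must be dropped (log 0), and histograms of *sampled* power-law
degree sequences carry a long singleton tail that biases the fitted
slope low. The test generator therefore prescribes the configuration
model's degree sequence from the expected histogram
`count(d) = round(n * d^-gamma / Z)` — the configuration model is
defined by a prescribed sequence, and this isolates fitter accuracy
from histogram sampling noise; a `sequence="sampled"` mode retains the
noisy variant, whose bias the fit inherits by construction.

Hubs are ranked by raw degree with a deterministic lexicographic
tie-break (no centrality variants). Network comparison reports shared
and group-unique node sets with per-class counts. Each edge unfolds
into one lncRNA–miRNA–mRNA triad per shared miRNA — the mechanistic
sponge relationships the edge summarises.

Exports: GraphML (round-trips to an identical network), SIF
(`LNC cerna MRNA`), and edge TSV.

## Synthetic data

The generator emulates the statistical structure the screens assume,
not RNA-seq realism:

- **Interaction maps.** Background target sets are drawn independently
  per regulator with sizes from a discrete power law on
  `[5, n_mirna/2]` (heavy-tailed, so a few regulators have many
  targets). Exponent default 3.0: inside the 2–3 range reported for
  miRNA–target degree distributions, and calibrated so that planted
  pairs (below) essentially always pass the shared-target screen at the
  default design — at flatter exponents, pairs planted onto regulators
  whose background sets approach `n_mirna/2` drown the planted overlap
  in chance overlap. For each planted pair, `planted_shared` specific
  miRNAs (default 6) are forced into both regulators' sets.
- **Expression.** Planted pairs are coexpressed through a Gaussian
  copula: latent correlation `r = 2 sin(pi * rho_s / 6)` gives expected
  Spearman `rho_s` (default 0.85) in every group; all other genes are
  independent. Latents map through a lognormal marginal
  (`exp(3 + z)`) — any strictly increasing marginal preserves ranks, so
  the planted Spearman correlation is exact in expectation and the
  skewed scale merely resembles expression data. Optional dropout
  zeroes entries independently *after* correlation generation, so it
  both exercises the expressed-in-more-than-half filter and attenuates
  realised rho; tests either set dropout to 0 or budget the
  attenuation.
- **Design sizes.** The default recovery design uses 200 miRNAs, 50
  lncRNAs, 300 mRNAs, 40 planted pairs and 20 samples per group —
  large enough per group for the `rho > 0.5, p < 0.01` screen to have
  real power, and small enough that the full pipeline runs in seconds.
  `study_scale_config()` provides the 7-vs-4 clinical design to
  demonstrate the small-cohort power problem.
- A planted mRNA follows exactly one lncRNA (mRNAs are drawn without
  replacement); lncRNAs may repeat across pairs, which is also how the
  optional hub planting (`hub_lnc_pairs`) concentrates edges on one
  lncRNA. Partners of a shared lncRNA are mutually correlated at `r²`,
  a side effect accepted for simplicity.

What passing recovery tests show: the pipeline's thresholds recover
rank-correlated, target-sharing pairs embedded in independent noise.
What they do not show: robustness to normalisation artefacts, batch
effects, count overdispersion, or miRNA-expression-dependent sponging —
none of which the generator models.

## Recovery metrics

Sensitivity = recovered planted pairs / planted pairs, where a pair
counts as recovered when retained in at least one group. Precision =
recovered planted pairs / all retained pairs; with an empty retained
set precision is reported as an explicit NA (`None`), never 0/0.

## Determinism and orchestration

Every generator output is a pure function of (config, seed); stage
outputs are byte-identical across repeated runs, and chaining the CLI
subcommands reproduces `cerna run` artifacts exactly. All randomness
descends from the single top-level seed (a simulation block without its
own seed inherits it). The analysis stages themselves are
deterministic: ordering is fixed by explicit sorts, never by hash or
dict incidentals. Exit codes: 0 success, 2 config error, 3 input
format error, 4 stage failure.

## Known limitations

- No miRNA-expression weighting, conditional/partial-correlation ceRNA
  scores, or directional regulation: the screen is marginal by design.
- The hypergeometric background treats all miRNAs as exchangeable;
  miRNA families and expression levels are ignored.
- Histogram least squares is a presentation-faithful but statistically
  crude exponent estimator (see above).
- Database-scale results depend on the interaction tables supplied;
  the package performs no download, identifier harmonisation, or
  evidence filtering.
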