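# Methods notes

## The composite-index model

The Soil Quality Index treats soil quality as a weighted average of
unit-scaled indicator scores.  Its assumptions are worth stating because they
bound what the number means:

- **Linearity and compensability.**  Min–max scoring is linear between the
  observed extremes, and a deficit in one indicator can be fully compensated
  by a surplus in another.  No optimum-interval ("mid is best") scoring is
  offered; pH, whose agronomic optimum is genuinely interior, is handled by a
  monotone direction choice (see below).
- **Data-driven weights.**  Weights come from the PCA of the analysis dataset
  itself, so the index is relative to the dataset in hand, not an absolute
  scale.  Two datasets yield comparable SQIs only if scored under a shared
  normalization scope and selection.
- **Correlation PCA.**  Indicators are standardized (z-scores, n−1 sd), so the
  analysis sees only correlation structure, never raw scales or units.

### Pipeline defaults and their rationale

| parameter | default | meaning |
|---|---|---|
| `eigenvalue_threshold` | 1.0 (strict >) | Kaiser rule: a retained component must explain more than one indicator's worth of variance; ties at exactly 1.0 are excluded |
| `min_loading` | 0.5 | an MDS candidate must be substantially represented on its component |
| `within_frac` | 0.10 | candidates must be within 10% of the component's maximum absolute loading |
| `r_threshold` | 0.6 | above this absolute Pearson correlation two candidates are considered redundant |
| `weight_mode` | `communality` | raw weight Σ_k (γ_k/Σγ_retained)·a²; non-negative by construction |
| `normalization_scope` | `global` | one min–max window over the whole dataset, so scores are comparable across sites and years |
| `som_to_soc_divisor` | 1.724 | Van Bemmelen factor for converting organic matter to organic carbon |

Candidacy is evaluated per component over *all* indicators — an indicator may
be a candidate on several components, and reaching the MDS through any one of
them suffices.  This matters in practice: an indicator whose largest loading
sits on a component where it loses the 10% race can still enter through a
later component it dominates.

The published form of the weight equation sums signed loadings, which can
produce negative weights; no published weight values exist to disambiguate it.
The default squares loadings (communality-proportional weights, standard MDS
practice); `as_printed` uses absolute loadings with eigenvalue shares over the
full spectrum.  Both normalize to Σw = 1, and the pruning step renormalizes
over the surviving MDS.

Scoring directions: BD and pH decreasing, all stocks and available pools
increasing.  The pH choice reflects the acid-to-neutral site population this
package targets (baselines 5.1–7.5, where lower pH correlates with the
better-buffered profiles only weakly); it is fully overridable per indicator.

Redundancy pruning is greedy by descending weight: a candidate is kept iff it
does not exceed `r_threshold` against any already-kept member of the same
component's candidate set.  This is equivalent to repeatedly dropping the
lower-weight member of the worst offending pair.  Ties break by larger
absolute loading on that component, then input order.  Every keep/drop
decision is recorded on the selection object (`MDSSelection.audit`) and
logged, because this step is the least self-explanatory part of the method.

### Numerical choices

- Correlation matrices are symmetrized to (R+Rᵀ)/2 before eigendecomposition;
  eigenvalues in [−1e−10, 0] are clipped to zero, anything lower is an error.
- Loading columns are sign-fixed so each column's largest-magnitude entry is
  positive (eigenvector sign is arbitrary; this makes output deterministic).
- Variance percentages are γ/p × 100 where p is the indicator count.  Some
  published loading tables scale percentages to a different total; the
  bundled worked example therefore stores its printed per-component
  percentages verbatim rather than recomputing them.
- Degenerate score ranges (x_max = x_min within a normalization scope) raise
  rather than silently emitting 0/0.
- Sample (n−1) standard deviations everywhere, including SYI.

## The synthetic trial generator

The generator emulates a six-site, four-treatment (control / NPK / 15% / 30%
manure substitution), three-replicate randomized complete block wheat–maize
trial.  Site baselines are real published initial-property values for six
Vertisol stations; baseline total N/P/K, which initial-property tables rarely
report, are derived from each site's organic matter and its
unfertilized-control molar C:N/C:P/C:K ratios, keeping the
available ≤ total invariant and the stoichiometry module's outputs in the
plausible band (control C:N ≈ 9–11).

Each indicator is generated as

    value = baseline_site · (1 + δ_site,treatment) · (1 + b_i·f + c_i·g + ε)

- **δ ranges** default to the response spans reported for this system: BD
  −1.3…−17.1% under 30%M, SOM up to +22.5%, available pools up to +42.5%,
  totals N/P largest under pure NPK, total K unresponsive, pH stable.  The
  site-specific δ is drawn once per (site, treatment) and held fixed across
  years — treatment effects in such trials are site-consistent, so the
  uniform quantile of the draw is shared across treatments within a site
  (nested ranges then never reorder arms within a site by chance).
- **f** is a standard-normal latent fertility factor per plot with loadings
  b (SOM 0.15 > avail. P 0.12 > total N 0.10 ≈ avail. N 0.10 — the loading
  hierarchy of the fertility cluster seen in field data), creating the
  cross-indicator correlations (r > 0.6) that exercise redundancy pruning.
- **g** is a second plot factor for the compaction axis (BD +0.09,
  avail. K −0.09): denser plots hold less exchangeable potassium.  Without
  it the BD–K contrast has no variance of its own and never forms a
  retained component, contrary to the loading structure the generator is
  meant to emulate.
- **ε** is residual noise with cv = 0.05 (the per-site variance of such
  trials is not published; 5% is a typical plot-level analytical + sampling
  cv, and it is an explicit, documented free parameter).

Grain yield follows the same scheme with crop-specific control baselines
(wheat 2.4–2.5, maize 2.8–3.2 Mg ha⁻¹) and per-treatment residual cv
(control 0.10 > NPK = 15%M 0.07 > 30%M 0.05): unfertilized plots are the
least stable, so the SYI responds to fertilization.

Out-of-range draws are clipped into the valid domain and counted in the log.
The default seed (20211001) is the trial-start month; all randomness flows
from the single `TrialDesign.seed`.

**What the generator does not emulate:** weather and interannual trends
(years are exchangeable), spatial autocorrelation between plots, manure
mineralization dynamics, measurement-method biases, and site × treatment
interactions beyond the drawn δ.  Passing tests therefore demonstrate that
the pipeline's algebra and selection logic behave correctly under a known
generative model — not that any particular field result will reproduce.

### Validation problem sizes

Parameter-recovery and ordering checks run at 6 sites × 4 treatments × 200
replicates × 1 year × 2 seasons (9 600 plot-seasons): large enough that the
delta estimator's sampling error (≈0.4% per arm mean at cv = 0.05) sits well
inside the 2% recovery tolerance, small enough to run in seconds.  Recovery
is assessed with the latent factors off (they are a correlation device,
validated separately by the correlation-structure test) and with the two
season estimates averaged per site, since the injected δ is season-constant.

A caveat on data-driven selection: with a strongly correlated fertility
cluster, *which* member survives pruning (SOM vs total N vs available P) is
sample-sensitive — their weights differ by a few percent and the winner can
flip between realizations.  This is an intrinsic property of MDS selection,
not an implementation artifact.  Directional treatment-ordering checks are
therefore run on the index computed under the fixed worked-example selection;
the data-driven selection is exercised separately (non-empty MDS, bounded
index, 30%M > control).

At three replicates per cell the SYI itself is a noisy statistic (its
numerator subtracts a 2-df standard deviation); cell values of a single
realization scatter by ±0.1.  Its mean ordering across treatments is a
large-sample property.

## The stoichiometry module

Molar ratios use atomic masses C 12.011, N 14.007, P 30.974, K 39.098
g mol⁻¹.  Carbon defaults to SOC = SOM/1.724 because wet-oxidation methods
report organic matter while ratio conventions use carbon; labs reporting SOC
directly set `use_som_directly_as_carbon`.  Ratios use total (not available)
N/P/K — available pools are three orders of magnitude smaller and produce
ratios outside any published band.  Two algebraic identities
(C:N · N:P = C:P and N:P · P:K = N:K) and scale invariance hold by
construction and are property-tested.

## Known limitations

- One pooled PCA across all sites/years/seasons; per-stratum PCAs are not
  offered (the normalization scope only affects scoring).
- No factor rotation, no parallel-analysis or broken-stick retention
  alternatives, no sigmoid scoring curves.
- No significance testing (ANOVA/Tukey letters) — the summaries report
  effect sizes only.
- The fertilizer-rate arithmetic rounds an exact half *down*
  (225 × 0.70 = 157.5 → 157), matching the convention of the rate tables it
  reproduces; all other fractions round to nearest.
- CSV is the only I/O format; no spreadsheet/database ingestion and no
  coordinate-system handling for site locations.
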