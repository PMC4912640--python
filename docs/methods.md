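# Methods

This note records the models, priors, numerical choices and known
limitations behind `spongenet`, in the spirit of a model-documentation page.

## Data model and filters

The working object is a samples × OTUs table of integer read counts with a
metadata table mapping each sample to a host species or environmental
habitat (seawater, sediment). Per-sample totals N_m are always recomputed
from the matrix, never cached.

Dataset-level cleaning runs in a fixed order, recorded in the table's
provenance: (1) drop OTUs whose dataset-wide relative abundance is below
10⁻⁵ (strict <, measured against the pre-filter grand total); (2) drop OTUs
whose taxonomy lineage contains a blocked label (default "Chloroplast",
case-insensitive, any rank); (3) zero out, in host samples only, OTUs whose
pooled relative abundance across seawater samples exceeds 10⁻⁴ (strict >).
"Across all seawater samples" is read as pooled counts (sum over seawater
samples divided by total seawater reads); a flag switches to the mean of
per-sample proportions. Zeroing rather than dropping keeps the table shape
aligned across habitats; downstream totals are recomputed. All filters are
idempotent.

## Diversity and dispersion

Chao1 uses S_obs + f₁²/(2f₂), switching to the bias-corrected
S_obs + f₁(f₁−1)/(2(f₂+1)) when no doubletons exist. ACE uses the standard
10-count rare/abundant split. Expected rarefaction richness is the
hypergeometric closed form evaluated with log-gamma arithmetic, so deep
samples do not overflow. Bray–Curtis dissimilarity runs on raw counts,
proportions (default) or Hellinger-transformed proportions.

Dispersion to group centroids embeds the distance matrix by principal
coordinates and keeps negative-eigenvalue axes separately: the squared
distance to the centroid is (real-axis part) − (imaginary-axis part),
floored at zero before the square root (the Anderson 2006 / vegan
`betadisper(type="centroid")` convention; verified against vegan to 10
decimals on a fixture). Groups of size one get distance 0 with a warning.

## Bipartite network and degree laws

An OTU enters the network if present (count > 0) in at least `min_samples`
(default 25) distinct samples across the whole dataset; a link (species,
OTU) exists if the OTU appears in ≥ 1 replicate of that species. The
complementary cumulative degree distribution Pc(k) = P(degree ≥ k) is the
object fitted — both fitted forms are decreasing, which the ≥-k form
requires; a ≤-k variant is available. Fits minimize untransformed residuals
with a trust-region least-squares solver from a small multi-start grid
(a ∈ {0.1, 0.5, 1}, b ∈ {mean k, 2·mean k}); a fitted cutoff beyond 10× the
largest observed degree is flagged "no cutoff support". Specialist/generalist
thresholds default to < 5 and > 50 host species. The prevalence-versus-degree
curve is a cubic smoothing spline with generalized cross-validation; tied
degrees are collapsed to weighted means first. Null networks redraw the same
number of links uniformly over all host × OTU pairs.

## Sparse Lotka–Volterra inference

### Model

For one host's core (S OTUs, M replicates ordered as a pseudo-time series —
the space-for-time substitution), latent log-abundances follow the discrete
Ricker-type Lotka–Volterra map

n_{i,m} = n_{i,m−1} + r_i (1 − (N_{i,m−1} + Σ_{j≠i} γ_ij α_ij N_{j,m−1}) / k_i) + ε_{i,m},

with N = exp(n), ε_{i,m} ~ Normal(0, σ_i²), and observed counts
y_{i,m} ~ Poisson(exp(n_{i,m} + log N_m + Π_m)), where log N_m is the
observed per-replicate total (offset) and Π_m a free per-replicate effect.
A **positive** α_ij raises OTU i's competitive load and is therefore a
harmful effect of j on i; negative values are facilitative. A harmful link
is only dynamically feasible while α_ij N_j < k_i — beyond that the victim's
equilibrium abundance is driven to zero and the link leaves no signature in
the counts.

Priors: r_i ~ Normal(0, variance 10); k_i ~ Exponential(1) (keeping carrying
capacities positive on the relative-rate scale the offsets induce);
γ_ij ~ Bernoulli(P), P = 0.1; Π_m ~ Normal(0, s.d. 100);
σ_i ~ HalfNormal(1) (unstated in the original analysis; swappable).
The slab on included coefficients is α_ij ~ Normal(0, 0.25). Its scale is a
calibration choice: with data simulated under the all-zero-interaction null
at the study's replicate count (M = 47), posterior inclusion probabilities
should sit near the Bernoulli prior rather than being crushed by the slab's
Occam penalty; a slab s.d. of 0.5 achieves that while leaving ≥ 2σ of prior
support across the per-capita effect magnitudes of interest (≈ 0.3–1.5).
The first replicate is anchored by n_{i,1} ~ Normal(log k_i, 1).

### Sampler

The sampler is a Metropolis-within-Gibbs kernel (numba-compiled), with:

* single-site random-walk updates for every latent n_{i,m}, with the
  interaction load cached and updated incrementally (cost O(S²M) per sweep);
* exact Gaussian conditionals for r_i (the transition mean is linear in r);
* log-scale random-walk updates for k_i and σ_i;
* a collapsed Gibbs update for each (γ_ij, α_ij): the Gaussian slab is
  marginalized in closed form, the indicator drawn from its exact Bernoulli
  conditional, and α then drawn from its Gaussian conditional (included) or
  the slab prior (excluded) — the collapsed form of Gibbs variable
  selection, which mixes without pseudo-prior tuning. Indicator state flips
  are counted per link as a mixing diagnostic;
* random-walk updates for each Π_m;
* two reparameterization moves along the posterior's near-flat directions:
  a per-replicate common-mode move (n_{·,m} ↓ δ, Π_m ↑ δ; observation term
  exactly invariant) and a global scale move (all n ↓ δ, all k × e^(−δ),
  all Π ↑ δ; observations *and* transitions exactly invariant, only the k
  and Π priors and the transform Jacobian enter). Without these the
  latent-scale direction mixes so slowly that R̂ on r and k stays above 1.5
  at desk-scale chain lengths; with them R̂ ≈ 1.03.

Step sizes adapt toward ≈ 40% acceptance during burn-in only. Chains start
from moment-matched latents (log relative rates scaled so the community
average sits near zero) with chain-dispersed jitter. Split-R̂ and an
initial-positive-sequence effective sample size are reported per continuous
parameter; R̂ > 1.1 raises a warning flag in the output, not a failure.

The desk preset runs 4 chains × 20 000 iterations (half burn-in, thinning
10) — a few seconds for S ≈ 5–12, M ≈ 50–200 on one CPU. The original
protocol (10 chains × 5·10⁶ iterations, 2·10⁶ burn-in, thin 50) is available
as the `paper` preset for overnight runs; the test suite and acceptance
script use reduced chain counts and lengths chosen so that their
convergence diagnostics are clean at each problem size.

### Identifiability

Only relative abundances are observed, so three flat or near-flat directions
exist by construction: (i) the per-replicate common mode of n trades against
Π_m; (ii) the global latent scale trades against all k (fixed by the
Exponential prior); (iii) with few OTUs, a strong link can have a
"compositional mirror" — "j boosts i" and "j suppresses the third OTU" fit
proportions almost equally well, and the posterior can be bimodal at S = 3.
The mirror fades as S grows (more species anchor the composition); link
recovery at S = 8 is essentially exact (AUROC ≈ 1.0).

### Variance decomposition

Per retained draw, the deterministic equilibrium solves (I + A) N* = k with
A the included interactions; the Jacobian of the latent map at N* has
J_ii = 1 − (r_i/k_i) N*_i and J_ij = −(r_i/k_i) α_ij N*_j. The stationary
covariance V solves the discrete Lyapunov equation V = J V Jᵀ + diag(σ²),
and OTU i's variance v_ii is attributed proportionally to
density dependence (J_ii² v_ii), interactions (Σ_{j≠i} J_ij² v_jj) and
stochasticity (σ_i²), normalized to sum to one. In the diagonal case this
reduces to the AR(1) identities (J = 0.5, σ = 1 gives v = 4/3 and shares
0/0.25/0.75), which the tests pin to 10⁻⁶. Draws with an infeasible
equilibrium or spectral radius ≥ 1 are skipped and the skip fraction
reported; above 50% the decomposition refuses to answer. (The decomposition
is a reconstruction via linearization — the original analysis delegates the
formula to its source without printing it.)

### Representative network

The link count L is the rounded posterior mean of Σγ; the L directed links
with the highest inclusion probability are kept (ties by |mean α|, then
lexicographic), signed by the posterior mean of α conditional on inclusion.
Connectance L/(S(S−1)) is reported next to the posterior mean connectance as
a self-consistency check (they agree within one link by construction).
Unordered pairs are typed by their two directed signs: (+,+) mutualism,
(−,−) competition, (+,−) exploitation, (+,0) commensalism, (−,0) amensalism.

## Cluster assignment

A query joins a sponge-specific (SC) or sponge/coral-specific (SCC) cluster
if its best hit (among the 10 retained) is in the cluster, exceeds 75%
identity (strict >) and no equally similar reference disagrees. Identity
ties with conflicting labels fall through to a majority rule: ≥ 60% of the
retained hits in the cluster and best in-cluster identity > 75%. "Top hits
disagree" is defined as ties-at-top with conflicting labels, the one place
the published rule under-specifies. Assignment is deterministic under row
permutation (re-ranked by identity, reference id as final tie-break).

## Phylogenetic signal

Blomberg's K = [MSE₀/MSE]_obs / [MSE₀/MSE]_BM with the phylogenetically
weighted mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), MSE₀ the ordinary variance about â,
MSE the V⁻¹-weighted version, and BM expectation
[tr(V) − n/(1ᵀV⁻¹1)]/(n−1); V holds shared root-to-ancestor path lengths.
The implementation matches picante's K to 10 decimals on a fixture.
Permutation P-values shuffle tips and use the never-zero estimator
(1 + #{MSE_perm ≤ MSE_obs})/(1 + n_perm). Mantel r is the Pearson
correlation of off-diagonal distances with joint row/column permutation of
the first matrix (one-sided, greater); the partial version residualizes both
matrices on the conditioning distances. Host identity enters partial tests
as a 0/1 same-species distance. When the conditioning matrix explains the
second matrix exactly, partial r is defined as 0.

## Synthetic-data generator

The generator's defaults are the study conditions the analyses are
validated under:

* **Degrees.** OTU host-degrees are drawn by inverse-CDF from the discrete
  law whose CCDF is the normalized truncated power law
  C(k) = k^−a e^(−k/b) / e^(−1/b), k ∈ [1, n_hosts], defaults a = 0.32,
  b = 7.44 hosts, 81 hosts. A CCDF is 1 at its minimum by definition while
  the analytic form is not, so refitting the unnormalized form to sampled
  CCDFs carries a small deterministic bias (≈ 11–13% median at 5000 OTUs,
  inside the 15% round-trip tolerance the generator is validated against).
* **Host assignment.** Each OTU's hosts are drawn without replacement with
  exponential host attractiveness weights, giving an exponential-like
  host-side degree distribution rather than a binomial one.
* **Classes and prevalence.** By default the class label follows from the
  drawn degree (specialist < 5, generalist > 50); replicate-level presence
  is Bernoulli at 0.9 for specialists/generalists and 0.2 for opportunists,
  emulating the observed prevalence dip at intermediate degree. The
  opportunist prevalence is a calibration knob with no generative claim
  behind it. Explicit class fractions switch to a stratified draw.
* **Counts.** Multinomial at fixed depth (default 20 000 reads) over the
  OTUs present in a replicate, with lognormal(0, 1.5) base abundances —
  column totals equal the requested depth exactly. Seawater samples mix
  exclusive background OTUs with a random 5% overlap of the host-associated
  pool at reduced weight.
* **LV series.** Forward simulation of the exact inference model: 100
  burn-in steps from n = log k, divergence guard |n| > 50 (both
  configurable), Poisson emission with the depth offset and a lognormal
  depth wobble of s.d. 0.1 — the diffuse s.d.-100 prior on Π is an
  *inference* prior; as a generative value it would overflow any count.
  Random sparse ground truths are rejection-sampled to have a positive
  equilibrium and spectral radius < 0.95, so recovery experiments never
  diverge.
* **Trees.** Yule trees (unit birth rate); the simulator stops at the event
  creating the n-th tip, which leaves two zero-length sister edges and a
  singular covariance, so every tip is extended by one further Exp(n)
  waiting time, keeping the tree ultrametric. Traits evolve by Brownian
  motion along branches or i.i.d. normal (no signal).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error and chimeras, biogeographic or
environmental covariates, taxonomy-structured abundances, and any
correlation between an OTU's host degree and its within-host abundance. The
last gap means synthetic cores are *not* generalist-enriched the way real
sponge cores are — core membership tracks abundance and prevalence, which
the generator draws independently of degree — so the core-versus-global
degree-enrichment curve is exercised on constructed cores in the tests, not
on end-to-end synthetic studies.

## Numerical and interface choices

* Strict inequalities at both filter thresholds; core prevalence uses
  ceil(0.85·M) (40 of 47) and the 1% abundance floor is inclusive (≥).
* Replicate ordering for the pseudo-time series defaults to sorted sample
  id; `given` and seeded `random` policies exist because the substitution
  makes any ordering equally defensible.
* Degree-fit tie-breaks and spline behaviour on ties are documented above;
  break-point scans (core enrichment) take the first crossing ascending.
* The CLI (`spongenet`) and the numbered analysis drivers are thin layers
  over the library; every computation lives in `src/spongenet/` where the
  tests and the acceptance script import it.
* Problem sizes in the test suite and acceptance script (e.g. 5000-OTU
  degree draws, S = 8 / M = 200 recovery, 5-species / 47-replicate
  calibration, 10⁵-step Lyapunov cross-checks) are chosen as the smallest
  sizes at which each statistical property is stable seed-to-seed.

## Known limitations

* Inference assumes the replicate series visits a stationary neighbourhood
  of a feasible equilibrium; doomed species (harmful load exceeding k)
  drift out of the model's support and their links are undetectable in
  principle.
* The absolute scale of k is set by its prior, not the data (offsets absorb
  totals); only ratios N*/k and the products entering J are data-identified.
* At very small S the compositional mirror mode can split posterior mass
  between observationally similar link placements; report inclusion
  probabilities, not a single hard network, when S ≤ 4.
* Variance shares use the diagonal-only attribution (J_ij² v_jj without
  cross-covariance terms); correlated noise between OTUs is attributed to
  stochasticity.
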