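# Methods

## Model and similarity measure

Let X be a D-dimensional multivariate normal vector with unknown covariance
Σ, observed through N i.i.d. samples and summarized by the sum-of-squares
matrix S = Σₙ(xₙ − μ)(xₙ − μ)ᵀ. Given Σ, S is Wishart(N, Σ). When the mean is
unknown, S is taken about the sample mean and N is replaced everywhere by
N − 1; we write N_eff for the count actually used.

For two disjoint clusters of variables X_i and X_j, two models are compared
on their union: M_D, where the joint covariance Σ_{i∪j} is unrestricted, and
M_I, where it is block-diagonal (X_i and X_j independent). With a conjugate
inverse-Wishart prior Σ ~ IW(ν, Λ) — density ∝ |Σ|^{−(ν+D+1)/2}
exp(−tr(ΛΣ⁻¹)/2) — both marginal likelihoods p(S|M) are available in closed
form, and the similarity is the log Bayes factor

    s(X_i, X_j) = ln p(S_{i∪j}|M_D) − ln p(S_{i∪j}|M_I)
                = Δφ_{i∪j} − Δφ_i − Δφ_j,

with

    Δφ_k = φ(N_eff + ν_k, Λ_k + S_k) − φ(ν_k, Λ_k),
    φ(n, A) = −(n/2) ln|A| + Σ_{d=1..dim(A)} ln Γ((n + 1 − d)/2).

Here ν_k = ν − D + D_k and Λ_k is the principal submatrix of Λ on cluster k:
the inverse-Wishart family is closed under marginalization with exactly this
parameter map, which makes the prior internally consistent across all levels
of a hierarchy. The same algebra yields the evidence of a whole partition,
and the evidence difference between two successive levels of a hierarchy
equals the similarity of the merged pair — merge values telescope.

Only evidence *differences* are exposed by the clustering interface. The
shared data constant |S|^{(N−D−1)/2}/Z(D, N) cancels in every difference and
is undefined when N_eff < D, while the differences stay finite because
Λ_k + S_k is positive definite whenever Λ is. This is what lets the method
run when the sample covariance matrix is singular. The absolute marginal
likelihoods are still implemented (for small, well-conditioned problems);
they exist so that Monte-Carlo integration over prior draws can validate the
closed forms, and the test suite does exactly that.

All evidence arithmetic is carried out in the natural-log domain; the
marginal likelihoods themselves overflow double precision already around
D ≈ 10. Log-determinants come from Cholesky factors; a factorization failure
is reported as-is, with no automatic jitter — silent regularization would
change the model being compared.

## Hyperparameters

Two stock priors are provided.

* **BayesCov** — ν = D, the smallest value giving a proper prior, and a
  diagonal Λ with Λ_dd = (ν − D + 1)/N_eff · S_dd = S_dd/N_eff, the diagonal
  scale maximizing the marginal likelihood of the all-singletons model. It
  adapts to the variances actually observed; Λ scales with the data squared,
  so results are invariant to units.
* **BayesCorr** — work on the sample correlation matrix (the sum of squares
  becomes N_eff · R̂), with ν = D + 1 and Λ = I. This prior's implied
  marginal distribution on every correlation coefficient is uniform on
  [−1, 1], verified in the tests by Kolmogorov–Smirnov on prior draws.

ν is stored as a real number; nothing in the evidence algebra requires it to
be an integer.

* **Bic** — the asymptotic (N → ∞) form of the log Bayes factor,

      s_bic = N_eff · Î − (D_i D_j / 2) ln N_eff,
      Î = ½ ln( |Ŝ_i| |Ŝ_j| / |Ŝ_{i∪j}| ),

  with Î the Gaussian plug-in mutual information. It has no hyperparameters
  and is identical on covariance or correlation input (the determinant ratio
  cancels any diagonal rescaling). Unlike the exact form it requires the
  relevant sample covariance blocks to be positive definite.

## Clustering algorithm and stopping

Agglomerative clustering starts from singletons and at each step merges the
pair with the largest similarity. When several pairs tie within 1e-12
(absolute), one is chosen uniformly at random from the supplied generator:
symmetric inputs produce genuine floating-point ties, and randomizing the
choice surfaces the instability instead of hiding it behind an arbitrary
scan order. Δφ values are cached per member set, so each step costs O(D)
new evidence evaluations.

Merging is worthwhile exactly while the best available similarity is
positive (the dependent model is the more probable one). The automatic
stopping rule therefore halts before the first merge whose best similarity
is ≤ 0; s = 0 means equal evidence, and not merging is the conservative
choice. Because merge values telescope into the partition evidence, the
stopped level is greedily the level of maximal marginal likelihood;
`best_partition` can also search all recorded levels directly (the default),
and the two coincide unless positive post-stop similarities sum back above
the running maximum — the tests check they agree in ≥ 95% of simulated runs.

Similarities need not decrease along the merge sequence, and the engine
never assumes monotone heights. Dendrogram export consequently uses the
merge step index as the node height; the true similarities are kept in the
merge table.

## Baselines, metrics, consensus

Mutual-information AHC uses Î directly (raw) or normalized by the joint
Gaussian differential entropy (Î/Ĥ_{i∪j}; Î/min(Ĥ_i, Ĥ_j) is available as an
option — the normalization convention is genuinely open in the literature,
and results that depend on it are treated as qualitative only). Linkage
baselines (single/average/complete/Ward) run on the dissimilarities 1 − |r|
or 1 − 0.5(1 + r) through the standard recursive updates; Ward is applied to
the supplied dissimilarity as is common when no feature vectors exist. The
random baseline merges a uniformly random pair at each step.

Partitions are compared by the raw Rand index, the adjusted Rand index
(chance-corrected under the permutation model; two identical degenerate
partitions score 1), and the proportion of correctly classified variables
under the optimal one-to-one cluster matching (Hungarian assignment on the
contingency table — the matching convention is a package choice, made
deterministic on purpose). Consensus clustering averages co-membership
indicators across an ensemble into a stability matrix and clusters
1 − stability with Ward's criterion. Benchmark methods are ranked
lexicographically by median ARI, then its 25th and 5th percentiles, the
minimum, and mean accuracy.

## Synthetic-data generator

One benchmark replication draws: (1) a partition of the D variables into
exactly C blocks, uniform over all S(D, C) set partitions via the Stirling
recursion S(D, C) = S(D−1, C−1) + C·S(D−1, C); (2) a block-diagonal
correlation matrix whose blocks are inverse-Wishart(D_k + 1, I) draws
rescaled to unit diagonal — the construction whose correlation coefficients
have uniform marginals on [−1, 1] for every block size (a plain Wishart draw
with the same degrees of freedom has uniform margins only for 2×2 blocks;
the uniformity property, not the sampling recipe, is the design contract,
and it is asserted by KS tests); (3) N observations, multivariate normal
with that correlation matrix, or elliptical multivariate Student-t (normal
divided by a per-sample √(χ²_ν/ν), which runs even at ν = 1 where the
covariance does not exist). Each dataset is summarized by its sample
covariance/correlation with N_eff = N − 1; methods with an oracle cluster
count are cut at the true C, auto-stopping variants keep their own stopped
partition, and auto-stopped hierarchies are never cut at a fixed K.

The default grid is deliberately desk-scale: D = 6, N ∈ {10, 90, 170, 250},
C = 1..6, normal and Student-t(3) families, 50 replications per cell — a
reduced version of the full design (500 replications, D up to 40) that keeps
a complete benchmark run around a minute on one core while leaving every
qualitative conclusion intact. The C = 1 and C = D cells are included in the
pooled evaluation by default and can be excluded by flag. One root seed
spawns independent per-replication substreams, so the result table is
bit-identical across runs with the same configuration and seed.

What the generator does *not* emulate: unequal variances across variables
(blocks are correlation matrices; BayesCov's variance-adaptive prior is
exercised only through sampling noise), non-zero means beyond the N − 1
correction, serial dependence, and any within-block correlation structure
other than the exchangeable-by-construction inverse-Wishart draw. Passing
benchmarks therefore demonstrate recovery of block-diagonal dependence
under these conditions, not robustness to, e.g., autocorrelated or
heteroscedastic real-world data.

## Numerical choices and degenerate inputs

* Symmetry of matrix inputs is enforced once at construction as (A + Aᵀ)/2,
  with asymmetries above 1e-12 (relative) rejected — tolerant of I/O
  round-trip noise, intolerant of genuinely asymmetric input.
* Î is clipped at zero; values below −1e-12·D_{i∪j} raise, as determinant
  round-off cannot explain them.
* |r| = 1 in a summary table is accepted: the reconstructed covariance is
  only positive semi-definite, but Λ + S remains positive definite and the
  exact similarities stay finite.
* Constant variables (zero sum-of-squares diagonal) are rejected when
  constructing the BayesCov prior.
* Uniform partition sampling compares a uniform deviate against ratios of
  exact integer Stirling numbers converted to double; for D ≤ 40 the
  relative conversion error is ~1e-16 and irrelevant at any testable number
  of draws.

## Toy data

The packaged 6-variable summary table (variances on the diagonal, sample
correlations below, partial correlations above — retained for fidelity,
unused) describes blood measurements from a study of early HIV diagnosis in
n = 107 children: immunoglobulins G and A (x1, x2), lymphocytes B and T4
(x3, x5), the T4/T8 ratio (x6) and the platelet count (x4). On these data
the exact Bayes measures merge the lymphocyte pair {x3, x5} first, the
immunoglobulin pair {x1, x2} second, then attach x6 to the lymphocyte group,
and with automatic stopping select the two-cluster partition
{x1, x2, x3, x5, x6} | {x4}, keeping the platelet count apart.

## Known limitations

* The inverse-Wishart prior couples variances and correlations; priors that
  separate the two would be preferable in principle but destroy the closed
  form.
* Similarities are Gaussian model comparisons; heavy-tailed data are handled
  only in the sense that the benchmark shows graceful degradation under
  Student-t sampling, not by a heavy-tailed likelihood.
* The BIC form needs positive definite sample covariance blocks and so
  cannot run when N_eff is smaller than the largest cluster union
  encountered; the exact forms have no such restriction.
* The greedy merge path is a heuristic; nothing guarantees the globally
  best partition at a given cluster count.
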