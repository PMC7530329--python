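# Methods

`cernet` infers a disease-associated lncRNA–mRNA network from paired
tumor/normal expression profiles and miRNA–target interaction tables, under
the competing-endogenous-RNA (ceRNA) hypothesis: transcripts sharing many
miRNA binding partners can regulate one another by competing for those
miRNAs. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Pipeline model

1. **Probe annotation.** Probe–transcript alignment hits (BLAST outfmt-6
   style) are filtered to perfect matches — match length equal to the probe
   length (default 60 nt) *and* 100% identity, since a "perfect match" of
   full length implies no mismatches. Three criteria are then applied in
   order: (1) probes hitting both a protein-coding and a lncRNA transcript
   are removed; (2) within each class, probes hitting more than one
   transcript are removed; (3) only transcripts supported by **more than
   three** (i.e. ≥ 4) surviving probes are kept. Criterion (3) counts probes
   after (1)–(2); the alternative (counting before) is not offered because
   the filtered mapping must be self-consistent (idempotent under
   re-filtering). Probe-level expression collapses to transcript level by
   the per-sample **median**, which tolerates one aberrant probe among the
   ≥ 4 supporters.

2. **Differential expression.** For transcript *g* with tumor−normal
   differences *x₁…x_k* over *k* patient pairs,

       d_g = mean(x) / (se_g + s0),   se_g = sd(x)/√k.

   The fudge constant *s0* is the 5th percentile of the se distribution — a
   simpler, fully documented alternative to the coefficient-of-variation
   grid search sometimes used for this statistic; it is exposed as a
   parameter and can be overridden. The null is built by flipping the sign
   of each pair's difference independently (the exact null for a paired
   design under symmetry), recomputing *d* in full per permutation, and
   pooling |d| across transcripts and permutations, which stabilizes tail
   estimates. Raw p = fraction of pooled null |d| ≥ observed |d| (no
   pseudo-count; p = 0 is reachable by design). "Adjusted p" is
   Benjamini–Hochberg over transcripts; transcripts with adjusted p < 0.01
   are declared differential, split into lncRNA and mRNA sets.

3. **Triple network and ceRNA pairing.** The two bipartite interaction
   tables merge into a global lncRNA–miRNA–mRNA network; restricting the
   gene layers to the DE sets (miRNAs keep only incident edges) gives the DE
   triple network. Every DE lncRNA–mRNA pair sharing at least one miRNA is
   scored by the upper-tail hypergeometric probability of sharing ≥ r
   partners given partner counts t (mRNA) and n (lncRNA) in a universe of m
   miRNAs. Choices:
   * the sum is computed in log space (`gammaln` + `logsumexp`) so large
     (t, n, m) do not overflow;
   * pairs with r = 0 are excluded before testing — they cannot be ceRNA
     partners, their p is identically 1, and scoring them would only dilute
     the FDR correction;
   * t, n, r are counted on the **global** network by default (m is global,
     so partner counts should live in the same universe); counting on the DE
     network is available via the `count_network` argument;
   * m defaults to the number of distinct miRNAs in the counting network and
     can be overridden when the tables are a subset of a larger database;
   * BH correction over all scored pairs; results ordered by
     (p, lncRNA id, mRNA id) so ties break deterministically.
   Pairs with adjusted p < 0.01 form the bipartite disease lncRNA–mRNA
   network (e.g. an LCLMN in the lung-cancer setting); nodes exist only by
   touching a significant edge.

4. **Topology.** Degree, betweenness and closeness on the undirected
   unweighted network. Both centralities are **unnormalized**: betweenness
   sums σ_st(v)/σ_st over unordered pairs s ≠ v ≠ t (halving or doubling is
   a global scale and cannot change rankings), and closeness is the
   reciprocal of the summed distances 1/Σ_j d(j, v) — not the (n−1)-scaled
   variant. On disconnected graphs closeness sums over the reachable set
   only and betweenness counts within-component pairs; the textbook formula
   is undefined for infinite distances so this is the natural completion.
   Hub candidates are nodes in the top-k (default 10) of all three rankings
   simultaneously, filtered to lncRNAs; ties at the k-th value are included
   rather than arbitrarily cut.

5. **Random walk with restart.** p_{t+1} = (1−r) W p_t + r p_0 with W the
   column-normalized adjacency matrix, restart probability r = 0.5, p_0
   uniform over the seed genes, iterated until the L1 difference falls below
   1e-10 (the metric is unstated in most formulations; L1 pairs naturally
   with probability vectors) with a safety cap of 10 000 iterations.
   Significance per candidate lncRNA is empirical: pseudo-seed sets of the
   observed size are drawn uniformly **without replacement** from the mRNA
   nodes, the walk reruns on the fixed graph (topology strictly preserved),
   and perm_p = m/n where m counts permutations whose score **strictly
   exceeds** the observed one (no +1 correction, so perm_p = 0 is
   reachable). A degree-preserving bipartite edge-rewiring null is provided
   as an alternative (`perm_method="rewire"`) since "randomly disturbing"
   a network can reasonably mean either; seed resampling is the default.
   Seed genes absent from the network are dropped with a warning.

6. **Co-expression modules.** Every network edge is screened by Pearson
   correlation on log2 values over **all** samples (tumor and normal
   pooled — the correlation then reflects both co-regulation and shared
   disease response; a tumor-only screen is a trivial caller-side subset).
   The two-sided p comes from t = r√((n−2)/(1−r²)) with n−2 df. Strict
   thresholds r > 0.6 and p < 0.05; **no** multiple-testing correction is
   applied at this stage by design (the screen is a descriptive filter on
   an already FDR-controlled edge set). A lncRNA's ceRNA module contains
   its retained mRNAs plus exactly the miRNAs adjacent in the global triple
   network to the lncRNA and to ≥ 1 member mRNA, with both edge layers.

## Synthetic data

The generator supplies the statistical structure the pipeline assumes, with
planted truth for recovery tests.

* **Expression**: log2 values are `baseline + shift·1[tumor] + α + ε` with
  baseline ~ N(6, 1) (typical log2 intensity of a two-channel array),
  α ~ N(0, (0.5·noise_sd)²) a per-transcript per-patient intercept shared by
  the two samples of a pair (this is what the paired statistic gains over an
  unpaired one), and ε ~ N(0, noise_sd²). Exactly round(frac_de · rows) rows
  get a tumor shift of ±de_effect, directions split evenly. Defaults:
  20 patient pairs (40 arrays), 60 lncRNAs + 240 mRNAs, noise_sd = 0.5,
  de_effect = 1.5 (a 2.8-fold change, comfortably detectable at k = 20 but
  not trivial at k = 10), frac_de = 0.25.
* **Planted co-expression**: pair members share the patient intercept and
  shift direction, and their residual noise is correlated by exactly the
  amount ρ′ that makes the pooled-sample population correlation equal
  coexpr_r, solving (d²/4 + s_α² + ρ′σ²)/(d²/4 + s_α² + σ²) = coexpr_r and
  clipping ρ′ to [−1, 1] (if clipping binds, the target is unreachable
  under the chosen effect/noise and the achieved correlation is the
  maximum). Planted pairs are a matching (distinct lncRNAs × distinct
  mRNAs) so this algebra stays exact; members are drawn from the
  DE-candidate rows so pairs survive the DE-mapping stage. With
  de_effect = 0 the DE truth sets are empty (there is nothing to detect)
  while co-expression planting still uses the candidate rows.
* **Interactions**: each gene–miRNA edge is present independently with
  probability background_degree/n_mirna (mean degree = background_degree;
  total edges binomial), and each planted pair receives shared_mirna_boost
  common miRNAs on top. Defaults boost = 6 over background 5 in a 150-miRNA
  universe: the planted overlap (≥ 6) is far in the tail of the background
  overlap (mean ≈ deg²/n_mirna ≈ 0.17).
* **Probe hits**: a structural fixture covering every filtering branch
  (unique hits, cross-class probe, within-class multi-target probe, 3- vs
  4-probe support, 59- vs 60-nt matches, sub-100% identity), with the
  intended surviving probe and transcript sets logged for exact comparison.

**What the generator does not emulate**: scanner/dye artifacts,
probe-sequence-driven cross-hybridization, heavy-tailed or
intensity-dependent noise, correlated background interaction structure
(miRNA families, target hubs), or realistic degree distributions. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under its own model assumptions, not performance on real
microarray data.

## Problem sizes and numerics

Tests and the acceptance script run the generators at their defaults
(300 transcripts, 20–40 samples, 150–200 miRNAs) and use 200–1000
permutations for the DE null and 200–5000 for the walk null; the exact
enumeration oracles cap at a 12-miRNA universe (hypergeometric) and 8 pairs
(2⁸ sign flips), where brute force is instant and exact. Degenerate inputs
are errors, not silent results: empty hit tables, single-pair designs,
constant vectors in the correlation screen, seed sets absent from the
network, and m smaller than an observed partner count all raise with a
named cause. An all-constant expression matrix yields s0 = 0 with a
warning.

## Known limitations

* The hypergeometric test treats miRNA partners as exchangeable; it ignores
  interaction strength and miRNA expression.
* BH is applied to discretely distributed permutation p-values, which is
  conservative at small permutation counts.
* The permutation null for the walk resamples seeds among mRNA nodes only;
  if the true seeds are atypical mRNAs (e.g. hubs), the null is against
  "random mRNA gene sets", not "random gene sets of matched degree" — the
  rewiring alternative addresses the complementary question.
* Closeness values on large networks are tiny (order 1/Σd); rankings, not
  magnitudes, are the intended product.
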