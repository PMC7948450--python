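# Methods

## Substitution model and likelihood

Protein evolution is modelled as a reversible continuous-time Markov chain
on the 20 amino acids (fixed order `ARNDCQEGHILKMFPSTWYV`). The rate matrix
is assembled from the LG exchangeabilities `S` and equilibrium frequencies
`π` as `Q_ij = S_ij π_j` (i ≠ j), diagonal set so rows sum to zero, then
rescaled so `−Σ_i π_i Q_ii = 1`; branch lengths are therefore expected
substitutions per site. The LG constants are vendored in
`src/ancres/data/lg.dat` (PAML lower-triangle format). Two frequency modes
are supported: the matrix's own frequencies, or observed alignment
frequencies (+F) computed gap-free with a 1e-6 pseudocount so no state has
zero frequency (which would break reversibility). Alignment-wide +F is the
default for the pipeline.

Among-site rate variation uses the discrete-gamma approximation: a
unit-mean gamma with shape α is cut into K equal-probability bins
(default K = 4) and each category's rate is its bin's **conditional mean**,
computed analytically from regularised incomplete-gamma differences —
chosen over bin medians because the category mean is then exactly 1 for any
α. For α = 1, K = 4 this gives 0.1370, 0.4768, 1.0000, 2.3863.

Transition matrices `P(t) = exp(Qrt)` come from one eigendecomposition of
the symmetrised generator `D^{1/2} Q D^{−1/2}` (D = diag π), which is exact
and stable for any branch length; entries are clipped at zero and rows
renormalised to absorb round-off.

Likelihoods use Felsenstein's pruning algorithm, vectorised over sites,
with per-node per-site log scaling factors rather than extended-precision
arithmetic. Gaps and unknown residues are missing data (all-ones tip
vectors): an all-gap column contributes exactly zero log-likelihood, and
indels are handled by a separate parsimony analysis (below). Branch lengths
are taken as given — tree inference and branch-length optimisation are out
of scope — but the gamma shape can be re-estimated by bounded 1-D search
(Brent, bracket 0.02–20, xatol 1e-4), which is deterministic.

## Marginal ancestral reconstruction

Posterior state distributions at an internal node are computed by virtually
rerooting the tree at that node (valid under reversibility) and combining
the conditional likelihoods of the subtrees hanging off it:

    p(a | site) ∝ Σ_k w_k π_a Π_c [P(r_k t_c) L_c](a),

normalised per site. This is marginal (per-node) empirical-Bayes
reconstruction, mixing gamma categories by their per-site likelihood
weight; joint reconstruction and posterior sampling are deliberately not
implemented. Targets are addressed by internal-node label or as the MRCA of
a taxon list.

Conventions, stated because summaries depend on them:

* the ML ancestral state is the per-site posterior mode, ties broken toward
  the lower alphabet index;
* a site is *ambiguous* when any non-best state has PP strictly above the
  threshold (default 0.2); when more than one state clears it, the
  alternative ancestor substitutes the **second-best** state only, and the
  full over-threshold list is kept in the report;
* the **overall PP** of an ancestor is the arithmetic mean of per-site
  best-state PPs over sites inferred present (columns the indel analysis
  resolves absent are excluded from the sequence, the ambiguity set, and
  this mean);
* percent identity between aligned sequences skips gap–gap columns, counts
  gap–residue as a change, and is rounded to one decimal.

## Indel handling

Gap structure is recoded as binary presence/absence characters: each
maximal run of columns with an identical per-taxon gap pattern is one
character (per-column coding is available behind a flag; the block coding is
a design choice, since indel events usually insert or delete whole
segments). Ancestral states come from the standard two-pass Fitch algorithm
(unordered, equal costs). An ambiguous `{0, 1}` set at the target node is
resolved toward presence — a stated convention that favours retaining
clade-typical segments such as C-terminal extensions — and the tie is
flagged so downstream users can see it. The minimum change count from the
bottom-up pass is exact on bifurcating trees (verified against exhaustive
enumeration up to six leaves).

## Kinetics

Steady-state data are fitted by unweighted nonlinear least squares to
`v = k_cat[S]/(K_M+[S])` (replicates pooled; weighting optional in
principle but not default, as replicate structure rarely warrants it at
n = 3). Initial guesses are data-driven — k_cat from the maximum observed
rate, K_M from the concentration nearest half-maximum — which makes the
optimiser insensitive to starting-point choices. When the fitted K_M falls
below the lowest assayed concentration the point estimate is not
identifiable from the design, so the fit is flagged censored and K_M is
reported as `"<c_min"`; catalytic efficiency then becomes a lower bound.
k_cat/K_M is reported in s⁻¹M⁻¹ rounded to 2 significant figures, the
precision kinetics tables print. Absorbance slopes (ΔA₃₄₀/min) convert to
rates via Beer–Lambert with ε(NADPH) = 6.22 mM⁻¹cm⁻¹ and a 1-cm path by
default.

Stopped-flow traces are fitted as single exponentials
`A(t) = amplitude·e^(−k_obs t) + offset` (initial rate from the
half-amplitude time); multi-phase fitting is out of scope because the
oxidative half reaction of the motivating enzymes shows no resolvable
intermediate. A fitted k_obs above π/Δt (the sampling limit) or a flat
trace is flagged rather than reported. The k_obs saturation across coenzyme
concentrations is the same hyperbolic fit, yielding k_red and K_d.

## Synthetic data

The generators emulate the study conditions the analysis expects:

* **Alignments** evolve site-by-site down the tree from equilibrium root
  states; each site draws one of the K discrete rates uniformly — exactly
  the mixture the likelihood assumes, so calibration tests are exact-model
  tests. True sequences at every internal node and per-site category draws
  are recorded. Benchmarks default to 16 taxa × 2000 sites (calibration)
  and 500 sites (recovery) at mean root-to-tip height 0.5
  substitutions/site and α = 0.7 — a moderate divergence regime typical of
  within-class protein-family reconstructions, sized to keep the full suite
  fast while leaving binomial noise well inside the tolerances tested.
* **Indel characters** evolve under a two-state gain/loss CTMC with the
  root at stationarity.
* **Kinetic data** use multiplicative Gaussian noise for rates (assay error
  scales with signal; default CV 5%) and additive Gaussian noise for
  photometric traces; default steady-state designs span 2.5–1000 µM
  substrate in triplicate.

Every generator is a pure function of (parameters, seed): same seed, same
bytes. What passing tests show is fidelity *under the model*: simulated
alignments have no alignment error, no compositional heterogeneity, no
site-specific rate profiles or covarion behaviour, and indel blocks are
independent characters — so calibration results transfer to real data only
to the extent the model fits it.

## Numerical and design choices

* Curation thresholds are strict inequalities for identity and coverage
  (>55, >80) and "≤" for the E-value cap, so the default 0.0 cap reproduces
  exact-zero collection while the flag stays usable; length keeps ≥510;
  deduplication is exact string equality after uppercasing, no clustering.
  Filter order is length → deduplicate, configurable.
* Likelihood/posterior agreement with exhaustive enumeration is tested to
  1e-10 on trees up to 4 tips; rerooting invariance to 1e-8.
* Unlabelled internal nodes get deterministic preorder labels `N1, N2, …`;
  alignment columns are 1-based in every report; sequence output is
  uppercase.
* The random-tree generator joins subtrees sequentially with exponential
  branch lengths rescaled to a target mean root-to-tip height; it is
  deterministic in the seed and independent of any library sampler.

## Known limitations

* Marginal reconstruction only; no joint reconstruction, no sampling from
  the posterior, no dating.
* No tree search or branch-length optimisation; the phylogeny is an input.
* Fitch parsimony's change count is exact on bifurcating trees;
  multifurcations are accepted but counts there are the classical Fitch
  heuristic.
* Kinetic fits are single-phase and unweighted; no global multi-wavelength
  fitting, no mechanistic multi-step cycle models.
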