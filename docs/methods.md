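# Methods

`cmphelix` implements a closed design–build–test–learn loop for discovering
thermostable collagen-mimetic peptoid (CMP) triple helices, together with the
post-processing analyses that interpret a finished campaign.  This note
records the models, the parameters that matter, the numerical choices, and
the limits of what the synthetic stand-ins can demonstrate.

## Design space

Candidates are 18-mer peptoids built from three repeats of a hexamer
`x1-y1-Gly-x2-y2-Gly`.  The x slots admit the five residues carrying a formal
charge at or near physiological pH (NLys, Nae, NCys, NAsp, NGlu; NCys is
grouped with them but modeled neutral, since its thiol is only ~11%
deprotonated at pH 7), and the y slots admit twenty peptoid residues.  The
combinatorial space is therefore 5² × 20² = 10 000 hexamer codes, enumerated
in lexicographic order so that every index, seed and audit entry is
reproducible.  Glycine is fixed at slots 3 and 6 to permit the close strand
packing of the triple helix.

Molecular graphs are assembled residue-by-residue as N-substituted glycine
units with the side chain bonded at the backbone nitrogen (proline closes a
pyrrolidine ring onto the alpha carbon).  Two conventions are fixed by the
package rather than inherited from data:

* the fingerprinted fragment is the *hexamer repeat*, terminated with an
  N-terminal hydrogen and a C-terminal primary amide;
* protonation at pH 7 follows the palette charges (ammonium NLys/Nae,
  carboxylate NAsp/NGlu, neutral NCys thiol, N-delta tautomer for NHis).

Both choices only need to be applied consistently for the embedding to be
meaningful; changing them shifts the principal components but not the
mechanics of the loop.

## Fingerprints and embedding

Each hexamer is encoded as a binary 2048-bit atom-pair fingerprint: every
unordered pair of heavy atoms within 1–5 covalent bonds contributes the
canonical tuple *(descriptor(a), descriptor(b), distance)*, hashed with
64-bit FNV-1a modulo 2048.  The atom descriptor is *(element, formal charge,
hybridization class, in-ring flag, heavy-atom degree)*; hybridization is
derived from the bonding pattern alone (triple bond or cumulated double
bonds → sp, aromatic or one double bond → sp², otherwise sp³).  Including
the heavy-neighbor count in the descriptor follows the atom-type definition
of the classic atom-pair fingerprint.  FNV-1a is a documented, stable,
non-cryptographic hash, so fingerprints are bit-identical across platforms
and processes.

The 10 000 × 2048 fingerprint matrix is reduced by mean-centered PCA
(covariance eigendecomposition — exact and deterministic; no unit-variance
scaling, which would be inappropriate for binary features).  The top ten
components capture 75.1% of the library variance under the conventions
above, and the 10-D scores are the only representation the surrogate ever
sees.

## Melt calling

A candidate's stability signal is the melting temperature Tm read off a
temperature-ramp denaturation trajectory (320 K start, 1 K/ns, frames every
20 ps).  Two event types are detected from the per-frame observables:

* **collapse** — the minimum over strands of the radius of gyration falls
  below 1.25 nm and stays below it for at least 200 ps;
* **dissociation** — any inter-strand central-residue distance reaches 2 nm
  for at least 200 ps.

The earlier onset wins and Tm is the ramp temperature at the *first* frame
of the sustained run; anchoring at onset rather than at the end of the
sustain window changes Tm by at most 0.2 K at 1 K/ns.  Trajectories with no
sustained event are censored at the final frame and excluded from replicate
means (the censoring count is reported).  Replicates (six per sequence by
default) are aggregated into a mean and standard error; a single surviving
replicate gets SE = 0 and downstream consumers apply a 1 K noise floor so
the surrogate's noise matrix stays well conditioned.

## Surrogate model

The surrogate is an exact Gaussian process from the 10-D embedding to Tm
with an anisotropic RBF kernel — one length scale per component plus a
signal variance — optimized by marginal-likelihood maximization (L-BFGS, 5
random restarts, fixed seed).  Replicate noise enters as a fixed
heteroscedastic diagonal (SE² per training point, the variance reading of
"adding the standard errors to the kernel matrix", which is the
mathematically consistent one).  Targets are standardized and inputs scaled
per dimension before optimization; hyperparameters are reported in natural
units, so the fitted model is exactly

    Tm(x) ~ GP( ybar , s² exp(−Σ_d (x_d − x'_d)²/(2 l_d²)) ) + N(0, se_i²).

A Cholesky failure triggers jitter escalation (1e-8 → 1e-4) before a
`SingularKernel` error.  The numerical fit is delegated to scikit-learn's
`GaussianProcessRegressor`; the package adds the standardization contract,
the heteroscedastic-noise plumbing, cross-covariance evaluation for batch
acquisition, and the fixed-hyperparameter path used by closed-form oracles.

## Acquisition and campaign protocol

Selection is batched q-Expected-Improvement over the discrete library:

    qEI(B) = E[ max( max_{x∈B} f(x) − (f* + β), 0 ) ],

estimated by Monte Carlo (512 draws by default) under the joint posterior
over the batch.  β shifts the incumbent threshold: β = 0 is the balanced
explore/exploit setting, and β = −f* moves the threshold to zero — pure
exploitation, which ranks candidates essentially by posterior mean.  Batches
of q = 8 are built greedily over the unevaluated pool with common random
numbers (one normal matrix per round; column j drives batch slot j), and
exact value ties break lexicographically by hexamer code.  Greedy
construction with CRN is the standard tractable approximation to joint qEI
on a finite library; no continuous optimizer is involved.

The campaign protocol: Round 0 draws 26 candidates uniformly at random;
each of up to 24 subsequent rounds refits the surrogate on everything
evaluated so far and selects 8 new candidates — β = 0 through round 18,
β = −Tm_max afterwards.  The stagnation rule (no strict improvement of the
top-8 mean Tm for 4 consecutive rounds) is armed only in the exploitation
phase; during the balanced phase a stalling top-8 mean is the expected
signal for *switching* strategy, not stopping, so the balanced phase always
runs its fixed schedule.  A full campaign therefore evaluates
26 + 24 × 8 = 218 candidates (2.18% of the library) unless exploitation
stagnates early.  All randomness descends from a single seed through spawned
seed sequences; reruns are byte-identical, and the audit log records every
selection with its replicate Tms, β, and running top-8/top-16/best summaries.

## Free-energy post-processing

Equilibrium stability of a finished candidate is the free-energy difference
ΔF between the triple-helix and denatured basins along a learned reaction
coordinate.

**TICA.**  The coordinate is the leading time-lagged independent component
of per-frame feature vectors (pairwise alpha-carbon distances in the
original protocol), obtained from the symmetrized generalized eigenproblem
C(τ)v = λC(0)v on mean-free features with a relative diagonal
regularization of C(0) (1e-10 of the mean variance).  Eigenvalues are
clipped into (0, 1]; the default lag is the 1 ns-equivalent of the frame
spacing and is configurable.

**WHAM.**  Umbrella windows (42 uniformly spaced centers, 1000 kJ/mol
force constants by default) are combined by iterating the standard
self-consistency equations in log space until the largest window
free-energy change is below 1e-7 kT (at most 1e5 iterations), at 320 K with
1 kcal = 4.184 kJ.  Histograms use 100 bins over the sampled range; bins no
window visited are masked, never interpolated, and a window sharing no
occupied bin with any other raises a diagnostic (`NoOverlap`) rather than
being silently bridged — adding intermediate windows requires new sampling
and is the caller's decision.

**ΔF extraction.**  The PMF is smoothed with a 5-bin moving average; local
minima separated by a barrier of at least 0.5 kcal/mol qualify as basins.
The helix basin is the lowest-coordinate qualifying minimum, the denatured
basin the highest-coordinate one, and ΔF = F(denatured) − F(helix) (point
minima, read from the unsmoothed profile near the smoothed location), so
positive ΔF means the helix is more stable.  Uncertainties come from five
bootstrap replicates that resample every window with replacement and rerun
the full reconstruction; the reported point estimate always uses the
unresampled data.

## Composition analysis

Campaign results are screened with Spearman rank correlations (average
ranks for ties, large-sample t p-values) of Tm against the number of
charged residues, the number of hydrophobic residues (the ten-residue set
NPhe, NIle, NLeu, NVal, NTrp, NTyr, Nbrpe, Nbrpm, Ntbu, Nspe), and each
residue's count.  A linear residue-count model
`Tm ≈ c + Σ_i α_i C_i` is fit by minimum-norm least squares: the counts
always sum to four, making the design exactly collinear with the intercept,
so individual coefficients are identifiable only up to that null space
while predictions, RMSE and the rank correlation of fit are unaffected.
Both metrics are in-sample by design.  Gly and Pro are excluded from the
counts (constant per hexamer).

The packaged 13-row stability table (five top screened sequences, two
negative controls, five PPG-flanked engineered variants, one natural
collagen control) supports the Tm-vs-ΔF concordance analysis.  The collagen
control is excluded from the rank correlation as a kinetic-trapping
outlier.  Note the table carries values at printed precision, which
includes two exact ties; average-rank Spearman on it gives 0.54, about 0.03
below the value obtained from unrounded data.

## Synthetic stand-ins and what they show

The `synth` module replaces the MD engine at desk scale:

* **Tm oracle** — latent Tm = 370 K + 12 K per NLys/NGlu, +6 K per light
  hydrophobe (NPhe/NLeu/NTyr/NIle), −10 K per Ntbu/NTrp/Nbrpm/Nbrpe, −8 K
  per Nae, plus a 6 K salt-bridge-style bonus per co-occurring
  (NLys, NGlu/NAsp) pair.  The landscape spans 334–430 K over the library
  and replicate noise of 8 K SD over six replicates gives standard errors
  of a few K, matching the dispersion the ramp protocol produces.  With
  these effect signs the library-wide rank correlation between latent Tm
  and the charged-residue count is +0.29 — positive but diluted, because
  NAsp contributes nothing and Nae destabilizes by construction.
* **Ramp trajectories** — stationary OU noise around helix baselines
  (Rg 1.6 nm, pair distance 1.2 nm) until an assigned event temperature,
  then exponential relaxation (0.3 ns) into the collapsed (1.0 nm) or
  dissociated (2.8 nm) value; the detector recovers the assigned T* to
  within a few K (relaxation lag plus OU jitter).
* **Biased Langevin sampling** — Euler–Maruyama with unit mobility.  The
  defaults (dt = 2e-5, recording every 60 steps, 2000-step burn-in) keep
  the integrator's stationary-variance inflation (≈ κ·dt/2 for total
  curvature κ ≈ 1000 kJ/mol) near 1% and make recorded samples nearly
  independent, so WHAM profiles are accurate and bootstrap uncertainties
  honest.  On the built-in tilted double well the reconstructed ΔF agrees
  with the quadrature value of the analytic potential within bootstrap
  error across seeds.

These generators reproduce the *statistical* features the detectors and
estimators consume — landscape structure, replicate noise, event
phenomenology, biased sampling distributions — not the physics behind
them.  Passing tests therefore demonstrate that the loop's inference
machinery is correct and that the campaign logic extracts a learnable
landscape efficiently; they say nothing about force-field accuracy, real
denaturation kinetics, or the transferability of the composition effects
encoded in the oracle.

## Problem sizes and known limitations

The shipped test and reproduction runs use the full 10 000-member library
for enumeration, fingerprinting, embedding and the default campaign
(26 + 24 × 8 evaluations), and 400-candidate sub-libraries for repeated
campaign-vs-random comparisons; umbrella validation uses 42 windows × 2500
recorded samples.  Known limitations: coefficients of the composition model
are reported only up to the count-sum null space; WHAM assumes samples
within a window are equilibrated and uncorrelated (the generator thins to
approximate this; real data should be thinned by the user); the PMF basin
finder uses point minima rather than Boltzmann-integrated basin weights;
and the supplementary per-candidate campaign table of the original study is
not redistributed here — analyses that need it accept a local copy at
`data/marc70225-sup-0002-TableS1.csv`.
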