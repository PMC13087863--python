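# cmphelix

Active-learning design of thermostable collagen-mimetic peptoid triple
helices.

Collagen owes its mechanical role to a triple helix built from a repeating
x–y–Gly motif.  Replacing the x/y amino acids with peptoid residues
(N-substituted glycines) brings proteolytic resistance and a huge palette of
non-natural side chains, but also extra backbone flexibility that
destabilizes the helix — so the design question is which side-chain
chemistries buy the stability back.  `cmphelix` is a toolkit for answering
that question with a simulation-driven active-learning loop, for
computational chemists and biomaterials designers who want to run, audit, or
extend such a campaign without standing up a molecular-dynamics cluster:
the MD stages are replaced by synthetic engines with known ground truth, so
every statistical component of the loop runs and is testable at desk scale.

## What it implements

* **Design space** — the combinatorial library of hexamer repeats
  `x1-y1-G-x2-y2-G` (5 charged x-residues × 20 y-residues at two slots each
  = 10 000 candidates), with validated sequence codes, RDKit molecular
  graphs and composition descriptors.
* **Featurization** — binary 2048-bit atom-pair fingerprints of the hexamer
  repeat (heavy-atom pairs within 5 bonds, stable FNV-1a hashing) and a
  10-component PCA embedding; the top ten PCs capture 75% of the library
  variance.
* **Surrogate** — exact GP regression Tm(x) with an ARD-RBF kernel,
  `Tm ~ GP(ȳ, s²·exp(−Σ_d Δx_d²/2l_d²))`, heteroscedastic replicate noise
  (SE² on the diagonal), marginal-likelihood hyperparameter optimization.
* **Acquisition** — batched q-Expected-Improvement over the discrete
  library, `qEI(B) = E[max(max_{x∈B} f(x) − (f* + β), 0)]`, with greedy
  batch construction under common random numbers and the two-phase β
  schedule (β = 0 explore/exploit, then β = −Tm_max pure exploitation).
* **Melt calling** — Tm from temperature-ramp observables: first sustained
  (≥ 200 ps) strand collapse (min Rg < 1.25 nm) or strand-pair dissociation
  (distance ≥ 2 nm) under a 1 K/ns ramp from 320 K; replicate aggregation
  with standard errors.
* **Free energies** — TICA reaction coordinates, WHAM reconstruction of the
  potential of mean force over umbrella windows, basin extraction
  (ΔF = F(denatured) − F(helix)) and bootstrap uncertainties.
* **Composition analysis** — Spearman screens and the residue-count
  regression `Tm ≈ c + Σ_i α_i C_i`, plus the Tm-vs-ΔF concordance analysis
  over the packaged 13-sequence stability table.
* **Synthetic engines** — a composition-driven Tm oracle, OU-based ramp
  trajectories with assigned melt temperatures, and biased Langevin
  sampling of analytic potentials, standing in for the MD stages.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from cmphelix import enumerate_library, palette, fingerprint, synth
from cmphelix.acquire import run_campaign
from cmphelix.compose import fit_composition_model, tm_deltaF_concordance

lib = [s.hexamer_code for s in enumerate_library()]
print(f"library size: {len(lib)}")

mols = [palette.sequence_to_molgraph(c) for c in lib]
fps = fingerprint.fingerprint_matrix(mols)
model = fingerprint.fit_embedding(fps)
print(f"top-10 PC variance captured: {model.explained_variance_fractions.sum():.3f}")

coords = fingerprint.embed_matrix(fps, model)
params = synth.OracleParams(seed=1)
state = run_campaign(lib, coords, lambda c: synth.oracle_tm(c, params), seed=1)
print(f"evaluated {len(state.evaluated)} candidates over {state.round_index} rounds")
print(f"best observed Tm: {state.Tm_max:.1f} K   top-8 mean: {state.top_mean(8):.1f} K")

cm = fit_composition_model(list(state.evaluated),
                           [state.evaluated[c].mean_Tm for c in state.evaluated])
print(f"composition model: RMSE = {cm.rmse:.1f} K, Spearman = {cm.spearman_fit:.2f}")

out = tm_deltaF_concordance()
print(f"Tm-vs-dF concordance: rho = {out['spearman_rho']:.2f}, "
      f"engineered advantage = {out['engineered_advantage_kcal_mol']:.1f} kcal/mol")
```

Output (about two minutes on one CPU):

```
library size: 10000
top-10 PC variance captured: 0.751
evaluated 218 candidates over 24 rounds
best observed Tm: 429.7 K   top-8 mean: 425.2 K
composition model: RMSE = 3.9 K, Spearman = 0.98
Tm-vs-dF concordance: rho = 0.54, engineered advantage = 1.9 kcal/mol
```

Reading it: the campaign touched 2.18% of the design space (26 random seeds
plus 24 rounds of 8) and climbed to a best melting temperature of ~430 K on
the synthetic landscape, whose latent optimum is 430 K — the surrogate and
acquisition found the top of the landscape from a tiny evaluated fraction.
The residue-count regression then rationalizes the campaign's own data
(here nearly noise-limited, RMSE ≈ 4 K against a ~3 K replicate SE), and
the concordance numbers come from the packaged published stability table:
ranking by cheap ramp Tm agrees with equilibrium ΔF at rank correlation
≈ 0.5, and the best PPG-flanked engineered sequence beats the natural
collagen control by 1.9 kcal/mol (50% relative).

The same stages are scriptable from the shell:

```bash
cmphelix enumerate --out lib.txt
cmphelix featurize --sequences lib.txt --out-coords coords.csv
cmphelix campaign --coords coords.csv --seed 1 --out run1/
cmphelix compose --table run1/audit.csv --out-coeffs coef.csv --out-screens screens.csv
cmphelix simulate umbrella --out windows.csv && cmphelix wham --windows windows.csv --out pmf.csv
```

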