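# condensax

Real-space modelling of the supramolecular structure of phase-separated
protein droplets from small-angle X-ray scattering (SAXS), together with the
post-identification analysis rules of crosslinking mass spectrometry (XL-MS)
used to probe conformational rearrangements on condensation.

The package targets the structural question behind protein condensates such
as those formed by microtubule plus-end tracking (+TIP) proteins: how are
elongated, multidomain dimers arranged inside a micrometre-sized droplet?
Its answer pipeline is:

1. **Reverse-Monte-Carlo (RMC) fitting.** Thousands of model copies —
   first Gaussian blobs (width σ = 40 Å in a 10,000 Å sphere), then linked
   spherocylinders approximating the dimer (model 1: one rod R = 12 Å,
   L = 300 Å; model 2: 155 + 135 Å; model 3: 155 + 76 + 50 Å) — are moved by
   random translations/reorientations, accepting only moves that strictly
   decrease

   χ² = Σᵢ [(c·I_mod(qᵢ) − I_exp(qᵢ))/σᵢ]²,

   with the scale c minimised in closed form. A Gaussian window
   (σ_w = 3000 Å or 1500 Å) suppresses the container's own form factor and
   limits the fit to q ≥ 2π/σ_w. The staged protocol grows model 2 and
   model 3 from the model-1 result, maintaining cap-to-cap links and
   avoiding core clashes.
2. **Structure metrics.** Radial distribution function g(r) with
   Monte-Carlo finite-volume normalisation; local nematic order
   S = (3/2)·e_max of ⟨u⊗u⟩ − I/3 in 400 Å boxes (≥ 30 particles); fractal
   dimension d from the power-law slope I(q) ∝ q⁻ᵈ; Guinier radius of
   gyration for dilute curves. A mass-fractal arrangement with d ≈ 2 and
   S < 0.4 is the signature of a percolation-like, orientationally
   isotropic droplet network.
3. **XL-MS pipeline.** Classification of crosslinked peptides (crosslink /
   monolink / selflink / zerolink), qualitative filters (DSS: ld.Score > 20
   in ≥ 2 of 3 replicates; PDH: ld.Score > 25, deltaS > 0.9, FDR < 0.05),
   domain mapping on the 440-residue reference sequence, householder-
   normalised targeted quantification, two-sided Student t differential
   analysis (enriched ⇔ log2FC > 1) and conformo-specific link selection.
4. **Synthetic data.** Seeded generators for fractal (d = 2 random-walk)
   structures, noisy droplet and dilute SAXS profiles, and crosslink tables
   with programmed condition-specific links and fold changes — so the whole
   pipeline is testable without any measured data.

## Worked example

```python
import numpy as np
from condensax import (generate_random_walk_structure, generate_droplet_profile,
                       fractal_dimension, blob_form_amplitude,
                       generate_xl_tables, default_link_populations,
                       filter_qualitative_dss, conformo_specific,
                       normalize_quant, differential_analysis, summarize_counts)

# --- SAXS side: a synthetic droplet interior and its fractal dimension
walk = generate_random_walk_structure(2000, 200.0, seed=0)   # ideal chain, d = 2
walk -= walk.mean(axis=0)
q = np.geomspace(0.002, 0.02, 25)
profile = generate_droplet_profile(walk, q, seed=0, sigma_blob=40.0,
                                   noise_fraction=0.02)
fit = fractal_dimension(profile, (0.002, 0.02),
                        form_amplitude=lambda qq: blob_form_amplitude(qq, 40.0))
print(f"fractal dimension d = {fit.d:.2f} +/- {fit.stderr:.2f}")

# --- XL-MS side: filter, count, select condition-specific links, quantify
tables = generate_xl_tables(default_link_populations(), seed=1)
kept = filter_qualitative_dss(tables.identifications)
print(summarize_counts(kept, "phase_separated"))
unique = conformo_specific(kept)
print(sorted(p.split("|")[0] for p in
             unique.loc[unique.condition == "pellet", "peptide"]))
diff = differential_analysis(normalize_quant(tables.transitions),
                             "pellet", "supernatant")
print(diff[diff.enriched][["peptide", "log2fc", "p_value"]].to_string(index=False))
```

prints

```
fractal dimension d = 2.09 +/- 0.03
{'crosslink': 11, 'monolink': 1, 'selflink': 4, 'zerolink': 0, 'total': 16}
['211-346', '211-359', '216-245', '245-346', '79-338']
peptide   log2fc  p_value
216-245 1.061574 0.000199
```

The slope of the structure factor recovers the ideal-chain fractal
dimension 2 within its regression error; the generator's five pellet-only
crosslinks come back exactly after filtering, and a programmed 2-fold
abundance difference is recovered as log2FC ≈ 1 with its t-test p-value
(the enrichment flag is strict at log2FC > 1, so links sitting exactly at a
2-fold change are flagged only when noise puts them above it).

The RMC fitters also come as scikit-learn-style estimators:

```python
from condensax import GaussianBlobRMC, SpherocylinderRMC
est = GaussianBlobRMC(n_blobs=200, container_diameter=4000.0,
                      window_sigma=1000.0, max_moves=3000, seed=1).fit(profile)
est.chi2_trace_        # strictly decreasing objective
est.ensemble_.centers  # fitted blob positions
```

A `condensax` command-line tool exposes the stages (`simulate`, `fit-blobs`,
`fit-cylinders`, `metrics`, `xl-filter`, `xl-quant`, `run`) with YAML
configuration, seed logging and reproducible outputs.

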