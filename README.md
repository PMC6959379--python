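# meshbag

Analysis toolkit for mesh-bag incubation experiments in forest soils:
what happens, chemically and microbially, to organic matter after fungi
colonize it.

In this kind of experiment, sand-filled in-growth mesh bags amended with
composted maize leaves are buried along the soil profile of a forest
(here: a nitrogen-fertilized and unfertilized Norway spruce stand),
left for months, and harvested. Because maize is a C4 plant and the
surrounding forest carbon is C3-derived, the carbon isotope signature
of the bag contents records how much new fungal carbon grew in. The
package implements the full downstream analysis:

- **NEXAFS deconvolution** (`meshbag.nexafs`) — C and N K-edge spectra
  are normalized to an edge jump of 1 and decomposed into an
  error-function ionization step plus Gaussian resonances at literature
  energies (7 π\* components for C1s, 5 for N1s, fixed FWHM 1.2 eV,
  free-width σ\* resonances). The reported quantity is the relative π\*
  abundance of each bonding class,
  *a*ᵢ = Aᵢ / Σⱼ Aⱼ over π\* peak areas only.
- **Isotope and elemental mass balance** (`meshbag.isotope`) —
  δ¹³C = (R_sample/R_standard − 1)·1000; the two-pool mixing model
  f_C4 = (δ_sample − δ_new) / (δ_C4 − δ_new); new carbon
  C·(1 − f_C4); the one-compartment decay constant
  k = ln(C₀/C_t)/t; and a declared-convention partition of the C/N-ratio
  increase into fungal-biomass and inorganic-N-leaching contributions.
- **FTIR fingerprinting** (`meshbag.ftir`) — total-area normalization,
  trapezoidal band integrals over six diagnostic vibrational regions
  (carbohydrate 970–1150 cm⁻¹ through carbonyl 1620–1800 cm⁻¹), and
  covariance PCA with a deterministic sign convention.
- **Community processing** (`meshbag.community`) — BLAST-hit rank
  assignment (≥96 %/80 % identity/coverage → species, 94–96 % → genus),
  rare-OTU filtering, technical-replicate averaging, seeded rarefaction
  to the median depth, guild profiles, Bray–Curtis dissimilarity
  d = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), and one-way PERMANOVA with a vectorized
  permutation null.
- **Synthetic data** (`meshbag.synthetic`) — seeded generators for every
  input (spectra, chemistry tables, OTU experiments) with the ground
  truth returned alongside, so each estimator is testable as a round
  trip.
- **Pipeline & CLI** (`meshbag.pipeline`, `meshbag` console script) —
  staged end-to-end runs with provenance metadata and plain-text
  reports.

## Worked example

```python
from meshbag import isotope, nexafs, synthetic

# Two-pool mixing: how much mesh-bag C is still maize-derived?
f_c4, ok = isotope.c4_fraction(-15.6, isotope.MixingEndMembers(-13.36, -25.82))
print(f"C4 fraction: {f_c4:.4f} (in range: {ok})")
print(f"new C at 10.3 g/kg total: {isotope.new_carbon(10.3, f_c4):.3f} g/kg")

k, loss = isotope.decay_constant(12.1, 10.3, t=17/12)
print(f"decay constant k: {k:.4f} /yr (loss: {loss})")
print(f"C/N increase: {isotope.cn_increase_percent(11.9, [14.7, 14.3, 14.8, 14.0]):.1f}%")

# NEXAFS round trip: generate a known mixture, normalize, deconvolute
truth = synthetic.NexafsGroundTruth(
    "C1s", {"carboxyl-C": 0.5, "aromatic-C": 0.3, "O-alkyl-C": 0.2},
    noise_sd=0.01, seed=42)
spec, _ = synthetic.gen_nexafs_spectrum(truth)
fit = nexafs.fit_spectrum(nexafs.normalize_edge_jump(spec))
for label, frac in sorted(fit.pi_abundances.items(), key=lambda kv: -kv[1]):
    if frac > 0.005:
        print(f"{label:>12s}: {frac:.3f}")
```

prints

```
C4 fraction: 0.8202 (in range: True)
new C at 10.3 g/kg total: 1.852 g/kg
decay constant k: 0.1137 /yr (loss: True)
C/N increase: 21.4%
  carboxyl-C: 0.500
  aromatic-C: 0.299
   O-alkyl-C: 0.200
```

A C4 fraction of 0.82 means 82 % of the carbon in that humus-horizon
bag is still maize-derived and 18 % entered from the soil (in-grown
fungal C); k = 0.11 yr⁻¹ is the single-pool decay rate of the bag
carbon over the 17-month incubation; and the deconvolution recovers the
planted 0.5/0.3/0.2 composition from a spectrum with 1 % noise.

The same stages run from the shell:

```bash
meshbag simulate --out demo --seed 0     # synthetic inputs + all stages
meshbag nexafs --edge C1s --spectra demo/nexafs_input --out fits.csv
meshbag report --out demo --seed 0       # Table-style summary report
```

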