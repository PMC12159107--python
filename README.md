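# nucsas

Small-angle scattering (SAXS/SANS) analysis of nucleosome core particles in
solution: contrast variation, Stuhrmann plots, P(r) inversion, core–shell
cylinder fitting, and high-pressure series analysis — with a synthetic
nucleosome-scattering generator so every method can be exercised and
validated without beamline data.

## Who this is for

Structural biologists and biophysicists analysing 1-D solution scattering
of protein–DNA complexes, in particular nucleosomes (≈147 bp of DNA wrapped
~1.7 turns around a histone octamer). The package covers the standard
desk-side analysis chain between data reduction (out of scope) and atomic
modelling (out of scope):

- **Model-free analysis** — Guinier fits (`ln I = ln I₀ − q²R_g²/3`,
  automatic self-consistent window with `qR_g ≤ 1.2`), regularised indirect
  Fourier transform to the pair-distance distribution `P(r)` with `D_max`
  scanning, standard and dimensionless Kratky transforms
  (`(qR_g)² I/I₀ vs qR_g`), difference `P(r)`.
- **Contrast calculations** — neutron scattering-length densities from
  residue-level atom inventories with labile-H/D exchange, H₂O/D₂O solvent
  SLDs, theoretical and experimental match points (`√(I₀/c)` vs fraction
  D₂O), X-ray electron-density contrasts.
- **Contrast-variation inference** — Stuhrmann analysis
  `R_g² = R_c² + α/Δρ − β/Δρ²`; component molecular weights from
  absolute-scale forward intensities,
  `√(I₀/n) = |Δρ_P| MW_P/(N_A d_P) + |Δρ_D| MW_D/(N_A d_D)`;
  per-q decomposition
  `I(q) = Δρ_P² I_P + Δρ_P Δρ_D I_PD + Δρ_D² I_D`.
- **Forward models** — orientationally averaged core–shell cylinder (core =
  histone octamer, shell = DNA wrap), Debye bead-model sums with a
  distance-histogram acceleration, Gaussian-coil reference; global fits of
  shared cylinder geometry across SAXS + SANS contrast series with
  per-curve scale and background.
- **Pressure series** — per-pressure Guinier/IFT summaries and
  return-to-baseline hysteresis metrics (ΔR_g, ΔD_max) for high-pressure
  SAXS ramps (0.1–300 MPa), plus reference calculators (rigid-rod DNA,
  Stokes–Einstein radius, centrifuge-cell hydrostatic pressure).
- **Synthetic data** — a bead-model nucleosome generator (superhelical DNA
  wrap, straight-tangent end unwrapping, morph to an extended chain) that
  emits neutron contrast series and pressure series with full ground-truth
  manifests, so every estimator above is tested by parameter recovery.

## Worked example

Simulate a five-point neutron contrast series (0/20/70/80/95% D₂O, ~1 mg/mL,
3% noise) and recover the match point and component masses:

```python
import nucsas as ns

profiles, truth = ns.simulate_contrast_series(seed=7)
comp = ns.nucleosome_composition()

points = []
for p in profiles:
    g = ns.guinier_fit(p)
    points.append((p.meta["fraction_d2o"], g.i0, p.meta["concentration"]))
    print(f"fD2O={p.meta['fraction_d2o']:.2f}  "
          f"Rg={g.rg:5.1f} +/- {g.rg_sigma:.1f} A   I0={g.i0:.4f} cm^-1")

mp = ns.experimental_match_point(points)
print(f"match point: {mp.match_point:.3f} D2O "
      f"(predicted {ns.theoretical_match_point(comp):.3f})")

mw = ns.component_molecular_weights(points, comp)
print(f"MW(protein) = {mw.mw_protein/1e3:.1f} kDa   "
      f"MW(DNA) = {mw.mw_dna/1e3:.1f} kDa")
```

prints

```
fD2O=0.00  Rg= 37.4 +/- 0.8 A   I0=0.1228 cm^-1
fD2O=0.20  Rg= 39.3 +/- 1.1 A   I0=0.0384 cm^-1
fD2O=0.70  Rg= 32.2 +/- 0.6 A   I0=0.0367 cm^-1
fD2O=0.80  Rg= 32.5 +/- 0.7 A   I0=0.0719 cm^-1
fD2O=0.95  Rg= 33.4 +/- 0.7 A   I0=0.1478 cm^-1
match point: 0.453 D2O (predicted 0.453)
MW(protein) = 107.9 kDa   MW(DNA) = 91.3 kDa
```

The apparent R_g dips between 20% and 80% D₂O because the solvent
approaches first the protein and then the DNA match point, reweighting the
components — the behaviour a Stuhrmann plot turns into the (R_c, α, β)
shape/composition parameters. The recovered masses agree with the
generator's composition (108.5 kDa octamer, 90.8 kDa 147-bp DNA) to ~1%.
The experimental match point of ~0.45 D₂O reproduces the composition-based
prediction.

The same analyses are scriptable from the shell:

```bash
nucsas simulate --kind contrast --seed 7 --out synth
nucsas matchpoint synth/manifest.jsonl --out results
nucsas stuhrmann  synth/manifest.jsonl --out results
nucsas mw         synth/manifest.jsonl --out results
```

## Layout

```
src/nucsas/
  profiles.py   # ScatteringProfile, .dat I/O, merging, JSONL manifests
  contrast.py   # SLDs, contrasts, match points (residue tables in data/)
  modelfree.py  # Guinier, IFT P(r), Kratky, series summaries
  series.py     # Stuhrmann, component MWs, per-q decomposition
  models.py     # core-shell cylinder, Debye sums, coil, global fitting
  synth.py      # synthetic nucleosome generator + ground-truth manifests
  cli.py        # `nucsas` command-line interface
docs/methods.md # model assumptions, parameter choices, limitations
```
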