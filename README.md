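# anisoaudit

Per-entry audit of X-ray diffraction anisotropy for macromolecular
crystal structures, with the real-space packing context needed to study
it: crystal contacts, Matthews coefficient and solvent content.

Diffraction anisotropy — direction-dependent fall-off of diffraction
intensity — is traditionally blamed on missing crystal contacts along
one direction of space, but many structures do not follow that rule.
Investigating the question at scale requires the same battery of metrics
for every entry: reciprocal-space anisotropy measures on the deposited
structure factors, and real-space packing measures on the deposited
coordinates.  `anisoaudit` computes that battery for one entry or a
batch, applies standard curation filters, and classifies entries into
soluble/membrane subsets from user-supplied annotation tables.  A
synthetic-data module generates reflection sets and toy crystals with
known ground truth, so the whole pipeline is testable offline.

## Metrics

For each entry (a legacy-PDB coordinate file plus an mmCIF
structure-factor file):

- **Anisotropic delta-B** (amplitudes and intensities, when present).
  The symmetric temperature-factor tensor *B* (Å²) is fitted to
  log-intensity residuals: with *q* = 1/*d* and unit diffraction
  direction **n**, the model is
  ln(*I*/⟨*I*⟩_shell) = *c*_shell − (*q*²/2)·(**n**ᵀ*B***n**),
  solved by iterated least squares with 3·RMS outlier rejection.
  delta-B = *b*₃ − *b*₁, the spread of the tensor eigenvalues,
  invariant under any isotropic offset.
- **Wilson B** from the slope of ln⟨*I*⟩ against (sin θ/λ)² over
  resolution shells with *d* ≤ 4.5 Å (*B* = −slope/2), and the
  **ratio** delta-B / Wilson B.
- **Directional resolution limits**: for each principal axis of the
  anisotropy ellipsoid, the resolution at which mean F/σ(F) drops below
  3.0 within a 20° cone around the axis, and **delta_res**, the spread
  between the best and worst axis.
- **Percentage of rejected reflections** during the anisotropy fit.
- **Crystal contacts ratio**: symmetry-expanded atom pairs within
  4.0 Å between the asymmetric unit and its crystal images, divided by
  the total atom count (heteroatoms and waters included).
- **Matthews coefficient** V_M = V_cell/(Z·M) and **solvent content**
  100·(1 − 1.23/V_M), used when the header lacks a deposited value.
- **Header metadata**: revision year, resolution, cell and space group,
  collection temperature, HET codes, keywords, solvent content.

Curation keeps entries with year ≥ 2006, resolution ≤ 5 Å,
amplitude delta-B ≤ 150 Å² and contacts ratio ≤ 1.

## Worked example

Simulate a data set with a strongly anisotropic temperature factor
(10, 10, 60 Å² along the cell axes) and a planted F/σF crossing at
3 Å along c*, then audit it:

```python
from anisoaudit import UnitCell, gen_reflections, analyze_anisotropy
from anisoaudit.synthetic import SimulationSpec, DirectionalSigma

spec = SimulationSpec(
    cell=UnitCell(42.5, 42.5, 42.5), dmin=2.0,
    b_tensor=((10, 0, 0), (0, 10, 0), (0, 0, 60)),   # strong fall-off along c*
    sigma_frac=0.2,
    directional_sigma=(DirectionalSigma(factor=10.0, d_max=3.0,
                                        axis=(0, 0, 1), cone_deg=20.0),),
    seed=7,
)
res = analyze_anisotropy(gen_reflections(spec))
```

which prints:

```
n_reflections = 20121
aniso_b (amplitudes)  = 50.8 A^2
wilson_b (amplitudes) = 15.9 A^2
ratio                 = 3.19
axis_limits = (2.0, 2.0, 2.97) A
delta_res   = 0.97 A
pct_rejected = 2.19 %
```

The fitted delta-B (50.8 Å²) recovers the imposed eigenvalue spread
(60 − 10 = 50 Å²); the c* axis limit sits at the planted 3 Å crossing
while the two clean axes reach the 2 Å data edge, giving delta_res
≈ 1 Å; and about 2% of the exponentially distributed intensities fall
outside 3·RMS of the log-residual fit.

The same operations are available from a shell:

```sh
anisoaudit simulate reflections --out sf.cif --seed 7 --cell 42.5 --b-diag 10 10 60
anisoaudit aniso sf.cif
anisoaudit run model.pdb sf.cif --annot annotations.tsv --out audit.csv
anisoaudit curate audit.csv --out kept.csv --dropped dropped.csv
```

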