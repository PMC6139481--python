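# Methods

## Conventions

One Debye–Waller convention is used throughout: amplitudes attenuate as
exp(−B(**n**)·s²) with s = sin θ/λ = 1/(2d), so intensities attenuate as
exp(−2·B(**n**)·s²), where B(**n**) = **n**ᵀB**n** is the directional
temperature factor along the unit diffraction direction **n** = **s**/|**s**|.

Real-space coordinates live in the standard PDB orthogonalization frame
(crystal *a* along Cartesian x, *b* in the x–y plane); reciprocal
vectors are computed in the dual of that frame, so coordinate files and
reflection data share one orientation.  All derived d-spacings are
convention-free (they depend only on the cell metric), which the test
suite asserts against the closed triclinic formula and against gemmi.

## Anisotropic tensor fit

The fit operates on the working intensities I (measured intensities, or
F² for amplitude data).  Reflections are binned into 20 equal-count
resolution shells; the per-reflection residual
y = ln(I/⟨I⟩_shell) is modelled as

    y = c_shell − (q²/2)·(nᵀ B n),        q = 1/d

and solved by linear least squares for the per-shell constants and the
six unique components of B.  Reflections with |y − ŷ| > 3·RMS are
discarded and the fit repeated, up to 5 cycles or until the rejected
set stabilizes; the fitted tensor is then averaged over the point-group
rotations of the space group (B ← mean RᵀBR), which enforces
crystallographic admissibility without a constrained solver.  The
anisotropy magnitude delta-B is the eigenvalue spread b₃ − b₁.

Two numerical choices deserve note:

- **Per-shell intercepts.** Normalizing by stepwise shell means while
  fitting a single smooth constant leaves sawtooth residuals on
  noise-free data, which a 3·RMS rule then "rejects".  Giving each
  shell its own intercept makes the noise-free model exact — zero
  residual, zero rejections — and leaves the anisotropic part of the
  fit unchanged.  A consequence is that the isotropic component of B is
  only weakly determined (it is nearly collinear with the shell
  intercepts); the meaningful output is the eigenvalue *spread*, which
  is invariant to isotropic offsets by construction.
- **Rejection semantics.** The rejection percentage is defined by this
  3·RMS rule.  On exponentially distributed (acentric Wilson)
  intensities it settles around 2%, dominated by the long left tail of
  ln I; on noise-free data it is exactly 0.  It is an internal quality
  indicator and is not comparable to rejection counts reported by
  likelihood-based anisotropy servers, whose criteria differ.

The least-squares fit recovers the eigenvalue spread of the generating
tensor within ~1 Å² at 20,000 reflections (see `scripts/acceptance.py`),
and is equivariant under rotations of the Cartesian frame to machine
precision on noise-free data.

## Wilson B

Weighted least-squares line of ln⟨I⟩_shell against the shell mean of s²,
weights equal to shell counts, over shells with mean d ≤ 4.5 Å; the
slope m gives B = −m/2.  The 4.5 Å cut excludes the low-resolution
regime where Wilson statistics do not hold; at least 3 shells must
remain or the fit refuses.  Shells with non-positive mean intensity are
dropped with a warning.  For anisotropic data this B is an effective
spherical average and is intentionally reported as such — the
delta-B/Wilson-B ratio is a dimensionless anisotropy severity index.

## Directional resolution limits

For each principal axis of the fitted tensor, reflections within a 20°
half-angle cone (Friedel-symmetrized: ±axis pooled) are sorted by
decreasing d and split into 10 equal-count bins.  Walking from low to
high resolution, the limit is the high-resolution edge (minimum d) of
the last bin whose mean F/σF still meets the 3.0 threshold, giving the
limit a deliberate ±half-bin quantization; no interpolation is done.
Degenerate outcomes use the shared data edges: if the first bin already
fails, the limit is the lowest-resolution d of the data set; if no bin
fails, the overall dmin.  Using data-set edges (rather than per-cone
edges) keeps the three limits on a common scale, so isotropic data
yields delta_res exactly 0 instead of picking up cone-sampling jitter.
Cones with fewer than 20 usable reflections are flagged unreliable but
still reported.  When a file carries only intensities, amplitudes for
the F/σF walk are derived as F = √max(I,0), σF = σI/(2F), with
non-positive intensities excluded (a full Bayesian intensity-to-
amplitude treatment is out of scope).

delta_res is the non-negative spread max(limits) − min(limits).

## Crystal contacts

A contact is an ordered (ASU atom, image atom) pair within 4.0 Å, where
images are all space-group operations combined with lattice translations
in {−1,0,1}³ (identity-with-zero-translation excluded); an atom meeting
its own image at zero distance (special position) is not a contact, and
intra-ASU pairs never are.  Each ASU atom may contribute several
contacts — these are atom-pair-listing semantics.  The model is first
re-anchored by an integer lattice shift of its centroid so the
translation shell is sufficient, which also makes the count invariant
under lattice translations of the input by construction; the shell
widens automatically while any cell edge is shorter than twice the
cutoff.  The production counter uses a k-d tree over the expanded
images; an exhaustive all-images distance scan (independent code path in
the synthetic module) serves as its oracle, and the two agree exactly on
every generated crystal.

Waters and heteroatoms participate on both sides of the contact count
and in its denominator (the total atom count); the contacts ratio is
n_contacts / n_atoms_total.

## Matthews coefficient and solvent content

V_M = V_cell/(Z·M) in Å³/Da, with Z the number of asymmetric units per
cell and M the asymmetric-unit macromolecular mass; solvent content is
100·(1 − 1.23/V_M), 1.23 being the reciprocal of the conventional
0.74 cm³/g protein partial specific volume in V_M units.  M sums
standard atomic masses over polymer atoms only (waters and heteroatoms
excluded) scaled by 1.05, the standard hydrogen mass fraction of
protein, since hydrogens are absent from typical X-ray models.
Negative solvent contents (over-packed hypotheticals) are flagged, not
clamped.

## Curation and subsets

Filters are applied in a fixed order and the first failing rule is
recorded: year ≥ 2006 ("after 2005" read strictly), resolution ≤ 5.0 Å,
amplitude delta-B ≤ 150 Å², contacts ratio ≤ 1.  The last three bounds
are inclusive-keep; entries whose delta-B or contacts ratio was never
computed are not dropped by those rules (the filters act on computed
values, not on missingness), while year and resolution are mandatory.
Curation is idempotent, order-independent and partitioning, asserted by
property tests.

Subset classification consumes a user-supplied annotation table
(mpstruc-style taxonomy).  Unannotated entries are soluble; membrane
entries get every applicable sub-label (fold, crystallization mode,
function, topology).  When the crystallization mode is unknown,
lipidic-cubic-phase growth is inferred from a configurable keyword and
lipid het-code list (monoolein-class codes OLC/OLB/OLA, MPG, "LIPIDIC
CUBIC PHASE", …) — an approximation to curated LCP registries, and
deliberately overridable.

## Synthetic data: what it emulates, and what it does not

`gen_reflections` draws acentric Wilson intensities: I ~ Exponential
with mean K·exp(−2s²·B(**n**)) on the complete Friedel-unique lattice to
dmin.  Reported uncertainties are σI = sigma_frac·⟨I⟩ (model mean), so
noise-free amplitude data has F/σF = 2/sigma_frac exactly — the
directional-sigma inflation mode plants F/σF crossings at chosen
resolutions and cone axes for limit tests.  The stochastic mode's only
randomness is the exponential Wilson draw; no separate Gaussian
measurement error is injected, so σI describes scale, not an extra
noise process.  Generators default to P1 reflection data; centric
zones, systematic absences, twinning, anomalous signal and
incompleteness are not modelled.  Passing recovery tests therefore
demonstrates estimator correctness under ideal Wilson statistics, not
robustness to pathologies of real deposited data.

`gen_crystal` builds toy P1/P2₁/P2₁2₁2₁ crystals from explicit
fractional positions and returns an exhaustively computed contact count
as ground truth.  `gen_audit_population` plants exact per-rule violation
counts just inside/outside the curation boundaries.  Every generator is
deterministic under its seed (byte-identical serializations).

## Problem sizes

Recovery checks run at ~20,000 reflections (a 42.5 Å cubic cell to
2 Å), 10 noise realizations per imposed spread; contact-oracle checks
use 50 random crystals of up to 500 atoms; curation checks use
populations of 1,000.  These sizes give sub-percent estimator noise
while keeping the full suite fast enough to run habitually.

## Known limitations

- The anisotropy fit is least squares on log intensities, not a
  likelihood treatment; weak reflections are handled by rejection, not
  down-weighting, so absolute rejection percentages are
  definition-specific.
- The Wilson fit reports a spherical average for anisotropic data.
- Multi-model coordinate files are read first-model-only; alternate
  conformations keep the first-listed altloc.
- Secondary-structure percentages are ingested as optional annotation
  columns, never computed.
- Corpus-scale statistics over a full archive snapshot are outside the
  package's scope; it audits the entries it is given.
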