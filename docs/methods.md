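# Methods

## Scope and assumptions

`pcsbonds` post-processes a *converged* gas-phase equilibrium structure of
a semirigid molecule built from H, C, N, O and S. The corrections were
calibrated for geometries from a double-hybrid functional with a
quadruple-ζ-valence basis; the code is agnostic about provenance, but the
coefficients only have their stated meaning for inputs of that quality.
Large-amplitude motions, open-shell species, charged systems and elements
outside the supported set are out of scope, as is computing the
vibrational (α) or electronic (g-tensor) corrections themselves — those
are inputs.

## Element constants

Covalent radii are the Cordero et al. (2008) single-bond values
(H 0.31, C 0.76, N 0.71, O 0.66, S 1.05 Å). For carbon the *generic*
radius is the default; the hybridization-specific values (sp³ 0.76,
sp² 0.73, sp 0.69) are exposed in `elements.CARBON_RADII_BY_HYBRIDIZATION`
for sensitivity studies but are not used by the pipeline — both the bond
order and the core–valence formula are calibrated against the generic
radius, and swapping it breaks the benchmark reproduction. Masses default
to the most abundant isotope (¹H, ¹²C, ¹⁴N, ¹⁶O, ³²S) so rotational
constants refer to the parent isotopologue; per-call overrides support
isotopologue work. A checksum test pins all defaults.

## Bond perception

Pauling order `P = exp[(Σr_cov − r)/b]` with decay `b = 0.3 Å` and
threshold `P > 0.3`. The two printed calibration facts — threshold 0.3 and
threshold distance Σr_cov + 0.35 Å — are mutually consistent for b = 0.3
only to 0.011 in order units (exp(−0.35/0.3) = 0.311); an import-time
guard asserts this agreement to 0.02 so any edit of the decay constant
must be deliberate. Perception is purely geometric; there is no
kekulization, and intramolecular H···H contacts (≈ 1.8 Å, P ≈ 0.07) fall
out naturally below threshold. A plain-text override file can force or
forbid specific pairs.

## Correction formulas

* `Δr_CVB = −k √(n_i n_j − 1) (r_i^cov + r_j^cov)`, `k = 0.0011`. Using
  covalent radii rather than the actual bond length makes the estimate
  independent of the method that produced the geometry. The √(n_ij − 1)
  dependence reproduces the published corrected-vs-reference differences
  of 2-furonitrile at their full printed precision (C–N −0.0028,
  C–O −0.0027, C–H −0.0012 Å) and vanishes identically for hydrogen-row
  pairs. "First-row" in the vanishing statement is read as the hydrogen
  row: C, N, O bonds all carry nonzero corrections in the benchmark
  tables, which forces that reading.
* `Δr_VB = a max(P² − 1, 0)` for C–C bonds only, `a = 0.0007`. The form
  was selected by interval arithmetic against the three aromatic C–C
  rows of the furonitrile table (each printed endpoint trusted to
  ±0.00005 Å): among the simple monotone candidates (linear, log,
  reciprocal, quadratic-in-(P−1), sinusoidal), only a(P²−1) admits a
  single coefficient consistent with all three rows, and a = 0.0007
  reproduces each at four decimals. The clamp at P = 1 keeps slightly
  stretched single bonds (P < 1) from being contracted further; the
  correction is insensitive to the precise order so long as single,
  double and triple bonds sit near 1, 2, 3.
* Both coefficients are configurable (`k`, `vb_coefficient`) and echoed in
  every CLI report. Angles are never corrected.

## Penalty refit

`S = Σ(r − r_t)² + f Σ(θ − θ_ref)²` with `f = 0.00115` and **angles in
degrees** by default. The unit matters: 0.00115 deg⁻² weighs a 0.03°
angle drift like a 1 mÅ bond residual, which is the balance that
reproduces the published corrected furonitrile structure (bonds to
3·10⁻⁴ Å *and* angles to 0.006°). With radians the angle term is ~3300×
softer and angles drift by ~0.25°, contradicting the published
"angles unchanged" behavior; the radian convention remains available as
`angle_unit="radian"`.

Plain gradient descent with η = 0.1 is the default path; a safeguard
halves η whenever a step would increase S (the degree-weighted angle
terms make the quadratic form stiff enough that one or two halvings occur
on typical rings) and is logged so the plain update is recoverable
(`adaptive_step=False`). Convergence is declared when the RMS
per-coordinate Cartesian step falls below 10⁻⁶ Å (cap 200 000
iterations; typical molecules converge in a few hundred). The gradient is
assembled by chain rule through dense Wilson B-matrix rows — molecule
sizes here (≤ ~50 atoms) make sparsity pointless.

Properties maintained and tested: S never increases across accepted
steps; the gradient has zero net force and torque, so the centroid and
orientation are preserved; connectivity is frozen from the input and
re-perception of the output reproduces it; tree-connected systems reach
S < 10⁻¹⁰ (targets exactly attainable), while rings retain residuals of
a few 10⁻⁴ Å that the penalty distributes between bonds according to f.
The residual scale is a property of the method, not a convergence
artifact: tightening the step threshold to 10⁻⁸ Å leaves it unchanged.

Degenerate inputs: an exactly collinear angle raises
`DegenerateCoordinateError`; near-linear angles (> 179.9°) are kept with
a warning — the nitrile angle at 178.65° is routinely handled. Dihedrals
are deliberately absent from the coordinate set (the penalty needs only
bonds and angles; torsions relax freely, which is inconsequential for the
planar/semirigid target class).

## Rotational constants

`B_i = κ/I_i` with κ = h/(8π²) = 505379.0084 MHz·amu·Å², computed once
from CODATA h and the atomic mass constant and frozen at 10 significant
digits. Axes are labeled a, b, c by descending constant. A vanishing
principal moment (linear molecule) reports A = inf with a warning;
single atoms raise. The planarity identity 1/C = 1/A + 1/B (equivalently
inertia defect I_c − I_a − I_b = 0) holds to 10⁻⁶ relative on planar
fixtures and is exposed via `inertia_defect`.

Ground-state assembly: `B0 = B_eq + ΔB_CVB + ΔB_VB + ΔB_vib`, with
ΔB_vib = −½Σα from user-supplied α constants. The electronic term
`ΔB_el = (m_e/M_p) g_ii B_i` (g in nuclear magnetons) is computed on
request but excluded from B0 by convention, matching the reference
tables; its sign follows g, an adopted convention since the printed
benchmark shows both signs and cannot disambiguate the formula's sign.

## Benchmark fixtures and statistics

Three component tables (validation set, 30 constants / PAH set, 24 /
heteroaromatic-CN set, 39) and the furonitrile geometry table are
embedded verbatim. A transcription guard asserts the additive identity of
every row at the 0.1 MHz print precision; two rows (naphthalene b,
benzothiophene a) are internally inconsistent *in the source* (components
vs total off by 0.6 / 0.4 MHz) and carry a `misprint` flag the guard
verifies is warranted and exhaustive. Statistics use the printed totals,
reproducing the printed footers (MUE 0.069/0.042/0.028%, MAX
0.196/0.119/0.129%) to ±0.005 points with the phenanthrene outlier
excluded as in the source footnote.

The error profile is a Gaussian in the relative-error axis with the
sample mean and standard deviation; the *unsigned* errors are the default
(matching the "relative unsigned mean error" convention), with a signed
variant available since only it exposes systematic bias. Normalization is
the standard (σ√2π)⁻¹.

The 2-furonitrile Cartesian structure used in end-to-end tests is
reconstructed from the tabulated internals (planar molecule: bonds +
angles + ring closure determine it). The printed table omits one ring
bond and two ring angles, which ring closure supplies; one printed angle
label (C3C4O5) is chemically impossible as written and is read as the
ring angle at C3. The reconstruction reproduces all tabulated internals
except one redundant H angle (off 0.19°, a rounding artifact of the
printed values).

## What the tests do and do not show

All molecular fixtures are idealized or reconstructed from printed
internals, not raw quantum-chemistry outputs; passing tests demonstrate
that the implemented formulas reproduce the published corrected
structures, assembled constants and benchmark statistics, and that the
refit engine has the advertised mathematical properties. They do not
re-derive the reference geometries, α constants or g tensors — the
headline "compute everything from the raw molecule" accuracy claim
requires external electronic-structure inputs that are out of scope here.

## Known limitations

* Corrections are meaningful only on top of the calibration level of
  theory; feeding lower-quality geometries yields corrected structures of
  the same lower quality.
* The valence term's functional form beyond the aromatic order range
  (1.3–1.7) is an extrapolation constrained only by its value near
  P = 1, 2, 3.
* Gradient descent is robust but first-order; pathological inputs (nearly
  collinear chains of heavy atoms) may need many iterations or a smaller
  learning rate.
* No torsional restraints: flexible molecules with multiple conformers
  must be handled one conformer at a time.
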