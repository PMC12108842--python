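# Methods

This note records the models, conventions and numerical choices behind
`hydrocouple`, in the spirit of a methods section: what is computed, which
decisions were genuinely open, and what the synthetic generators do and do
not emulate.

## Units, boxes, and periodic geometry

All internal quantities are in angstrom and picosecond; MDAnalysis converts
nm-based formats (GRO/XTC/TRR) at the I/O boundary. Only orthorhombic boxes
are supported — triclinic inputs raise an error rather than being silently
wrapped, trading generality for easily verified distance code. Every
distance and angle criterion uses the minimum-image convention
(component-wise wrap `d − L·round(d/L)`, exact for orthorhombic cells).
Trajectory formats store frame times in single precision; on loading, times
within float32 rounding of a uniform grid are snapped to the exact grid so
the uniform-spacing invariant (tolerance 10⁻⁶ ps) remains meaningful for
long runs.

TIP4P-style virtual sites are carried in the atom table but excluded from
all geometric criteria: hydrogen-bond geometry is defined on oxygen and
hydrogen positions only.

## Water order parameters

Two waters are hydrogen-bonded when the O–O minimum-image distance is
< 3.5 Å and at least one of the four donor arrangements (either molecule
donating either hydrogen) has an O–H···O angle at the hydrogen within 40°
of linearity. The relation is symmetric by construction.

ζ of a water is the O–O distance to its nearest non-hydrogen-bonded water
minus the distance to its farthest hydrogen-bonded water. ζ is *undefined*
(stored as NaN, never clamped to zero) when the water has no bonded partner
or no non-bonded water; undefined records are excluded from every statistic
and counted in the run log. The neighbor search uses the full pairwise O–O
distance matrix per frame: at the water counts this package targets
(10²–10³ per frame) the vectorized full matrix is faster and simpler than
cell lists, and trivially identical to an exhaustive search.

q uses exactly the four nearest water oxygens (no distance cutoff), with
protein atoms never counted as neighbors. Low-coordination waters are *not*
filtered out, so q may be negative near interfaces; filtering would bias
interfacial statistics, and the negative values are themselves informative
about constrained geometries.

The per-residue order series averages ζ over the residue's contact waters
frame by frame. Contact assignment measures from the water **oxygen** to
residue **heavy** atoms (both config-exposed: `contact_water_site`,
`contact_residue_atoms`); the oxygen locates the molecule and heavy atoms
define the residue surface. Exact distance ties go to the lowest residue
index for reproducibility. The shell criterion itself uses all three real
water atoms against protein carbons at 5.0 Å, strict inequality.

## Residue descriptors

RMSF and per-residue RMSD are computed after a global least-squares
(Kabsch) superposition of each frame onto the reference frame using all
protein heavy atoms; the transform is applied to all atoms, so rigid-body
motion never contributes. The RMSD reference is the first frame of the
analysis window and the per-residue atom set is the residue's heavy atoms —
conventional defaults, config-exposed, since no single standard exists.
Per-residue RMSF is the mean of its heavy atoms' per-atom RMSF. A
`superpose=False` escape hatch exists for pre-aligned input.

SASA is Shrake–Rupley with Bondi van der Waals radii, a 1.4 Å probe, and a
deterministic golden-spiral point set (default 960 points/atom), making
results reproducible bit-for-bit; an isolated carbon is exact to quadrature
(≤ 1% at 960 points). Points falling exactly on another expanded sphere
(possible only for degenerate geometries such as coincident atoms) are
buried only against a lower atom index, so an exactly shared surface is
counted once. The per-residue value is the sum over the residue's atoms and
the reported value is the time mean; the pipeline strides frames (~40
evaluations per run) because SASA varies slowly relative to its cost.

Residue classes: non-polar {ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP}, polar
{SER, THR, CYS, TYR, ASN, GLN}, charged {ASP, GLU, LYS, ARG, HIS};
glycine, lacking a side chain, is excluded from class statistics.
Histidine is titratable and defaults to charged (`histidine_class: polar`
moves it).

## Relaxation times

The ACF estimator divides the lag-τ covariance (averaged over the n−τ
available pairs) by the full-series variance, so C(0) = 1 exactly; |C| can
marginally exceed 1 at large lags, which is why lags above n/2 are never
used (config `acf_max_lag_fraction`). Sums are evaluated by FFT, exact up
to float rounding.

The relaxation time is the trapezoidal integral of C(τ)/C(0) from 0 to T,
where T is the first crossing of 0.1, located by linear interpolation
between the bracketing lags (reducing discretization bias; for an exact
exponential ACF with τ₀ = 1 ps sampled at 0.01 ps the estimate is 0.900 ps
to within 10⁻⁵). Segments whose ACF never reaches 0.1, and segments whose
estimate exceeds 10% of the segment duration, are discarded; the residue
relaxation time is the unweighted mean of surviving segment estimates.
Gapped series are split into maximal gap-free runs, dropping runs shorter
than `min_segment_frames` (default 50 — shorter segments cannot support
the validity filter).

Known bias: subtracting each segment's own mean depresses the sample ACF of
short segments, so heavily gapped series recover relaxation times a little
low (≈10% when segments are ~20 τ₀ long, worse for shorter segments). This
is a property of the segment-wise method itself, shared by any
implementation of it, and it motivates the validity filter.

The ζ-velocity v = (ζ(t+Δt) − ζ(t))/Δt is sampled at Δt ∈ {0.1, 1.0} ps
over windows containing no undefined entries. Its distribution width is
reported as the full width at half maximum of a histogram density (default
bin 0.1 Å/ps), with half-height crossings interpolated linearly on each
flank and the outermost crossings used if a flank is multimodal. FWHM was
chosen over half-of-FWHM as the plain reading of a distribution
"halfwidth"; the bin width is config-exposed.

## Coupling statistics

Spearman ρ is Pearson on mid-ranks (ties averaged); pairs with any
undefined member are dropped per correlation. Headline correlations are
computed over surface residues only — those with a defined mean ζ — since
buried residues have no hydration-water signal to correlate. The G1–G4
groups classify residues by whether σ_RMSD and σ_ζ (computed on the
high-rate series, gaps excluded) strictly exceed their means over the
classified residues; a value equal to the mean falls in the lower group.
G1 = flexible residue/calm water, G2 = both fluctuating, G3 = both stable,
G4 = calm residue/fluctuating water. Replicate trajectories are pooled by
concatenating per-residue series with a NaN separator, so means and sigmas
use all observations while no autocorrelation segment ever bridges a
replicate boundary.

## Synthetic generators

The generators provide ground-truthed inputs; they emulate the *structure*
of real data the pipeline consumes, not water physics.

* **Water boxes.** Lattice mode places oxygens on a diamond-cubic (ice-like)
  lattice (nearest-neighbor O–O 2.75 Å) with hydrogens assigned along bond
  directions satisfying ice rules — every water donates two and accepts two
  hydrogen bonds, every interior water has q = 1 and ζ ≈ 1.74 Å. Gaussian
  rigid-molecule displacement degrades order continuously. Random mode
  packs molecules uniformly (minimum O–O 2.4 Å) with uniform random
  orientations.
* **OU series.** Exact-discretization stationary Ornstein–Uhlenbeck
  processes, whose ACF is exactly exp(−τ/τ₀); this makes the 0.9·τ₀
  truncated-integral value a closed-form oracle for the relaxation
  estimator. Optional geometric-length gaps emulate the intermittent
  definition of per-residue series.
* **Toy protein–water system.** Residues (two carbon beads each) sit on a
  large ring, 16 Å apart, far enough that clusters never interact. Each
  residue carries a three-water cluster rigidly tethered to it: a central
  water, a hydrogen-bonded partner at a fixed 2.8 Å, and a non-bonded water
  whose retreat distance encodes ζ(t) = r_nhb(t) − 2.8 geometrically, so
  the pipeline's shell → contact → ζ chain reads back a planted OU series
  exactly. The planted structure: per-class displacement amplitudes
  (non-polar 0.25, polar 0.45, charged 0.7 Å per coordinate — RMSF
  ordering), per-class ζ relaxation times (0.3 / 0.45 / 0.7 ps, residue
  relaxation 12× slower — both orderings and the ratio ≫ 1), a ζ mean
  decreasing with amplitude in proportion to `coupling_strength` (the
  negative flexibility–order coupling), and static carbon scaffolds
  (glycine residues, excluded from class statistics) shielding rigid
  residues so SASA rises with flexibility. Defaults (60 residues,
  2000 frames at 0.1 ps) populate all three classes and all four
  fluctuation groups with enough frames for stable segment statistics.

  What the toy system does **not** emulate: water exchange between shells
  (clusters are tethered, so contact maps have no gaps), diffusive water
  dynamics, realistic ζ magnitudes (cluster geometry shifts the contact
  mean up by 1.4 Å), or protein internal degrees of freedom. Recovered
  τ_RMSD is systematically below the planted displacement timescale
  because the RMSD magnitude series decorrelates faster than the
  underlying displacement; the class ordering survives, which is what the
  pipeline claims to detect. Passing tests on this system therefore
  demonstrate that the pipeline recovers planted orderings and signs from
  data of the right shape — not that any particular water model behaves
  this way.

## Problem sizes

The shipped tests and the acceptance script run the toy system at up to 60
residues × 2000 frames (≈ 780 atoms), OU recovery at 50,000 steps × 20
seeds, and oracle comparisons on ≤ 50-water boxes — sizes chosen so the
full verification cycle completes in minutes on one core while keeping
every estimate's sampling error well inside the asserted tolerances.

## Known limitations

Buried waters, residence times and second shells are out of scope; ζ treats
only water–water hydrogen bonds (protein donors/acceptors are not network
members); no stretched-exponential or spectral ACF analysis; triclinic
boxes and velocity data are unsupported.
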