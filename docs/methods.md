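# Methods

This note records the models, defaults and numerical conventions behind
each module, the design choices made where practice is genuinely open,
and what the synthetic generators do and do not emulate.

## Single-channel idealization (`idealize`)

**Model.** One two-state (closed ↔ open) channel per patch. The analysis
assumes a single conducting level; multi-channel NPo analysis, burst
analysis and dwell-time distribution fitting are out of scope.

**Dead time.** t_d = 1/(2πf_c) with f_c the low-pass cutoff in Hz
(default 1 kHz, giving 0.159 ms ≈ 0.16 ms). Candidate events shorter than
t_d are *merged into the enclosing dwell*, shortest event first, rather
than deleted-and-split — the standard reading of "ignoring" sub-dead-time
excursions in half-amplitude practice. Merging is iterated to a fixed
point and same-state neighbours are coalesced, so the output strictly
alternates and partitions T_m to within one sample period.

**Threshold tie-break.** A sample lying exactly on the 50% threshold
keeps the previous state (the first sample of a record counts as closed).
The rule only matters for noiseless synthetic data; measured samples tie
with probability zero.

**Level assignment.** All-point amplitude histogram (200 bins, 5-bin
boxcar smoothing, zero-padded so edge-bin modes are detectable); the two
most prominent peaks are the levels, the taller peak — the modal
baseline — is the closed level. This identifies "closed" correctly
whenever the channel spends more time closed than open at any one level;
for P_o > 0.5 records, pass levels explicitly (the `Levels` override
mirrors manual verification of transitions at the bench).

**Windowed consistency.** Non-overlapping windows (default 30 s) are
compared to the whole-record P_o with a 0.95–1.05 acceptance band. The
window placement rule is a display convention, not an estimator; we use
deterministic non-overlapping placement from t = 0.

**Voltages.** V_mem = V_rev − V_cmd. |LJP| < 3 mV is neglected; larger
values are subtracted (V_mem = V_rev − V_cmd − LJP), with LJP defined as
the potential of the bath relative to the pipette as reported by
amplifier software. The correction branch is provided for completeness;
typical CsAsp-based solution pairs stay under the 3 mV threshold.

**i–V slopes.** Separate OLS fits to points at negative and positive
membrane potential, slopes in pS. Points indistinguishable from baseline
(as happens near the reversal potential of a doubly-rectifying channel)
must be excluded by the caller — a data-quality judgement the code does
not automate.

## Hill fitting and chelator equilibria (`doseresponse`)

**Fit.** Po(x) = A·xⁿ/(K_dⁿ + xⁿ), fitted by trust-region-reflective
least squares on a log-parameterization of (K_d, n, A), which enforces
positivity without active bounds. Initialization: K_d at the geometric
mean of the doses, n = 1, A = max response. Residuals are computed on the
linear response scale without log-transforming, and replicates enter as
individual points (unweighted by default). Standard errors come from the
Jacobian at the optimum. Flags: constant responses (non-identifiable),
non-convergence, K_d outside the dosed range by more than 100×.
Noiseless self-consistency is recovered to better than 10⁻⁶ relative over
K_d ∈ [0.1, 100] µM, n ∈ [0.5, 4].

**Surface.** Independent Hill fit per co-ligand column; n is floated per
column by default (`fix_n` shares it if desired — with the data the
generator produces, sharing changes K_d estimates by less than their
standard errors). The K_d trend and a monotonicity report quantify the
sensitization of the channel to PIP₂ by the G-protein.

**Amplification curve.** Ratio of the two fitted curves, evaluated at
user doses (the conventional probes are 5, 16 and 50 µM PIP₂). The
denominator floor is 1% of the larger fitted amplitude; points below it
are masked as numerically singular rather than reported. Note the ratio
of two Hill curves with equal n is monotone in dose — any biphasic shape
in measured amplification curves is a property of the data, not of this
functional form.

**Chelator solver.** 1:1 metal–chelator mass action. With one chelator
the free-ligand conservation equation is monotone and solved by Brent
bracketing to machine precision; with several chelators a vector root
solve in log free-ligand space is used. Mass conservation is audited to
10⁻⁹ relative (achieved: ~10⁻¹⁵) and free ≤ total always. Default
apparent association constants, user-overridable:
log₁₀K(Ca·EGTA) = 6.8, log₁₀K(Mg·EGTA) = 1.6 (M⁻¹) at pH 7.2, ~22 °C,
ionic strength ≈ 0.15 M. Apparent EGTA constants differ between
tabulations at the tens-of-percent level (protonation corrections are
temperature- and ionic-strength-sensitive), which is why downstream
checks on free concentrations carry a ±25% tolerance. With these
defaults the standard inside/out bath (10 mM EGTA, 7.13 mM CaCl₂,
3.31 mM MgCl₂, pH 7.2) gives free Ca²⁺ ≈ 0.44 µM and free Mg²⁺ ≈ 3.0 mM,
matching the nominal 500 nM / 3 mM design values of such recipes within
that tolerance.

## Three-cube FRET (`fret`)

Inputs are background-corrected intensities (an optional per-cube
background can be subtracted on construction). The intensity gate
0.5 < I_CFP/I_YFP < 2.0 is strict at both bounds. E_EFF is affine in FR
with slope equal to the extinction ratio (default 0.079 for ECFP/EYFP
through a 440-nm excitation band); FR is invariant under global
rescaling of the DA intensities, so exposure differences between cells
cancel. Interpretation of E_EFF as E·A_b relies on 1:1 stoichiometry
with the acceptor on the limiting moiety; the package reports E_EFF and
leaves the E vs A_b split to the caller. Distance conversion
r = R0·(1/E − 1)^(1/6) requires a user-supplied Förster radius and the
*intrinsic* E — there is deliberately no default R0.

## Occupancy sorting (`occupancy`)

**Keys.** `original_particle_id` is derived from the image name plus
micrograph name and coordinates (rounded to 0.01 px); upstream
conversions that rename images will break the trace-back, in which case
supply a column mapping. `subunit_index` is the rank of the in-plane
rotation angle (mod 360°) within a particle: the four expanded copies
differ by 90° offsets, so rank order reproduces the ring order up to a
cyclic rotation — exactly the invariance the pattern classification has.

**Canonicalization.** The lexicographically minimal cyclic rotation of
the binary occupancy tuple. Only the cyclic group is quotiented (C4, not
D4): mirror-related patterns are distinct in general ring sizes, though
for binary 4-rings mirroring changes nothing. For a tetramer the 16
tuples partition into classes of sizes 1/4/4/2/4/1
(0, 1, 2-cis, 2-trans, 3, 4).

**Integrity.** Particles with a row count different from the symmetry
order are excluded, not repaired, and reported; sorted counts plus
exclusions always reconcile with the input.

**Dialect.** RELION 3.x `data_particles` STAR, parsed and written with
gemmi's STAR machinery; column names are configurable to absorb dialect
drift. cryoSPARC `.cs` files are assumed converted upstream.

## Structure metrics (`structure`)

**Superposition.** Atoms are paired by (chain, residue number, atom
name); unpaired atoms are dropped and counted. Kabsch SVD with the
determinant correction enforces a proper rotation. The conventional
selection for whole-channel comparisons is Cα of the channel chains.

**Interface area.** Shrake–Rupley sampling (default 960 points/atom,
1.4 Å probe, Bondi-style radius table with a 1.7 Å fallback; waters
excluded) through biotite. The headline number is the *per-side* buried
area (SASA_A + SASA_B − SASA_AB)/2 — "contact surface" in the
crystallographic sense — with the total ΔSASA also reported, since both
conventions are common. Doubling the point count changes totals by
< 0.5%; against the closed-form two-sphere cap the error is < 2% at 960
points.

**Domain rotation.** Models are first superposed on a reference frame
(e.g. the transmembrane domain), then the optimal rigid transform of the
domain selection is decomposed. With a supplied axis (e.g. the four-fold
pore axis) the swing–twist decomposition gives the rotation about that
axis and the screw translation along it; the sign follows the right-hand
rule about the supplied axis direction, so "counterclockwise viewed from
the cytosolic side" corresponds to a positive angle about an axis
pointing from the membrane toward the cytosol. Constructed screw motions
are recovered to < 0.1° and < 0.01 Å.

**Deposited models.** Metrics on published coordinate sets (interface
areas, inter-class RMSDs, domain angles of deposited channel/G-protein
complexes) run through the same three functions on files the user
provides; exact residue ranges behind published numbers are usually
unstated, so expect selection-dependent variation at the few-percent
level. The shipped tests validate the machinery on constructed fixtures
with exact ground truth instead of bundling large coordinate files.

## Synthetic data (`synthetic`)

What the generators emulate — and what they do not:

* **Gating traces.** Continuous-time two-state Markov path via
  exponential waiting times (no discretization bias near the dead time),
  started from the stationary distribution, sampled at 10 kHz; white
  Gaussian noise shaped by a 4-pole low-pass Bessel filter at 1 kHz and
  rescaled to the requested post-filter SD. The *signal* itself is left
  unfiltered, so true dwells are exactly recoverable; consequently filter
  rise times, capacitance transients, seal drift and 1/f noise are not
  emulated, and passing idealization tests demonstrates correctness of
  the estimator, not robustness to every amplifier artifact. Default
  unitary current −2 pA with 0.2 pA noise (SNR 10, comfortably above the
  half-amplitude detection regime).
* **Particle tables.** Patterns drawn i.i.d. per particle from the given
  frequencies, a uniformly random cyclic phase (so canonicalization is
  genuinely exercised), random bound/unbound focused-class ids from
  {1, 2}/{3, 4}, and base pose angles in [0°, 90°). Class assignment
  errors of real focused classification are not modelled.
* **Po surfaces.** Default conditions follow the study design this
  package serves: Gαi3 0.07–14.6 µM, eight PIP₂ doses 1–100 µM, six
  replicate patches, 5% additive noise clipped to [0, 1]. K_d^PIP2
  interpolates from 23.3 µM at the lowest to 10.2 µM at the highest Gαi3
  with n = 2 and a two-fold amplitude span, which places peak
  amplification (~7-fold) in the physiological 5–12 µM PIP₂ window. The
  per-column Hill parameters other than the two anchor K_d values are
  this package's choices, since full surface parameters are rarely
  printed.
* **Three-cube sets.** The forward model writes donor bleed, direct
  acceptor excitation and sensitized emission into the three cubes such
  that the analysis equations invert it exactly (noiseless round-trip
  error < 10⁻¹² over the full parameter grid); optional multiplicative
  noise models exposure variability. Donor quenching of S_CFP(DA) is not
  modelled — it cancels from FR by construction and would only matter
  for estimators this package does not implement.
* **Structure fixtures.** Gaussian atom blobs under exact rigid
  transforms, optional coordinate noise; two-sphere "complexes" for the
  analytic buried-area oracle; frame+domain pairs for screw-motion
  recovery.

## Problem sizes in the shipped tests

The test suite runs at desk scale by design: 10–120 s traces for
idealization properties and six 100-s traces for the P_o bias check
(bias < 2% against the stationary value), 200 seeded replicates for
noisy Hill recovery and K_d-ordering checks, 10⁴ particles for fraction
recovery (3σ binomial), and 960-point SASA sampling. These sizes give
the statistical resolution each assertion needs; all scale linearly if
larger runs are wanted.

## Known limitations

* One channel per patch is assumed throughout; records with superimposed
  openings are outside the estimator's model.
* The chelator solver treats only 1:1 complexes (no ML₂ species, no ATP
  as a ligand) and takes apparent constants as given rather than
  computing protonation corrections from absolute constants.
* The occupancy module is metadata-only; it cannot detect misassigned
  focused classes, only inconsistent row counts.
* SASA uses a fixed radius table without hydrogens, matching deposited
  heavy-atom models; adding explicit hydrogens changes absolute areas.
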