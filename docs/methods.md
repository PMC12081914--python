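# Methods

This note records the models implemented in `betahelix`, the assumptions
behind them, the defaults and why they were chosen, and the limitations a
user should know about.

## Rung grammar (`rung`)

A rung is an 18-residue sequence laid out on an equilateral triangle: three
six-residue β-strand sides (`side_spans`, default 1–6 / 7–12 / 13–18) joined
by two covalent three-residue turns (`turn_spans`, default (5,6,7) and
(11,12,13)) plus the non-covalent junction between the terminal prolines.
Indexing is 1-based everywhere a residue number appears (W9 means the ninth
residue).

Motif scanning checks every six-residue window against the two left-handed
β-helix hexapeptide patterns `[LIV][GAED]XX[STAV]X` and `[LIV]GXXXX`,
anchored to the window; `X` matches any standard residue including P and G.
Overlapping windows are reported, and a window matching both patterns
produces two matches.

`check_design` evaluates six rules (length, terminal prolines, G-N-N turns,
single interface tryptophan, lysines off the core, hydrophobic ratio).
Choices that were genuinely open:

- **Hydrophobic set.**  Default {A, C, F, I, L, M, V, W}; P, G and Y count
  as non-hydrophobic.  The ratio rule passes when hydrophobic:other does not
  exceed 1:1.5, i.e. at most 7 hydrophobic residues in 18.  The set is a
  function argument because hydrophobicity scales differ at the margins
  (A, Y, P).
- **Core (inward-pointing) positions.**  The lysine rule requires the
  cationic residues to sit outside the hydrophobic core.  Which positions
  point inward is not derivable from sequence alone; the default takes the
  hexapeptide anchor offsets — the first and fifth position of each side
  ({1,5,7,11,13,17} for the default spans), where the `[LIV]` and `[STAV]`
  anchors of the repeat sit — and is caller-overridable.
- **Turn placement.**  The default turn spans put N6/N7 at the vertex
  adjoining W9, so the two asparagine ladders flank the trimer interface;
  the second turn is taken as 11–13 by symmetry.  Both spans are
  constructor arguments since other assignments are conceivable.

`EXAMPLE_RUNG_SEQUENCE` (`PIKAGNNAWVGNNIKSTP`) is a *synthetic*
design-compliant example used in documentation, models and tests; it is not
a published sequence.  `mass_from_mz` provides the hook for validating a
real candidate sequence against observed assembly ions.

## Peptide arithmetic (`chem`)

Masses are sums of standard residue masses plus water; C-terminal amidation
subtracts 0.98402 Da (monoisotopic) / 0.985 Da (average).  m/z uses a proton
mass of 1.00728 Da.  Monoisotopic values are what electrospray identity
checks quote; both scales are always reported.  The residue table is
cross-checked against Biopython in the test suite.

Net charge and pI use Henderson–Hasselbalch sums over N-terminus, C-terminus
(free acid only), D, E, C, Y, H, K, R with an EMBOSS-style pKa table
(N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8,
R 12.5), configurable because published pI values rarely state their table.
pI is found by bisection to 0.01 pH; a sequence whose net charge never
crosses zero (e.g. a pure polybase amide) has no pI and raises.

Charge ratio CR = (mol peptide × amino groups) / (mol nucleic acid ×
phosphates).  An siRNA duplex of two n-mers contributes 2(n−1) backbone
phosphates by default (20-mer guide → 38 per duplex); overhang chemistry can
change this, so the count is an argument.  Encapsulation efficiency from a
dye-intercalation assay is EE = 1 − (F_complex − F_bg)/(F_free − F_bg),
clamped to [0, 1].

## Solenoid models (`builder`)

Cα-only idealized models, in nm.  The 18 positions of a rung are placed at
uniform arc length δ along the triangle perimeter with sharp corners and a
half-step phase: the first residue of each side sits δ/2 past the corner, so
every vertex falls midway between its flanking residues.  This puts the
terminal prolines symmetrically about the non-covalent vertex and N6/N7
about the interface vertex, and keeps all same-side neighbour distances
exactly δ.

Defaults: δ = 0.34 nm (mid-range of 0.33–0.35 per residue), n_s = 6,
h = 0.47 nm, P = 28.5 nm, left-handed, vertex clearance v = 0.1 nm.  The
twist per rung τ = 360·h/P ≈ 5.94° is applied to single helices and trimers
alike, although the pitch is measured on assembled cylinders only — an
idealisation.  The trimer is three copies related by exact 120° rotations,
each with its interface vertex on the inward-pointing bisector at radius v.

`predicted_diameter` returns √3·n_s·δ (3.5 nm at defaults), i.e. twice the
vertex-to-opposite-side height of the vertex-at-axis packing of perfect
triangles, reported to 0.1 nm.

**Known geometric tension.**  A rigid equilateral triangle of side 2.04 nm
has its proline corner 2.04 nm from the interface vertex, so with the vertex
near the axis the outermost Cα atoms sit at radius ≈ 2.05 nm and the model's
outer diameter (2 × max radial coordinate) is ≈ 4.1 nm — above the ~3.5 nm
side-to-side estimate and slightly above the 3–4 nm envelope seen
experimentally, where corners are rounded and termini flexible.  The
packing was chosen for physical plausibility: the shortest inter-chain
contact is then the W9–N7 pair at ≈ 1.06 nm, matching the 1–1.2 nm
interface contact seen in solvated simulations.  Configurations that squeeze
the outer diameter under 3.9 nm require pushing the vertex past the axis and
produce inter-chain Cα clashes below 0.2 nm; they were rejected.  The
distance-window checks in the acceptance suite record this discrepancy
rather than hide it.

## Coordinate metrics (`metrics`)

Distance maps are dense symmetric matrices (nm), refused above 20,000 atoms
(a desk-scale guard, not an algorithmic limit).  Region statistics take two
label selectors and a statistic (mean/min/max) over cross pairs, excluding
self-pairs; regions are explicit user inputs rather than baked-in
definitions.  Kabsch superposition uses SVD with a reflection guard (the
smallest singular direction is flipped when the optimum orthogonal map is
improper), returning RMSD, the proper rotation and translation.  Radius of
gyration is unweighted.  Backbone φ/ψ follow the IUPAC sign convention;
termini are NaN, and residues with missing atoms are skipped with a warning.

Ramachandran classification uses rectangular regions (degrees): beta
φ∈[−180,−45], ψ∈[45,180]∪[−180,−150]; right-α φ∈[−160,−20], ψ∈[−120,45);
left-handed φ∈(20,125], ψ∈[−45,90]; otherwise "other".  The literature
draws no single set of boundaries, so the rectangles are an explicit,
overridable argument.

## Diffraction (`diffraction`)

Bragg conversion at λ = 1.5406 Å (Cu-Kα) with domain checks (d > λ/2).
Harmonic assignment is a greedy pass from the largest d-spacing: each
candidate fundamental collects every smaller peak whose ratio rounds to an
allowed order n (default {2,3,4,5}) within a relative tolerance (default
2%, which covers a ~1% discrepancy such as 16.5 vs 4 × 4.17 = 16.68).  A
peak may serve in several families; only families with members are
returned.  Peak picking from raw diffractograms is out of scope — the
module consumes peak lists.

## Spectroscopy (`spectro`)

MRE = mdeg / (10 · pathlength · molarity · n_units); n_units defaults to the
residue count (pass N−1 to normalise per peptide bond — both conventions
are in circulation).

The melt model is two-state van't Hoff with linear baselines, temperatures
converted to kelvin internally.  The model-free midpoint (Savitzky–Golay
first-derivative extremum, window 9, cubic, with parabolic refinement) is
reported alongside the fitted T_M, and their discrepancy is exposed, not
hidden.  A transition is declared absent when the peak smoothed derivative
times the temperature span is below 1.5× the signal amplitude — a straight
line gives equality, a sigmoid concentrates slope well above it.

Isodichroic detection interpolates the sign-change crossings of each
consecutive-temperature pair of spectra and returns the median crossing;
pairs that are numerically identical carry no information and are skipped;
a spread above tolerance (default 2 nm) raises instead of averaging away an
ill-defined point.

Second-derivative band picking: Savitzky–Golay (window 9, order 3) second
derivative on a uniform grid; bands are minima with prominence above 5% of
the second-derivative range, refined parabolically, and labelled from an
editable amide assignment table (1623–1625 intermolecular β-strand;
1636/1689 antiparallel markers; 1649–1651 α-helix; 1665–1668 β-turn;
1540–1550 amide II turns).

CAC breakpoint: continuous two-segment piecewise-linear least squares, with
the breakpoint searched over interior grid points plus a 41-point log-spaced
refinement between the best point's neighbours.  Fluorescence noise scales
with signal, so the default estimator is inverse-variance weighted
(sd ∝ |y|); unweighted least squares is available (`weighting="ols"`).
Candidates must have a steeper upper than lower segment, and a single line
is preferred when the two-segment fit improves the (weighted) SSE by less
than 5%.

## AFM numerics (`imaging`)

Pitch extraction: linear detrend, Hann window, one-sided periodogram
(`scipy.signal.periodogram`), peak frequencies refined by parabolic
interpolation of log power; periods are reported sorted by power and the
fundamental is the largest significant period.  Significance accounts for
multiple comparisons: under the exponential null of periodogram ordinates,
with the noise mean estimated as median/ln 2, the threshold
(median/ln 2)·ln(N/α) (α = 0.05) is the level a pure-noise spectrum of N
bins exceeds anywhere with probability α.  A naive "k × median" rule has a
per-bin false-alarm rate of several percent and routinely promotes a noise
bump to "largest significant period" on realistic profiles.  Wave-vector
phrasing in the field is ambiguous about a factor of two, so all significant
periods are reported and the largest is named fundamental — a convention,
not an interpretation.

Tip-dilation correction uses the spherical-tip contact model: a tip of
radius R imaging a step of height h broadens each edge by √(2Rh − h²) while
h < R, and by R once the tip equator makes contact (h ≥ R); total
broadening is twice that, and corrected widths clamp at zero with an
under-resolved flag.  The branch behaviour is validated against a numeric
circle-over-step contact oracle in the tests.

Dimension statistics use the population standard deviation (a single
measurement reports sd 0) and Freedman–Diaconis histogram binning.

## Cell tracks (`tracks`)

Per-track: net displacement, total path, persistence = net/total ∈ [0,1]
(stationary tracks are flagged, not errored), mean velocity = total path /
duration.  MSD is time-averaged per track with overlapping windows, then
ensemble-averaged (the non-overlapping estimator is available); the
anomalous exponent α is the log–log slope from the second lag point to
max_lag_fraction (default 0.25) of the shortest track, limiting lag-estimate
variance.  Tracks must share a common time step; 2-D only.

## Synthetic data (`fixtures`)

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng` — no global state; identical calls are
byte-identical.  Named scenarios live in `scenarios.toml` (version-bumped on
any change):

- `cd_melt_paper`: 20–80 °C at 1 °C, T_M 65 °C, ΔH_vH 400 kJ/mol, folded
  baseline −11000 + 10·T, unfolded −3000 + 5·T, Gaussian noise sd 80
  (≈1% of the ~8000-unit amplitude).  ΔH_vH reflects a sharp, cooperative
  assembly transition that completes well inside the range; a broad
  (≤200 kJ/mol) transition truncated at 80 °C would leave the unfolded
  baseline — and hence T_M — statistically undetermined at realistic noise.
- `ftir_melt_paper`: 25–80 °C at 5 °C, T_M 67 °C, ΔH_vH 400 kJ/mol, noise
  sd 0.002 on a 0.8-unit amplitude (64-scan absorbance averaging is clean;
  with only 12 points the midpoint is unrecoverable at percent-level noise).
- `tht_paper`: two-fold serial dilution 100 → 1.5625 µM, breakpoint
  12.5 µM, segment slopes 1 and 40 a.u./µM, 2% multiplicative noise.
- `afm_pitch_paper`: 570 nm profile at 0.5 nm steps, 28.5 nm period,
  amplitude 1.5 nm plus a 0.5 nm second harmonic, 0.2 nm height noise.
- `cd_isodichroic_paper`: seven spectra on 190–250 nm, linear mixtures of a
  β-helix-like basis and a tilted copy crossing exactly at 204 nm, noise
  sd 0.02.

What the generators emulate — and what they do not.  They reproduce the
*numerical* structure of the measurements (grids, amplitudes, noise scale,
the planted parameter) so that estimator correctness and statistical
behaviour can be tested by round-trip recovery.  They do not emulate
instrument systematics (baseline drift beyond linear, wavelength shifts,
detector saturation), sample heterogeneity, or any physics beyond the
two-state/two-segment/sinusoidal models themselves.  A passing round-trip
therefore shows the estimator recovers parameters under the stated noise
model; it does not show that real data obey that model.

## Problem sizes

The test suite and the reproduction script run on desk-scale inputs: models
up to a few hundred rungs (tens of thousands of Cα atoms at the distance-map
bound), 61-point melts, 7-point titrations, 1140-sample profiles, and track
ensembles of ≤500 walkers — sizes chosen to match the corresponding
measurements, and to keep every analysis well under a minute.

## Known limitations

- Models are Cα-only; no side chains, sterics or energetics.  Backbone
  dihedral analysis requires full N/CA/C input (e.g. from a PDB file); the
  package does not generate full backbones.
- Sharp triangle corners overestimate the outer diameter of the cylinder
  (see the geometric tension above).
- The melt fit assumes two-state behaviour with linear baselines; the
  derivative midpoint is the model-free fallback when that assumption is
  doubtful.
- Harmonic assignment is purely arithmetic on d-spacings; it does not weigh
  intensities or synthesize unobserved orders.
- Track metrics assume uniform sampling and 2-D projection; depth changes
  and drift beyond a linear trend are not modelled.
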