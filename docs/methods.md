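# Methods

This note records the scientific model behind `vcgsim`, the defaults and
their rationale, the numerical choices, and what the synthetic data do and
do not establish.

## Coordinate and sign conventions

The frontal plane uses x positive toward the anatomical left and
y positive toward the feet. This makes the clinical hexaxial angles
native: lead I points along 0°, lead II along +60°, lead III along +120°,
and a normal QRS axis of +60° is literally the vector (cos 60°, sin 60°).
Plotting flips the y axis so loops render superior-up. Angles are stored
in degrees in the public data model (radians internally) and reported in
[−180°, 180°), with the +180° boundary mapped to −180°.

The limb assignment places RA upper-left, LA upper-right and LL at the
bottom of an equilateral triangle centred on the origin. With
`DI = V(LA) − V(RA)`, `DII = V(LL) − V(RA)`, `DIII = V(LL) − V(LA)`,
Einthoven's law `DII = DI + DIII` is an identity of the construction, and
the package treats any violation as a data diagnostic, never as something
to repair.

## Forward models

**Ideal projection** maps a heart vector (V_h, α) to
`DI = V_h cos α`, `DIII = V_h cos(α − 120°)`, with DII synthesized from the
identity so the law holds to the last bit.

**Resistive tank** abstracts a saline-bath rig as DC point-source
superposition in a homogeneous half-space:
`V = I/(2πσ)·(1/r_src − 1/r_sink)` (factor `1/(4πσ)` for a full space),
distances in metres. Assumptions and deliberate omissions:

- The medium is quasi-static and purely resistive. Electrode double-layer
  capacitance and any transient behaviour of the physical cell are out of
  scope; a DC-driven bath read at sampling rates far below electrochemical
  time constants is adequately described by the resistive solution.
- Container walls are ignored (no method of images). This biases absolute
  potentials but cancels substantially in lead differences near the
  centre; it is a known deviation of the model, as it is of the physical
  rig itself relative to a torso.
- Electrodes are points; source/sink depth is ignored (2-D positions with
  the half-space factor).
- Defaults: side length 100 mm, conductivity 1.5 S/m (a reasonable value
  for 0.9 % NaCl at room temperature; configurable because bath salinity
  and temperature vary), source current 1 mA, sink at the centroid.
- The raw differential voltages of a central-anode rig come out
  sign-flipped; the model reproduces this (`polarity_inverted=True`) and
  the processing order is fixed: raw voltages → subtract calibration
  offsets → polarity correction. Calibration offsets are per-lead means of
  raw readings taken at a reference position, so both steps act on the
  same (raw) convention.

Near-field behaviour: at source displacement r from the sink, lead
amplitudes grow as r with a relative deviation from linearity of ~0.2 %
at r = 0.05·L, ~1 % at 0.1·L and ~2.6 % at 0.15·L (L = side length).
The waveform of a circular trajectory correspondingly carries a few
percent of harmonic distortion (≈9 % rms at r = 0.1·L). Conformity checks
therefore compare *fitted fundamental amplitudes* across radii (≤2 % error
for radius pairs within 0.15·L) rather than insisting the waveform itself
is a pure sinusoid.

## Reconstruction

The mean-electrical-axis relation
`V_h = DI/cos α`, `tan α = 1/√3 + (2/√3)·DIII/DI` is algebraically exact
for any single-dipole projection but numerically fragile (division by DI,
quadrant-blind arctangent). The implementation uses the equivalent
Cartesian form `v_x = DI`, `v_y = (DI + 2·DIII)/√3` with `atan2`, which
agrees with the printed form wherever DI > 0 and extends it to DI ≤ 0.
A sign-flipped variant (`printed_signs=True`, negating v_y) is provided
for leads whose central-anode polarity has *not* been corrected
(equivalently, a y-up display convention); it reflects α about the x axis.

Choices at the edges:

- An all-zero triplet returns V_h = 0, α = 0 with a degeneracy flag rather
  than raising: a calibrated rest state is a legitimate zero.
- DII never enters reconstruction. Perturbing DII changes only the
  Einthoven residual `DII − DI − DIII`, which is attached to loops as a
  per-sample diagnostic. When the worst residual exceeds 5 % of the
  record's peak lead magnitude (configurable), a warning is emitted and
  reconstruction proceeds — real ECG leads are not an exact single-dipole
  projection and must not be rejected.

## Synthetic trajectories

**Circles** validate conformity: the ideal model gives each lead a
sinusoid `g·r·cos(ωt + φ_lead)` with φ = 0/−60°/−120°, so amplitude
ratios equal radius ratios and frequency ratios equal angular-velocity
ratios exactly; the tank model reproduces this to the near-field accuracy
above. The ideal gain default is 0.01 V/mm.

**Cardiac cycles** use a teardrop parametrization per wave: over
normalized phase s ∈ [0, 1], `V_h = A sin(πs)`,
`α = axis + direction·spread·cos(πs)`. The loop departs from and returns
to the origin (sin 0 = sin π = 0), sweeps from axis+spread to
axis−spread, and passes the mean axis exactly at peak magnitude — a
smooth, closed, oval-like loop. This parametrization is the package's own
synthetic construction; no claim of physiological derivation is made.

Defaults (chosen to resemble textbook-normal frontal-plane values, and
fixed once): amplitudes P/QRS/T = 0.1/1.0/0.3 V, axes 50°/60°/45°,
spreads 25°/40°/20°, durations 90/85/180 ms, isoelectric PR/ST/TP
segments 60/100/300 ms (cycle 0.815 s ≈ 74 bpm). The `hand` time scale
multiplies every duration by 12.5, mapping the ~80 ms QRS to ~1 s, the
pace at which a human traces loops by hand. Default traversal is
counterclockwise in the y-inferior convention. Noise is additive i.i.d.
Gaussian per lead (not correlated torso noise), seeded. The `altered`
preset drops every k-th QRS loop (default k = 3) while P waves continue —
an illustrative conduction-block caricature, not an arrhythmia model.

The default sampling rate for cycle synthesis is 800 Hz; at that rate the
QRS apex falls exactly on the sample grid of the default durations, which
is convenient but not required — recovery tolerances hold for generic
rates via the estimator below.

**What the generator does not emulate:** baseline wander, powerline
interference, respiratory axis modulation, beat-to-beat variability,
correlated inter-lead noise, and any non-dipolar content (its records
satisfy Einthoven's law exactly up to the added noise). Tests that pass on
these records establish the correctness of the pipeline's mathematics,
not robustness to real-world ECG artefacts.

## Loop-parameter recovery

`peak_vector` estimates the maximal heart vector of a loop. Naive argmax
of |V| is noise-fragile: near the apex the magnitude is flat while the
angle moves quickly, so small magnitude noise produces large angular
jitter. The estimator therefore: (1) locates the apex on
moving-average-smoothed Cartesian components (21 ms window); (2) takes
the *orientation* from the magnitude-weighted mean vector over the apex
cap (samples ≥ 80 % of the smoothed maximum) — exact for loops symmetric
about their axis, and averaging ~n_cap samples of noise; (3) takes the
*magnitude* from a least-squares quadratic fitted to the raw magnitude
within ±16 ms of the apex, avoiding both smoothing attenuation and
single-sample noise. For noisy records, `beat_average` (sample-wise mean
over cycles of known length) gives the usual √m noise reduction first.
With eight averaged cycles at 5 % noise, recovery errors stay ≈1° and
≈2 % across 100 replicates; noiseless recovery is ≈1e-14 ° and ≈0.05 %
(the residual magnitude bias of the quadratic apex fit).

## Dynamic time warping

Classic DP with the symmetric unit-weight step pattern
{(1,0), (0,1), (1,1)}, local cost |x−y| (squared selectable), optional
Sakoe–Chiba band. Backtracking breaks ties toward the diagonal, then the
vertical predecessor, making paths deterministic. The normalized distance
divides by the number of path steps. Z-normalization before alignment
defaults on, because amplitude mismatch between operators/devices is
expected and the comparison should be scale-free.

Similarity is not a standardized quantity; two definitions are computed
and both appear in every report: `100·max(0, ρ_warped)` (default) and
`100·exp(−d_norm/scale)`. Neither is claimed to reproduce any particular
published similarity figure, which generally depends on unstated formulas
and private recordings.

A property worth knowing: the warped-correlation *null* for two
independent white-noise sequences is strongly positive (≈0.78 at
n = 1000), because unconstrained warping pairs similar values by
construction. The normalized distance separates genuinely related records
from noise far more cleanly (≈0.01 for a true time-warped copy vs ≈0.47
for independent noise after z-normalization); reports include both so
users are not misled by a high ρ alone. The warped correlation of a
negated copy is −1 only along the identity alignment — DTW's own optimal
path for x vs −x re-warps the pair.

The DP is O(N·M) in time and memory in straightforward numpy/Python;
records of a few thousand samples align in seconds, which fits the
interactive and test workloads this package targets. Long recordings
should be windowed or decimated first.

## I/O and determinism

The CSV dialect (`time_s,DI,DII,DIII`, volts, `#` comments) is written
with 17 significant digits and read back with round-trip float parsing,
so write→read is bit-faithful and seeded CLI runs are byte-identical.
A missing DII column is synthesized from Einthoven's law with a warning.
Non-uniform time grids are rejected unless resampling is explicitly
allowed (linear interpolation onto the median step). Readers for binary
waveform-database formats are intentionally absent: converting to the CSV
dialect externally keeps the package dependency- and download-free.

## Known limitations

- The tank model's harmonic distortion grows with r/L; conformity claims
  are limited to r ≤ 0.15·L.
- The teardrop cycle cannot represent notched QRS complexes, biphasic
  waves, or ST displacement.
- `peak_vector` assumes a single dominant wave within the record (use it
  per averaged beat, not across long multi-beat strips).
- DTW cost is O(N·M); no pruning or lower-bounding is implemented.
- Frontal plane only; no sagittal/transverse loops or 3-D lead systems.
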