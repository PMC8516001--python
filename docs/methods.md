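# Methods

This note documents the models, estimators and design choices behind
`unfoldmap`, in the order a trajectory passes through the pipeline.

## Trajectory model

Coordinates are a `(T, N, 3)` array of Å bound to an ordered atom list.
Author residue numbering from the input file is kept verbatim in
`residue_id` and used in every report; analyses index residues internally
by a contiguous 0-based index. Multi-model PDB is the supported trajectory
interchange format (one frame per MODEL); plain coordinate tables
(T rows × 3N columns) can be bound to an existing topology. Binary MD
formats are out of scope. Water is recognised by residue name
(HOH/TIP3/TIP3P/SPC/WAT); hydrogens by the element column when present,
else by a leading-character heuristic on the atom name — a tolerance for
PDB dialects that lack element records.

## Coarse graining

Each residue is reduced to one representative point per frame. The default
scheme is the centroid of the side-chain heavy atoms, falling back to Cα
for glycine or missing side chains; `CB_or_CA` and `CA` schemes are
offered for users who want to match other conventions. The centroid was
chosen because it is rotation-robust and defined for every residue; which
single side-chain atom other toolchains pick is, in general, not
documented, so no attempt is made to reconstruct any particular one.

Pairs with |i − j| ≤ excl are excluded (default excl = 1: bonded
neighbours carry no information about tertiary rearrangement). The default
distance cutoff is infinite; when finite, the pair roster is fixed on
frame 0 — a time-varying roster would make X_ij(t) ill-defined as a
series. The rate series is the absolute forward difference
|X(t+1) − X(t)|, length T − 1; when paired with a per-frame scalar, the
scalar is truncated to its first T − 1 samples. A forward difference is
the simplest causal estimator, and one documented alignment rule beats a
cleverer scheme with an ambiguous one. No periodic-boundary minimum-image
handling is applied: the intended inputs are whole solvated molecules
where protein-scale distances never wrap.

## Activity function and order parameter

The activity a(t) is a Gaussian-windowed RMSF: with truncated-Gaussian
weights w_k ∝ exp(−k²/2σ²) over k ∈ [−δ, +δ], clipped at the trajectory
bounds and renormalised,

    RMSF(t) = sqrt( mean_a Σ_k w_k ‖r_a(t+k) − μ_a(t)‖² ),

where μ_a(t) is the same-weighted mean position of atom a. Defaults:
δ = 5% of the frame count (rounded, minimum 1, with a warning below 20
frames), σ = δ/2 (so the ±δ truncation keeps ≈95% of the Gaussian mass),
atom selection Cα. The σ and selection choices are package conventions —
the windowed-RMSF idea fixes neither — and both are configurable. Values
are in Å but are best read as arbitrary units; normalisation is never
applied silently. Coordinates are centred on frame 0 before the windowed
moments are formed: the statistic is invariant to a constant rigid shift,
and centring avoids catastrophic cancellation in the E[x²] − E[x]² form
(a static trajectory yields exact zeros).

The order parameter is the RMSD from the frame-0 conformation, by default
*without* rigid-body superposition: in a pulling run the deviation should
reflect the stretching itself, which superposition would remove. Kabsch
superposition (scipy's `Rotation.align_vectors`) is available as an
option, and an external per-frame series can be supplied instead.

Pulling-schedule arithmetic uses 1 m/s = 0.01 Å/ps: duration_ns =
extension_Å / (10 × velocity_m_per_s), step count = duration / timestep.

## Mutual information

The estimator is plug-in MI on discretised series, reported in bits:

    I(x, y) = Σ_ab p(a,b) log2[ p(a,b) / (p(a) p(b)) ]

over occupied cells of the joint histogram. Discretisation is
equal-frequency (quantile) binning by default — an adaptive rule that
spends resolution where the data mass is and makes direct-mode values
invariant under strictly monotone transforms of either series (up to
quantile-edge ties); equal-width binning is available. The automatic bin
count is clamp(floor(sqrt(T/5)), 4, 16), a compromise between resolution
and the plug-in estimator's positive bias, which grows roughly as
(bins−1)²/(2 ln 2 · T). A constant series occupies a single bin and gives
MI = 0 rather than an error. Cell contributions are totalled with `fsum`,
so I(x, y) = I(y, x) holds exactly, not merely to round-off.

An optional permutation null (shuffling the scalar series with a seeded
generator) calibrates the bias: the MI of truly independent series should
fall inside its own null. The default is no permutation test, since the
reported quantity is the raw normalised MI.

Normalisation divides the matrix by its global maximum (an all-zero matrix
passes through unchanged). Min–max shifting was rejected because
subtracting the smallest matrix element would manufacture an artificial
zero. Selection keeps pairs with normalised MI strictly greater than the
threshold (default 0.7); ties at the threshold are impossible by
strictness, and ties for the maximum are all kept. Block scores average
the matrix over ordered segment pairs (intra-segment blocks use i < j
only) to quantify the block structure a heat map shows visually.

## Structural analyses

*Hydrogen bonds.* Geometric criterion: donor–acceptor distance
≤ 3.5 Å **measured between the heavy atoms** (the convention of the common
visualisation tools, not H···A), and D–H–A angle within 45° of 180°.
Donors and acceptors are protein N/O heavy atoms; covalent D–H attachment
is inferred by a D–H distance < 1.2 Å since no bond table is parsed.
Intra-residue bonds are excluded. Bond-set membership (for per-set count
series) is orientation-agnostic, because β-sheet hydrogen bonds alternate
direction along paired strands. Whether side-chain donors/acceptors should
be excluded for a backbone-only count is genuinely open; the default
counts all N/O atoms within the set ranges.

*Water shells.* Water oxygens (name OH2/O/OW in water residues) within a
radius (default 4.0 Å, always explicit in output headers) of any atom of
each listed residue; the aggregate series counts each water once even when
it sits near several listed residues.

*Triplet angles.* The angle at the middle residue's Cα between the vectors
to the flanking residues' Cα atoms, in [0°, 180°]; coincident points raise
an error naming the frame.

*Smoothing.* Centred moving average, default window 11 frames (±5), odd
windows only. The window shrinks at the series edges so output length
equals input length — the alternative (shorter output) would silently
misalign smoothed and raw series.

*Hydropathy.* A residue is in contact with the opposite part of a segment
pair when any of its heavy atoms is within 4.5 Å of that part (hydrogens
excluded by default so the result does not depend on protonation).
Contacts are evaluated on a single reference frame, default frame 0, since
the analysis characterises the folded-state interface. Contact and
non-contact means are reported per part and pooled (both aggregation
levels are defensible; reporting both costs nothing). An empty set's mean
is reported as missing, never as zero. The Kyte–Doolittle (1982) and
Black–Mould (1991) scales are bundled; the former is signed, the latter
non-negative by construction.

## Synthetic data

`make_unfolding_trajectory` emulates the phenomenology of a
constant-velocity pulling run, not its physics. Residues are pseudo-atoms
(one CA, one CB offset 1.5 Å perpendicular to the local chain direction,
so centroid and Cα schemes give distinct but correlated series) on a
gentle self-avoiding helix, 3 Å apart along the chain axis. The chain is
partitioned into rigid segments; each *responsive* segment and everything
downstream translates along a separation axis by a planted ramp, linear by
default (constant-velocity pulling) with 20 Å amplitude over 1,000 frames,
cumulative when several responsive boundaries are present. I.i.d. Gaussian
jitter (default σ = 0.5 Å per atom per frame) models thermal noise; it is
deliberately white, the simplest null under which the MI independence
properties must hold — autocorrelated (Ornstein–Uhlenbeck) noise is a
possible extension, not the default. The defaults (50 residues ≈ a small
single-domain protein, 1,000 frames matching a typical SMD frame count,
20 Å ≈ a large-scale separation, 0.5 Å ≈ thermal fluctuation amplitude)
are the package's standard test conditions.

The planted truth records exactly the residue pairs spanning a responsive
boundary and the exact ramp series, so tests can run the direct-MI mode
against either the stored ramp (external order parameter) or the computed
RMSD. What passing on this generator shows is that the pipeline recovers a
genuine distance–order-parameter dependence against white noise; what it
does not show is robustness to correlated solvent-driven motion, partial
unfolding intermediates, or force-field artefacts — real-trajectory
behaviour is out of the generator's scope by design.

The hydrogen-bond fixture places an N–H···O triple at an exact requested
donor–acceptor distance and D–H–A angle; the solvation fixture places
water oxygens uniformly in the shell [r/2, r] (spares parked at 10 r) so
the counting routine must recover a prescribed schedule exactly, for any
seed.

## Determinism and numerics

Every stochastic component takes an explicit seed (`numpy`'s PCG64);
identical config + seed reproduce every output byte, and output files
carry provenance headers (version, seed, config hash). Matrix exports use
`%.6g`; series exports `%.10g`, which round-trips the values to reading
precision. Angles are clipped into [−1, 1] before `arccos`. Degenerate
inputs (constant series, all-zero matrices, empty selections) pass through
with defined results rather than errors wherever a defined result exists.

## Known limitations

* The MI estimator is the package's documented replacement for adaptive
  density estimation used elsewhere in this problem domain; plug-in MI on
  quantile bins has a known positive bias at small T (use the permutation
  null when absolute values matter).
* Heat-map rendering is intentionally absent; the TSV exports are designed
  to drop into any plotting tool.
* The rate-mode analysis carries little signal when the global change is a
  smooth slow ramp (the per-frame increment is far below the jitter
  level); the direct mode is the right tool for directional perturbations,
  and the rate mode for burst-like activity.
* PDB is the only trajectory format; converting binary MD output is left
  to the user's toolchain.
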