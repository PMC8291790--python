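# Methods

## Salt-bridge model

A salt bridge is scored between an acidic side-chain carboxylate oxygen
(Asp OD1/OD2, Glu OE1/OE2) and a basic side-chain nitrogen (Lys NZ;
Arg NE/NH1/NH2; His ND1/NE2) when the minimum oxygen–nitrogen distance is at
or below the cutoff.  Defaults and their rationale:

- `cutoff = 3.2 Å` — the "strong" salt-bridge convention used when comparing
  thermophilic homologs; exposed as `--cutoff`.
- Histidine is basic by default (`include_his`): published comparative tables
  include His bridges (e.g. `D87–H90`), and protonation states are unknown in
  crystal or homology models.  The imidazole's charge is pH-dependent, so the
  flag exists for users who want a strict Lys/Arg set.
- Arg NE is included alongside NH1/NH2 because the guanidinium charge is
  delocalized over all three nitrogens.
- Terminal charges (OXT, N-terminal amine) are excluded: comparative tables
  list side-chain pairs only.
- No sequence-separation filter: adjacent-in-sequence pairs are genuine
  bridges in these tables (e.g. `E367–R369`).
- One bridge per residue pair, with the minimum qualifying atom-pair distance
  recorded; intra-chain by default (`--interchain` to relax).
- Residues of a charged type with no side-chain charged atoms in the model
  (truncated side chains) are skipped and counted in a warning.

These conventions are deliberate choices, not fitted values.  If counts on a
particular structure disagree with another tool, sweep `include_his`, the Arg
atom set, and the cutoff rather than editing code; all are keyword arguments.

A *network* is a connected component of the residue–bridge graph with at
least two edges — a single bridge is never called a network.  Components are
computed with networkx; the test suite re-derives them with an independent
union-find oracle.

Wild-vs-mutant diffs match bridges position-wise: a bridge is retained when
both endpoints keep their positions, even if a declared substitution changed
the residue type at one endpoint (the mutation map argument).  Gained =
mutant-only, lost = wild-only; network preservation asks that every edge of a
wild network has a positional match in the mutant set.

## Comparative design

Inputs: an alignment of the target with thermostable homologs (aligned FASTA
or Clustal; per-sequence start numbers let a mature protein count from, say,
residue 23 after signal-peptide removal) and one bridge set per enzyme,
either detected geometrically or parsed from a published table.

1. **Participation table.** Both endpoints of every bridge are projected
   onto alignment columns (strictly monotonic position↔column maps; gaps
   unmapped).
2. **Hotspots.** A column is a hotspot when at least `support` distinct
   homologs (default 2 — the observed pattern is "two or three homologs per
   spot") contribute a bridge residue there and the target contributes none.
   Hotspot count is non-increasing in `support` by construction.
3. **Coordinating positions.** For every bridge supporting a hotspot, the
   partner endpoint's column is located in the target.  The residue required
   there is the majority partner residue across homologs; the position is
   reported only when the target residue *differs from that residue*.  The
   exact-residue rule (rather than charge class) is deliberate: a Lys at a
   position where homologs use a bidentate Arg cannot partner two acidic
   residues at once, so K→R is a real design requirement, while a target
   already carrying the required Arg is correctly skipped.
4. **Proposals.** One proposal per position: hotspot proposals copy the
   majority charged residue among the supporting homolog residues (D/E/K/R
   vote; His supporters do not vote because the copied charge should be
   pH-robust; ties prefer E over D and K over R), coordinating proposals copy
   the needed partner residue.  Positions where the target already holds the
   proposed residue are dropped, and duplicates resolve in favour of the
   hotspot role.
5. **Evaluation.** Given wild and mutant structures (detected with identical
   parameters) or declared bridge sets, the report lists gained/lost bridges,
   flags each proposal as productive when a gained bridge touches its
   position, and checks preservation of every wild-type network.

### The packaged worked example

The worked example ships the published bridge tables of the cold-adapted
target (9 bridges), three thermophilic homologs (24, 13, 12) and the
eight-site mutant (13), plus an alignment of the four enzymes.  The original
alignment figure exists only as an image, so the packaged file is a
**synthetic stand-in**: a deterministic builder lays one backbone column per
target position, anchors the homolog bridge residues whose correspondences
the published hotspot annotations imply (five hotspot columns over target
positions 61/236/268/277/409; partner columns at 156/243/390; partner columns
where the target already carries the required charge at 35/178/214/246/250/
255/419), and places every other homolog residue in its own single-sequence
insertion column.  Background residues are drawn from uncharged letters with
a fixed seed.  The design engine applied to this input *derives* the five
hotspots, the three coordinating positions and all eight published mutations
(N61E, K156R, P236E, T243K, D268E, T277D, Q390K, R409D); none of those
outputs is hard-coded.  At the fifth hotspot the stand-in aligns three
homolog acids (E/D/D), giving the strict Asp majority that the published
R409D implies.  A stand-in built from different anchor choices could yield a
different proposal set; the packaged file is data, frozen in the repository,
and a test asserts it matches the builder byte-for-byte.

## Trajectory flexibility

- **Superposition** is a hand-written Kabsch fit (SVD with determinant
  correction, so the rotation is always proper).  A mobile selection that is
  collinear (second singular value ≤ 1e-8 of the first) is rejected — the
  rotation about the axis would be arbitrary.  A collinear *reference* (e.g.
  the exactly straight mean structure of an idealized chain fixture) is
  tolerated: the rank-deficient cross-covariance still yields an optimal
  rotation.  Correctness is checked against a random-quaternion grid search
  and against MDAnalysis in the tests.
- **RMSD**: per-frame, over a named atom selection, after superposition onto
  the first frame or a supplied reference; `superpose=False` supports pinned
  closed-form checks.
- **RMSF**: computed over the trailing `window` fraction of frames (default
  0.4, generalizing "the final 8 ns of a 20 ns run").  Frames are superposed
  onto an iteratively refined mean structure (tolerance 1e-6 Å, ≤20
  iterations); `reference="first"` is provided because the original analyses
  do not state which convention they used, and neither mode is asserted as
  canonical.  Replicate profiles can be averaged (`average_profiles`),
  mirroring duplicate simulations.
- **Region comparison**: a region is *rigidified* when its mean RMSF drops by
  more than `min_delta` between variants, *flexibilized* when it rises by
  more, else unchanged.  `min_delta = 0.05 Å` is a package choice (no
  published threshold exists) and is exposed everywhere.

Binary MD formats are out of scope; trajectories enter as multi-model PDB or
XYZ, converted upstream.

## Kinetics

`arrhenius_ea` is an ordinary least-squares fit of ln v on 1/T(K)
(`scipy.stats.linregress`), Ea = −slope × 8.314 J K⁻¹ mol⁻¹ reported in
kJ/mol with r² so users can flag non-Arrhenius curvature; no weighting.
`peptide_mass` sums average residue masses plus one water (Biopython's
tables) — average, not monoisotopic, to match gel-scale estimates.
`normalize_activity` rescales to percent-of-maximum (optimum curves) or
percent-of-control (residual-activity stability curves).

## Synthetic generators and what they do not show

- `make_structure` plants exact charged-atom geometries on a 10 Å residue
  grid: each planted pair's nearest charged atoms sit at the requested
  distance and all unplanted charged pairs stay several Å beyond the cutoff.
  The scaffold is not physical protein geometry — no backbone continuity, no
  sterics — so passing tests demonstrate detector correctness, not realism of
  any structural model.
- `make_trajectory` oscillates each Cα sinusoidally with a planted peak
  amplitude *a* about an ideal chain over whole periods, making the pinned
  RMSF exactly a/√2.  Real trajectories have correlated, anharmonic motions;
  the fixture validates the estimator, not MD behaviour.  Under full
  superposition some fluctuation is redistributed along the chain, so exact
  amplitude recovery is asserted in the pinned frame and rank agreement in
  the fitted frame.
- `make_rates` draws v(T) = A·exp(−Ea/RT) over 0–35 °C in 5° steps, with
  optional Gaussian noise on ln v.  Noiseless tables are recovered exactly
  for any Ea in 10–100 kJ/mol; with σ = 0.05 and 8 temperatures the mean of
  200 replicate fits stays within 5% of truth.  The default Ea of
  39.4 kJ/mol matches the scale of published wild-type values but is a
  generator parameter, not a reproduced measurement.
- All generators are deterministic under their seed (byte-identical files).

## Problem sizes

The packaged worked example is analytical (milliseconds).  The acceptance
script uses 20 planted-structure round trips, 50-frame/200-residue
trajectories, and 200 Arrhenius replicates at 8 temperatures — sizes chosen
so the whole reproduction runs in seconds while keeping the stochastic checks
well-sampled.

## Known limitations

- No electrostatics, pKa, or ΔΔG: detection is purely geometric, and residue
  choice copies homolog charge classes rather than optimizing energy.
- Hotspot/coordinating role labels can be construction-dependent when a
  position could be reached both ways; only the position set is robust.
- The geometric detector has been validated against brute-force scans and
  planted fixtures; counts on specific published structures depend on their
  exact coordinates and the convention flags above.
- Structure reading keeps the first model and drops waters, ions, ligands
  and hydrogens implicitly present in the files; altloc duplicates resolve to
  the highest-occupancy conformer.
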