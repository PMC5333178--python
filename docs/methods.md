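# Methods

This note records the model behind `ligandpath`, its tunable parameters,
the numerical choices made where the design was open, and what the
synthetic scenarios do and do not demonstrate.

## Data model and conventions

A trajectory is a `FrameSet` (per-frame protein atom coordinates with
residue/atom metadata, optional partial charges and radii, frame spacing
`dt` in femtoseconds, default 2) plus a `LigandTrajectory` of reference
positions `P(x)`, one per 0-based time step. All coordinates are Angstrom;
intervals are half-open `[start, end)`. The ligand reference point is the
unweighted centroid of the ligand's atoms; a mass-weighted centre is
available (`ligand_reference="mass"`). For a single-atom ligand both
coincide.

The baseline trajectory dialect is multi-model PDB, read and written with
biotite; binary formats go through MDAnalysis and require a topology.
Partial charges come from PQR (occupancy-column convention, MDAnalysis
reader). When charges are absent, charge-dependent attributes are reported
as *missing*, never zero — zero is a meaningful charge. Van-der-Waals radii
use a small element table (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å);
unknown elements fall back to 1.70 Å with a one-time warning.

## Attributes

**Stuckness.** `s(x)` is the ratio of the maximal pairwise displacement to
the summed step lengths over a `2n+1` window (default `n = 4`), clipped at
the trajectory ends. It is scale- and rigid-motion-invariant and equals 1
exactly for monotone straight motion. Because the quantity is *high* for
straight motion but the phenomenon of interest is oscillation, the table
carries both `straightness` (= `s`) and `stuckness` (= `1 - s`); plots
default to the latter. A frozen window (path length < 1e-9 Å) makes the
ratio 0/0: we report straightness as missing and stuckness as 1.0 with a
`frozen` flag — an immobile ligand is maximally stuck.

**Active site, distance, direction.** The active-site position is the
mass-weighted centre of all atoms of the listed residues, recomputed per
frame. Direction is the sign of the discrete distance derivative:
decreasing distance = "toward". Exact ties inherit the previous label, the
first step defaults to "away", and the final step repeats its predecessor.
These tie/endpoint rules are conventions; only the sign rule is inherent.

**Free space.** With an imported sphere profile, the radius of the sphere
containing `P(x)` whose centre is nearest (nearest-centre tie-break); if no
sphere contains the ligand, the nearest sphere's radius with an
`outside_tunnel` flag. Without a profile, the *temporal tunnel*: centre =
mean of the 10 protein atoms nearest `P(x)`, radius = distance from that
centre to the closest protein atom. By construction the radius never
exceeds the distance to any atom.

**Lining, profiles, turnover.** Residue–ligand distances are
vdW-*surface* distances (centre distance minus both radii, clamped at 0);
a 2 Å centre-to-centre cutoff would select almost nothing, so the lining
cutoff (default 2 Å) applies to surface distances, with a centre-to-centre
mode available. The k = 3 closest residues feed the timelines and the
turnover count (symmetric difference of consecutive lining sets, hence
≤ 6). The hydrophobicity profile is the unweighted mean of a residue scale
(Kyte–Doolittle bundled; two-column files loadable) over residues within
the cutoff; the charge profile is the mean partial charge of in-range
atoms. Empty selections are missing, not 0.

**Classification.** Priority order: *active-site* if
`d_AS <= 4 Å`; else *outside* if the minimal surface distance to any
protein atom exceeds 5 Å; else *inside* if ≥ 40 protein atoms lie within
8 Å (centre–centre) of `P(x)`; else *surface*. The taxonomy is standard;
the thresholds are package defaults exposed in `CategoryThresholds` and
chosen to be geometrically meaningful for globular proteins of radius
~10–15 Å (a buried position in such a protein has on the order of 40–80
heavy atoms within 8 Å).

**Smoothing and aggregation.** The sliding window is a centred moving mean
(odd window, clipped at the ends) that skips missing values; uniform bar
aggregation splits steps into near-equal half-open bins (remainder on the
leading bins) with per-bin means over non-missing values and the modal
category, ties broken by the classification priority.

## Simplification

**Complexity.** The turning complexity at a vertex sums
`(|u|+|v|)^2 * alpha(u, v)` over consecutive segment pairs whose segments
lie entirely within arc-length `nu` of the vertex (both endpoints closer
than `nu` along the polyline — strict inequality). Angles are radians, so
`c(x)` carries units of rad·Å² and is exactly 0 on collinear input.
Zero-length segments have no direction and contribute nothing. The stretch
variant divides the neighborhood's path length by the chord between its
first and last vertex; it is ≥ 1 wherever a segment exists, and a chord
below 1e-9 Å (closed sub-loop) receives a sentinel of 1e6 with a flag —
closed loops are legitimately "maximally complex", and a sentinel avoids a
division by zero. Defaults: `nu` = 2 Å, threshold `tau` = 1 rad·Å²,
improvement threshold `eps` = 1 % of the initial total complexity. The
`tau`/`eps` defaults are package choices (a gentle real-scale curve —
turning ~0.1 rad per 0.7 Å step — scores ≈ 0.7 rad·Å², just under `tau`,
while thermal jitter scores an order of magnitude higher).

**Levels and back ends.** A "simplification level" k on an interval means:
smoothing back end — k successive Savitzky–Golay passes (window 9, order 2
by default) over that interval's points; vertex-preserving back end —
Douglas–Peucker at tolerance `base * 2^(k-1)` (base 0.5 Å). Both are
monotone and composable, which makes incremental updates well defined.
Savitzky–Golay windows shrink to the largest valid odd size on short
segments (segments under 3 points pass through unchanged), and the first
and last point of every smoothed interval are pinned so the global
polyline stays continuous across interval joints; there is no
cross-interval blending.

**Interactive scheme.** The state is a contiguous interval partition of
`[0, N)` with per-interval levels; adjacent equal-level intervals merge.
An edit `(start, end, level)` is applied incrementally from the cached
trajectory only when the edited range coincides exactly with one maximal
cached interval of uniform level ≤ the target and does not merge with an
equal-level neighbor — per-interval smoothing is range-sensitive, so any
other situation recomputes from the raw input (per maximal interval, in
ascending level order). Under that precondition the incremental and
from-scratch paths are bit-identical for the smoothing back end (pass
composition). For Douglas–Peucker, the incremental branch re-runs the
algorithm on the cached kept vertices at the larger tolerance: that
preserves the subset-of-original-vertices and tolerance guarantees, but is
not generally bit-identical to a from-scratch run, which is why the
bitwise cache-coherence test targets the smoothing back end and the
vertex-preserving back end is audited through its subset/tolerance
guarantees instead.

**Automatic scheme.** Start with the whole trajectory as the complex set
C. Each iteration: evaluate the complexity of the current trajectory, mark
vertices with `c(x) < tau` simple and remove them from C (splitting its
intervals; fragments under 3 steps are dropped as unsimplifiable), raise
the level by one on every remaining complex interval, re-evaluate, and
stop when C is empty, the improvement `delta_c` falls below `eps`, or an
iteration cap (50) is reached (best-so-far returned with a warning flag in
the trace). Removed points are never re-added, so C shrinks monotonically.
Total complexity usually decreases, but endpoint pinning on many short
intervals can locally increase it; the `delta_c < eps` rule terminates the
loop in that case, and the per-iteration trace records both totals.

Smoothing can move vertices off the true path (through protein walls in
the worst case); the maximal deviation from the raw trajectory is reported
as a diagnostic, not bounded. The vertex-preserving back end exists
precisely to confirm observations made on the smoothed variant. Keeping
the simplified path inside computed void space is out of scope.

## Synthetic scenarios

The generator emulates the *statistical and geometric* structure the
analysis assumes — no force field, no energetics. A static shell of
3-atom pseudo-residues (default 200 residues, inner radius 5 Å, outer
13 Å, names cycling through the 20 amino acids so scale lookups are
exercised) has a cylindrical channel (radius 3 Å) cleared along +z, three
active-site residues ringed around the channel's buried end, and
alternating ±0.3 e charges on channel-lining residues. The ligand is a
single carbon-like atom whose path concatenates labeled phases:

- *outside*: random walk 10–18 Å beyond the surface (well past the
  outside-clearance threshold), drifting over the channel pole;
- *surface*: walk confined 3–4 Å above the outer radius, steered to the
  channel entrance over its final quarter;
- *transit*: swift insertion down the channel mouth, then a
  direction-persistent walk (step 0.7 Å, persistence 0.85) bouncing
  between the channel walls and `z` limits;
- *stuck* / *active-site*: Ornstein–Uhlenbeck oscillation (stationary std
  0.8 Å per coordinate, mean reversion 0.7) around a mid-channel point or
  the active-site centre, with a short settle glide so phases stay
  spatially continuous.

Global Gaussian jitter (σ = 0.15 Å) is added everywhere. The stuck
amplitude (0.8 Å) and transit step (0.7 Å) are deliberately similar so the
phases are *not* separable by speed alone — the stuckness window statistic
is what separates them. All randomness flows from one seeded PCG64
generator, so outputs (including files) are bitwise reproducible.

The default scenario (seed 42; 2,000 steps; phases 500 outside /
300 surface / 400 transit / 500 stuck / 300 active-site) yields ≈ 98 %
per-step agreement between the positional classification and the phase
labels; residual disagreement sits at phase boundaries (channel entry,
the glide into the active site), which are genuinely ambiguous.

What passing tests on these scenarios do *not* show: behavior on flexible
proteins (the shell is rigid; attributes are frame-local by design, with
no superposition), multi-atom ligand steric effects, realistic solvent, or
tunnels that bend. The generator validates the statistics and the
plumbing, not molecular realism.

## Problem sizes and numerical tolerances

The test suite and acceptance script run at desk scale: the 2,000-step
default scenario with a 600-atom shell, 100–400-step variants for
per-operation oracles, 100 random walks of 50 points for the decimation
audit, and 200 interval edits for cache coherence. Exhaustive brute-force
oracles (all atom pairs, all segment tuples, all pairwise displacements)
back every spatial attribute; analytic cases (collinear paths, the unit
right-angle elbow, 0/1 alternation) pin the complexity and stuckness
formulas to 1e-9 or better. Floating-point equality is asserted bitwise
where the design guarantees it (cache coherence, determinism) and at
1e-9–1e-12 where re-associations of the same arithmetic are involved.

## Known limitations

- One ligand per pass; analyze multiple ligands by running once per ligand.
- No pKa/protonation modelling; the donor/acceptor classes are a static
  residue-level table (D/E acceptors; K/R/W donors; S/T/Y/N/Q/H both).
- Tunnels are consumed (CAVER-style CSV), never computed.
- The smoothing back end's deviation from the raw path is unbounded;
  image rendering is best-effort and not pixel-tested — correctness lives
  in the CSV/JSON exports.
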