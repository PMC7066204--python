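# Methods

`sggrad` couples motile cell agents to a diffusing, degradable
chemoattractant field and uses that hybrid model to ask when chemotaxis is
robust: over what concentration range, population size, distance and time a
group of cells can steer, depending on whether the gradient is imposed
externally or self-generated by the cells' own attractant breakdown.

## The attractant field

The environment is a 2D lattice of attractant concentration c(x, y) (nM) on
a uniform square grid (spacing dx, default 4 um at library level, 5 um in
the assay builders).  Diffusion follows dc/dt = D * laplacian(c) and is
advanced with the DuFort-Frankel leapfrog scheme: explicit in form,
unconditionally stable, two time levels.  Boundaries are no-flux except
where noted.  Grid points may be pinned at their initial value; a pinned
strip acts as an infinite reservoir or sink, and an imposed gradient is the
profile that forms dynamically between a source strip and a sink strip
(deliberately so: the early, exponential-ish phase of gradient formation is
part of the stimulus cells experience, rather than assuming a linear ramp
from t = 0).

Two numerical points deserve record:

* **Parity balance.** The leapfrog stencil splits the space-time lattice
  into two interleaved classes that exchange no mass, and its checkerboard
  mode is *neutral* (amplification -1), so any class imbalance in the two
  starting levels persists forever as a checkerboard artefact.  A plain
  forward-Euler bootstrap leaves a point load ~50% imbalanced.  The
  bootstrap here therefore takes *both* starting levels after a
  forward-Euler substep whose diffusion number is exactly 1/8 — the value
  at which Euler's checkerboard amplification factor (1 - 8 nu) vanishes —
  which annihilates the imbalance; the free-space heat-kernel oracle then
  passes to better than 2% RMSE of peak from a single loaded node.
* **Exact mass ledger.** Sinks must treat both time levels identically:
  degradation decrements are applied to both levels and clamped to what
  both can absorb, and clamped undershoots of the update itself are
  corrected symmetrically.  With that, initial mass - final mass equals the
  degradation ledger exactly (tested at 1e-6 relative), which would not
  hold if either operation touched one level only (the leapfrog's level
  averaging re-creates about half of any one-sided removal).

Total mass is Sum(c) * dx^2 (nM um^2); a nominal unit depth is absorbed
into the cells' Vmax units.

## Cell agents

Cells are point agents with position, heading and constant speed (default
13 um/min, vegetative *Dictyostelium* scale).  A cell interacts with all
grid nodes within 6 um of its centroid (its "overlapped points").

**Sensing.** Receptor occupancy follows the single-site isotherm
y = c / (c + Kd) with Kd = 12 nM.  The cell's local gradient is the
least-squares plane fit of *occupancy* (not raw concentration) over the
overlapped nodes: saturable receptors perceive occupancy differences, which
is what makes both very dilute and saturating attractant illegible.
Degenerate node sets give a zero gradient.

**Steering.** Every reorientation interval (5 s) a persistence angle is
drawn from a wrapped normal centred on the current heading (sigma =
0.6 rad, sampled as a normal reduced mod 2pi — accurate for sigma well
below ~1.5 rad).  The unit persistence vector is added to a bias vector
along the normalized occupancy gradient with magnitude

    bias_strength * min(contrast / contrast_saturation, 1),

where contrast = |grad y| * (2 * overlap radius) is the occupancy
difference resolvable across the cell body; defaults bias_strength = 2.5,
contrast_saturation = 5e-3.  Contrasts below a detection threshold
(`contrast_threshold`, default 4e-4) contribute no bias.  The threshold is
a deterministic stand-in for receptor shot noise: a persistent walk
integrates arbitrarily faint biases into near-perfect chemotaxis over an
hour, so without a noise floor the model cannot reproduce the saturation
failure of imposed gradients at 100x Kd (the foot of any ramp would remain
legible forever).  The new heading is the angle of the summed vector; the
cell then moves at constant speed, reflecting off domain walls.

**Degradation.** Each cell removes attractant at the Michaelis-Menten rate
r = Vmax * c / (c + Km), with c the mean over its overlapped points, the
removed mass split evenly across those points and clamped at zero.  When
degradation is *induced*, Vmax is multiplied by the Hill factor
vb + (1 - vb) * y^h / (ki^h + y^h) of the trailing-minute average occupancy
(vb = 0.05, ki = 0.4, h = 2): enzyme activity is switch-like in how busy
the receptors have recently been.

**Running average and mitosis.** The trailing-minute occupancy average is
an exact sliding window (circular buffer of per-tick samples, initialized
at zero, so fresh cells warm up for one minute).  When the attractant is a
mitogen, the division *rate* interpolates linearly from 0 at average
occupancy 0.35 to 1/min at occupancy 1 — the unique one-parameter-free
choice making the expected waiting time exactly infinite at the floor and
exactly 1 min at saturation; division is then a Poisson event per tick.
Rate-linear interpolation (expected time (1 - floor)/(y - floor) min) was
chosen over time-linear interpolation because only a rate can be
meaningfully zero.  After division the daughter appears at the mother's
position with a random heading and both windows are zeroed, which is what
produces the brief refractory period.  A population cap (default 4000)
guards runaway growth in saturating attractant; growth otherwise
self-limits when the enlarged population pulls occupancy below the floor.

## The simulation loop

One agent tick (1 s): field sub-steps covering the tick; per cell — sense,
update the occupancy window, degrade, reorient (every 5th tick), move,
maybe divide; then record.  Cells are processed in stable id order as
arrays, and all randomness flows through one generator seeded from the
scenario, so identical scenario + seed reproduces trajectories
bit-identically (tested).  Division events are logged in the trajectory
table at their event time (mother row `division`, daughter row `birth`).

## Assays and calibration

The physical parameters the model needs but that no single measurement
fixes — D, dx, dt, speed, bias, Vmax, Km, population sizes — were
calibrated once so that the qualitative behaviors emerge at assay scale,
and then frozen:

* **Numerics** (assay builders): dx = 5 um, field dt = 0.1 s, agent tick
  1 s, D = 300 um^2/s (aqueous-scale small-molecule diffusivity in dilute
  agarose).  Accuracy at this setting is covered by the unit oracles.
* **Kinetics** (bridge/folate system): Vmax = 1.2e6 nM um^2/min per cell,
  Km = 500 nM.  Chosen so that the self-generated response score holds
  >= 50% of its maximum across 30 nM - 30 uM on the 1 mm bridge, and the
  population-collapse knee at 10 uM falls inside a 12-400 cell scan.
* **Bridge**: 1 mm channel, 50 um wide, 500 um reservoirs at both ends
  (finite attractant), 100 cells seeded in a 40 um band at the channel
  entrance.  Imposed mode uses a bare channel with pinned end strips.
  The response score is the fraction of starting cells displaced > 400 um
  along the axis within 1 h, displacement measured from each cell's own
  start.
* **Disc well**: default radius 250 um in a 1400 um arena — a scaled-down
  re-creation of the 1 mm-radius bench well, sized so a mitogen-versus-
  simple comparison runs in seconds.
* **Two-spot**: quarter-scale (125 um drops, 250 um centre-to-centre) with
  D scaled by the same linear factor (75 um^2/s), preserving the ratio of
  arena flooding time to cell crossing time; 200 cells; 1 h duration;
  scored at the end by splitting all cells at the drop-centre line
  perpendicular to the spot-spot axis (degrading cells leave the original
  footprint, so a footprint-only count would discard exactly the cells the
  assay is about).  The arena border is pinned at 0 nM: the bench drops sit
  on an agar field much larger than the assay region, and an open boundary
  reproduces the two features of that surround that matter — the local
  concentration first rises and then *falls* back through the sensitive
  range (which sets the no-degradation ceiling), and residual attractant
  drains rather than accumulating.  The two-spot cell model uses a sharper
  enzyme (Km = 100 nM) and a higher detection threshold (2e-3) than the
  bridge cells: the bench pairing is cyclic AMP with its phosphodiesterase,
  a different receptor and enzyme system from folate/deaminase, and the
  scaled drop needs a penetration depth sqrt(D * Km / (density * Vmax))
  small relative to the drop radius, as it is at full scale, for the
  drop interior to be shielded under constitutive degradation.

With these settings the three degradation logics reproduce the distinct
two-spot dynamic ranges: no degradation responds at 1-100 uM (saturation
kills 300 uM), always-on at 3-300 uM (the weak 1 uM signal is destroyed
before the drop interior sees it), and occupancy-induced degradation at
1-300 uM (enzymes stay basal until receptors have been busy, so the low
floor of the non-degrading system is kept together with the high ceiling of
the constitutive one).

## What the generator emulates — and what it does not

The synthetic scenarios emulate geometry, transport, saturable sensing,
enzyme kinetics and proliferation logic of under-agarose chemotaxis
assays.  They do not model: receptor-count stochasticity beyond the
deterministic detection threshold; cell shape, pseudopods or adhesion;
cell-cell volume exclusion (cells interact only through the shared field);
3D transport through the agar thickness; or attractant re-synthesis.
Passing tests therefore demonstrate the collective logic of self-generated
gradients in this model class, not quantitative agreement with any
particular cell line's measured parameters.

## Numerical choices and degenerate inputs

Problem sizes in the test suite (bridge 1 mm with <= 400 cells,
quarter-scale two-spot, 1-2.5 h simulated) are chosen so the full suite
runs on a laptop-class single core in tens of minutes.  Ties and edge
cases: a cell overlapping no node centre falls back to its nearest node;
exactly opposed persistence and bias vectors fall back to the persistence
draw; a cell stepping outside the domain is reflected and its normal
heading component inverted; `maybe_divide` truncates daughters at the
population cap; zero-duration runs echo the initial state.  The trajectory
CSV writer uses fixed 6-significant-digit formatting so identical runs
produce byte-identical files.

## Known limitations

* The DuFort-Frankel consistency error grows with (D dt / dx)^2; the assay
  builders keep the diffusion number near 1, adequate for fields that
  evolve over minutes but not for resolving sub-second transients.
* The two-spot floor/ceiling calibration is specific to the quarter-scale
  geometry; rescaling the drops without rescaling D (and revisiting the
  detection threshold) will shift the positive ranges by about one
  half-log ladder step.
* Division at high occupancy is fast (1 min) by design, following the
  model's abstraction of "growth exactly where needed"; real cell cycles
  are hours, so mitogenic rescue timescales are illustrative, not literal.
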