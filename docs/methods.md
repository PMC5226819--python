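# Methods

## Model and assumptions

`cawave` simulates networks of two-variable Ca²⁺ oscillators. Per cell the
state is (X, Y) = free cytosolic and free ER-luminal Ca²⁺. The cytosol gains
Ca²⁺ from a stimulus-driven plasma-membrane influx `J_INF`, from a constant
ER leak `β`, and from the InsP₃-receptor channel `J_EREFF`; it loses Ca²⁺
through a lumped linear extrusion `J_EFF` (plasma-membrane pumps, organelles,
buffering, never saturating in the physiological range) and through the SERCA
pump `J_SERCA` into the ER. The factor γ converts a transported flux into the
corresponding change of ER concentration (effective ER volume ≪ cytosolic
volume). The receptor flux uses *stationary* open probabilities — no
activation/inactivation kinetics, no allosteric coupling between the
cytosolic and luminal regulation, no electrochemical driving-force term — so
the whole single-cell model is a plane system, and sustained spiking is a
relaxation oscillation: slow ER loading between spikes, fast release during
one. Gap junctions exchange only cytosolic Ca²⁺, diffusively
(`d·Σ(X_u − X_v)`, conservative by construction); ER lumina are never
connected. Only existing links carry flux, so boundaries and holes are
no-flux by omission.

Units: concentrations in nM (`Y₀ = 260 000 nM` = 260 µM), time in s,
[InsP₃] in µM (matching `K_b = 1 µM`). All logarithms in the receptor terms
are base 10; the bell mean `M ∈ [2.18, 2.4]` and width σ are log₁₀-nM
quantities. The stimulus time courses evaluate to 0 exactly at `t = t1`
(below their pre-onset baselines of 0.015 µM and 0.1 nM/s) before rising;
this printed discontinuity is reproduced as such and the integrator restarts
at every distinct onset time.

## Parameters

All single-cell constants sit in `CellParams` (see
`examples/configs/defaults.yaml` for the full list with units). Two deserve
comment:

* **Bell width `sigma_bell = 0.3` (log₁₀-nM).** The width of the receptor
  bell controls whether the positive feedback window around `M` can reach the
  post-stimulus operating point `x* = (r_e2 + J_INF,max)/r_e1 ≈ 111–123 nM`.
  For σ ≲ 0.25 the feedback window never reaches `x*`: the cell fires one
  onset transient and settles on a stable fixed point for *every* stimulus in
  the physiological range, so no oscillatory regime exists at all. σ = 0.3
  is the smallest width (on a 0.05 grid) at which the documented regime
  structure emerges: sustained oscillation across the standard stimulus range
  (period ≈ 35 s at the reference stimulus, falling with both plateaus),
  saturation without repeated spiking at strong stimulation (influx plateau
  ≳ 6 nM/s, or [InsP₃] plateau ≳ 5 µM at ordinary influx), and short damped
  transients at the weak edge. It is therefore the package default.
* **Coupling `d`**: named levels low/moderate/high = 0.0015/0.0045/0.0075
  (1/s); the synchronization experiments also use 0.009.

Noise levels for the random sensitivity fields are named triples
(σ_iIP3max µM, σ_iJINFmax nM/s, σ_t1 s): low (0.2, 0.01, 4),
moderate (0.4, 0.025, 10), high (0.6, 0.04, 10).

## Heterogeneity generators

The generators produce per-cell stimulus triples `(t1, i_IP3,max,
i_JINF,max)`. The random variant draws i.i.d. normal noise for `i_IP3,max`
and *independent* normal draws for the other two, then reassigns the latter
by the rank of the former (t1 reversed). This makes the Spearman correlations
exactly +1 (`i_IP3,max` vs `i_JINF,max`) and −1 (vs `t1`) while keeping all
three marginals normal. Ties are broken by row-major node index. Draws below
1% of the parameter mean are remapped onto distinct positive values below
that floor in their original order — a plain clip would create rank ties; the
remap count is recorded in the field metadata. The central-zone variant
applies the same construction separately to the zone and the background; by
default the zone's mean onset is the minimal background onset, so the zone
always leads. For even grid dimensions the central block is biased toward
lower indices.

The generators emulate static cell-to-cell variability in agonist
sensitivity (receptor copy-number noise). They do not emulate temporal
stochasticity (channel noise), spatially correlated sensitivity, or
amplitude/measurement noise on the traces — so passing tests say nothing
about robustness to those.

## Graphs

Dense lattice: links between all node pairs at squared Euclidean distance
≤ 2 (edge count `n(m−1) + (n−1)m + 2(n−1)(m−1)`). Sparse variants build
per-node removal probabilities `p(v) = p·(max F − F(v))/(max F − min F)`
from one draw of a unit-variance Gaussian field with correlation
`exp(−‖x−y‖²/c₀)`, `c₀ = √(n²+m²)` (exact Cholesky sampling with 1e−10
jitter — exactness is affordable at these sizes). Because the source
quantity is a *node* probability, a link's removal probability is taken as
the symmetric mean of its endpoints (configurable: min/max/single-endpoint).
By the F → −F symmetry of the field the expected removed fraction under any
of these rules is exactly p/2. Holes remove nodes strictly below the
empirical q-quantile (linear interpolation convention) of the same field
draw.

## Numerics

The coupled system is integrated with adaptive RK45 at rtol 1e−6 / atol 1e−9
(nM scale), restarted at every distinct onset time, with dense sampling every
0.5 s. The spikes are fast (~5 s) but the Jacobian is mild; on the 25×25
network RK45 is ~6× faster than LSODA with indistinguishable trajectories
(LSODA remains selectable). State layout is block-wise `[X₁..X_N, Y₁..Y_N]`
in row-major node order. Before logarithms the state is floored at 1e−6 nM;
floor hits are counted and reported (zero in all standard runs). Halving the
tolerances moves `m_sync` by well under 0.02 (tested).

## Analysis conventions

* **Peaks**: local maxima with prominence ≥ 20% of the detection-window
  range (max − min) and ≥ 2 nM, separated by ≥ 5 s, with parabolic
  sub-sample refinement. The range-based bar keeps the detector on full-size
  spikes and ignores the few-nM bumps that diffusive coupling bleeds in from
  spiking neighbors.
* **Phase**: piecewise linear, 2π per inter-peak interval, defined only on
  `[τ₁, τ_last]` (never extrapolated). Phase differences are sampled on the
  trajectory's own output grid restricted to the overlap of the two cells'
  definition intervals.
* **Q and m_sync**: 10 equal bins on [0, 2π) by default (stable at the
  few-hundred-sample sizes of standard runs; configurable, reported in the
  SyncReport); `m_sync` is the unweighted mean over edges where both cells
  have ≥ 2 peaks; skipped edges are counted.
* **Analysis horizon**: the entropy index needs on the order of ten
  oscillation cycles per cell to be meaningful. The weak-influx
  synchronization experiments (`fig6a–c`, mean influx plateau 0.108 nM/s)
  therefore integrate to 3000 s — their periods are 100–600 s — matching the
  ~15 cycles a 600 s window provides at the default influx.
* **Regimes**: zone I if spiking persists into the final third of the run,
  zone II for transient spiking that dies earlier, zone III for at most one
  (onset) spike; an absolute 5 nM prominence floor keeps plateau ripple from
  counting. Zone borders are threshold-sensitive by nature; diagnostics
  (peak counts, baseline, final level) are reported with the label.
* **Wave speed**: per wave, Chebyshev distance from the grid center to the
  boundary (which all boundary cells share) divided by the median boundary
  upward-crossing delay; crossings at half-way between the 1st and 99th
  percentile of the post-transient windowed trace (the analysis skips the
  first quarter of the run so the large onset transient never sets the
  level). Mean ± normal-theory 95% CI across waves.

## Design choices and limitations

* The reference wave-initiation configuration gives the sensitive center a
  *later* onset (t1 = 72 s vs 60 s), violating the usual rank pairing; it is
  reproduced as specified, and "earliest post-onset spike" is assessed after
  the latest onset time, once every cell is stimulated.
* At the standard coupling strengths a neighbor's ~5 s spike transfers only a
  few percent of its amplitude, so coupling biases spike timing but does not
  hard-lock heterogeneous neighbors: the model yields moderate `m_sync`
  gains with `d`, wave patterns whose center-to-boundary lag breathes rather
  than locking (making the measured radial speed only weakly d-dependent),
  and entrainment of non-oscillating cells only when they are
  InsP₃-responsive but influx-starved (hovering near threshold, integrating
  neighbor kicks). Fully locked waves appear only at couplings an order of
  magnitude above the named levels.
* Out of scope: InsP₃ diffusion through gap junctions, explicit Ca²⁺ buffer
  species, saturating (Hill) pump variants, receptor gating kinetics,
  mitochondria, time-varying or weighted graphs, and any quantitative scoring
  of spiral-core dynamics (the pattern presets are provided for qualitative
  inspection).
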