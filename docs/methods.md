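# Model and methods

`calyxsim` models action-potential-evoked transmitter release at a single
presynaptic active zone (AZ) of the calyx-of-Held type: a sub-square-micron
membrane patch carrying docked synaptic vesicles and voltage-gated Ca²⁺
channels inside a reflective 600 × 600 × 1200 nm cytosolic compartment.  Every
Ca²⁺ ion that enters through a channel is tracked individually through
buffered diffusion until it is (possibly) captured by the five-site fusion
sensor of a docked vesicle.  The question the model addresses is geometric:
which spatial arrangements of channels relative to vesicles reproduce the
functional signatures of "domain overlap" release control — a high Ca²⁺
current–release cooperativity (log–log slope ≈ 3 of release vs Ca²⁺ influx),
a per-vesicle release probability p_ves ≈ 0.1 per AP, and sensitivity of
release to millimolar EGTA.

## Geometry

* **Active-zone maps.** A map is a simple planar polygon (the AZ outline)
  plus docked-vesicle centres, in nm, origin at the polygon centroid.
  Vesicles are 45 nm spheres; "docked" vesicles sit with a 5 nm cleft between
  sphere and membrane (the EM docking criterion is a membrane distance of
  ≤ 10 nm; we take the class midpoint).  The sphere is reflective for Ca²⁺
  and, by default, for mobile buffers.
* **Synthetic maps.** The reconstruction coordinates behind the published
  maps are not available, so the generator emulates their statistics:
  blob-like outlines from a radially perturbed ellipse (low-order Fourier
  modes, one irregularity knob, 64 vertices, exact area scaling), and
  vesicle centres placed uniformly with a 45 nm hard core.  Population draws
  use zero-truncated normals with the published moments (area
  0.07 ± 0.03 μm², density 110 ± 40 /μm²); vesicle count = round(area ×
  density) reproduces the count–area correlation (r ≈ 0.7).  Two fixed
  reference maps stand in for the two example AZs: 0.05 μm² with 6 vesicles,
  and 25/280 μm² with 11 vesicles.  The large map's generator seed is chosen
  (deterministically) so that its bottom half contains a void wide enough
  for a 25-channel supercluster 30 nm clear of every vesicle, matching the
  geometry described for the real example.  Synthetic maps reproduce the
  size, density and near-randomness of the EM sample but not any
  biologically structured features the sample might hide (e.g. subtle
  boundary–vesicle correlations); passing tests therefore validate the
  method on EM-like geometry, not any particular biological AZ.
* **Channel placement rules.** `random`: uniform over the polygon minus the
  vesicle footprints (a channel cannot sit under a docked vesicle);
  `exclusion_zone`: uniform over the polygon minus discs of radius
  (22.5 + d_ex) nm around each vesicle centre, i.e. ≥ d_ex from every vesicle
  *edge* (reference d_ex = 30 nm); `supercluster`: all channels on one
  hexagonal patch (pitch 14 nm) placed in a void space, by default in the
  bottom half of the map, with ≥ 30 nm edge clearance, and position-tuned so
  the standard-AP mean p_ves is near 0.1.  Channel count = round(area ×
  280 /μm²), minimum 1.

## Biophysics

* **AP waveform.** V(t) = rest + amplitude · f((t − t₀)/s), with
  f(u) = (1 − e^(−u/τ_r)) e^(−u/τ_d), τ_r = 0.1 ms and τ_d solved once so the
  half-width is exactly 0.49 ms; rest −80 mV, peak +40 mV.  The width scale s
  stretches the whole depolarised phase; 9 width scales, geometric over
  [0.45, 2.0] and snapped to include 1.0, drive the cooperativity protocol —
  a range chosen so the narrowest AP roughly halves the peak open
  probability, spanning the dynamic range of the published current families.
* **Gating.** Two-state Markov channel, α(V) = α₀e^(V/40 mV) (shallow,
  near-saturating opening) and β(V) = β₀e^(−V/10 mV) (steep closing).  The
  two amplitudes are calibrated by bisection against two anchors: peak open
  probability 0.60 under the standard AP (published), and steady-state open
  probability 0.90 at 0 mV (from published P/Q-type activation curves,
  V½ ≈ −15…−20 mV).  Calibrated defaults: α₀ = 1.2398 /ms, β₀ = 0.1378 /ms;
  activation τ at 0 mV ≈ 0.7 ms.
* **Single-channel current.** GHK flux form with apparent reversal +45 mV,
  anchored at 0.12 pA at 0 mV; an ohmic mode exists for sensitivity checks.
  Ion entry while open is an inhomogeneous Poisson process of rate
  |i(V(t))|/2e (~375 ions/ms per open channel at 0 mV).
* **Buffers.** ATP (free fraction 260 μM, k_on 5×10⁸ /M/s, K_d 200 μM,
  D 220 μm²/s), parvalbumin (100 μM, effective k_on 10⁷ /M/s, K_d 50 nM,
  D 43 μm²/s; Mg²⁺ competition folded into the effective rates), and an
  immobile endogenous buffer with equilibrium binding ratio κ ≈ 40 (4 mM,
  K_d 100 μM) and slow kinetics (k_on 3×10⁶ /M/s, k_off 0.3 /ms).  The
  global κ of the terminal constrains only the equilibrium ratio; the
  kinetics were identified against the reported operating characteristics of
  the model (10–20 μM transients at docked vesicles paired with p_ves ≈ 0.1,
  and half-suppression of release by 0.5 mM EGTA) — with fast fixed-buffer
  kinetics (k_on 10⁸ /M/s) the microdomain collapses and EGTA becomes
  ineffective, contradicting those reported characteristics.  EGTA, when
  added: k_on 1.05×10⁷ /M/s, K_d 70 nM, D 220 μm²/s.  D_Ca = 220 μm²/s.
* **Fusion sensor.** Five sequential Ca²⁺ binding sites per vesicle at the
  membrane-facing pole: forward (5−j)·k_on·[Ca], backward j·k_off·b^(j−1)
  with b = 0.25, fusion from the full state at γ = 6 /ms; k_off = 9.5 /ms.
  k_on = 2.054×10⁸ /M/s is calibrated once so a 15 μM, 0.5 ms free-Ca²⁺ step
  yields fusion probability 0.1, the reported pairing of local transient
  amplitude and release probability; the value sits inside the range of
  later uncaging studies (1.6–1.9×10⁸ /M/s).  Driven by amplitude-scaled
  AP-like transients the sensor's intrinsic log–log cooperativity is ≈ 3.3,
  just below the theoretical five-site ceiling ≈ 3.5 — no spatial channel
  arrangement can exceed it.

## Particle engine numerics

* **Time step.** Fine step Δt = 7×10⁻⁵ ms, chosen so the per-axis rms
  Brownian step (5.55 nm) is ≤ ¼ of the vesicle radius; the engine refuses
  coarser steps near obstacles, and refuses buffer reaction probabilities
  > 0.2 per step.
* **Free flights.** Away from obstacles the walk is event-driven: each free
  ion samples its next buffer-binding time exactly (exponential, total rate
  Σ k_on·[B_free]) and takes a single Gaussian step to that event or to a
  flight horizon keeping the rms 3-D displacement below half the clearance
  to the nearest vesicle surface.  Flat-wall reflection of a Gaussian
  increment is exact (method of images), so only the curved spheres
  constrain the step.  Flights never cross a pending snapshot or trace
  recording boundary.
* **Obstacles.** A proposed move ending inside a sphere is rejected
  outright (Metropolis): symmetric proposals plus rejection preserve the
  uniform equilibrium law exactly, which is what sets the sensor's drive;
  reflection/projection schemes tested instead biased the near-sphere
  density by 10–30 %.
* **Buffers as pseudo-first-order partners.** Soluble buffers are in
  > 10-fold excess over peak local Ca²⁺, so they are treated as a
  well-mixed pool: a binding ion is parked for an Exp(k_off) sojourn and
  re-emitted displaced by the Gaussian the buffer molecule would have
  diffused (immobile buffer: no displacement).  Free-buffer concentrations
  are tracked from the bound counts, and every species is conserved by
  construction.  This is exact in the well-mixed limit — no
  encounter-radius calibration — and is validated against the deterministic
  mass-action ODE (fusion probability agreement ≤ 5 %).
* **Sensor capture.** The sensor's capture pocket is the cytosolic shell
  hugging the sphere's bottom cap (within 20 nm of the membrane contact
  point, within 10 nm of the sphere surface).  An ion inside the pocket
  binds a free site at rate (5−j)·k_on·c_ion with c_ion the concentration
  one ion represents in the pocket volume, so the well-mixed mass-action
  limit is recovered exactly; the pocket is sized so capture stays
  reaction-limited (per-visit binding probability ≪ 1) — smaller pockets
  showed a measurable discrete-depletion undercount, for which an optional
  retry-time correction (`sensor_retry_time_ms`, calibrated against the
  well-mixed ODE) is provided.  Unbinding re-emits the ion uniformly in the
  pocket; fusion removes the sensor and sequesters its bound ions.
* **Trial window.** AP trials integrate to (last ion injection + 2 ms),
  capped at the 5 ms release window: after the free-Ca²⁺ transient has
  equilibrated into the buffers the residual fusion hazard is < 10⁻³ of
  peak.  Step-depolarisation trials stop exactly when every vesicle has
  fused, else at the stimulus end.
* **Determinism.** One integer seed drives gating, injections and the
  particle kernel through split SeedSequence streams; identical seeds give
  identical trials.

## Estimators

* **Cooperativity slope.** For each AP width: Q_Ca = mean injected ions ×
  2e, and mean p_ves over vesicles; OLS on (log Q, log p).  Points are
  excluded as *saturated* when p > 0.5·p_max **and** p > 0.2 (release far
  below 0.2 cannot be in the sensor's saturating regime; without the
  absolute floor the relative rule discards the valid top of curves that
  never saturate), and as *noise* when the binomial sd exceeds 50 % of the
  estimate; if fewer than 3 points survive the saturation threshold is
  relaxed just enough.  All exclusions are reported.  Trial counts per
  width follow a graded schedule (up to 4× the base count at the narrowest
  widths, where release is rare and trials are cheap) so the steep
  low-release points stay above the noise floor at desk-scale counts —
  the original protocol used 2000–4000 trials per width for the same
  reason.  The slope is averaged over independent spatial seeds
  (re-drawn channel placements).
* **Release statistics.** p_ves per site with Wilson intervals, mean, c.v.,
  failure fraction (trials releasing nothing), released-count histogram,
  release-rate histogram (50 μs bins).
* **EGTA dose–response.** Release relative to the zero-EGTA control across
  concentrations; monotone non-increasing.
* **Depolarisation kinetics.** Step −70 → 0 mV (10 ms); channels gate at
  fixed-voltage rates; the mean aggregate cumulative release is fitted with
  A(1 − e^(−t/τ)) from release onset (2 % of the final plateau) — the
  activation/diffusion latency, which the exponential form cannot
  represent, is reported separately as the per-vesicle delay statistic.  A
  double exponential is fitted for an AIC comparison — it should not be
  preferred.  Per-vesicle delay (10 % of
  cumulative release) and 20–80 % rise times are reported against the
  distance metric: supercluster-centre distance, or the mean distance to
  the three nearest channels.

## Problem sizes

Desk-scale runs use 220–250 base trials per AP width (graded up to 4× at
the narrowest widths), 150–350 trials for single-condition release and
depolarisation measurements, 1–3 spatial seeds, and 80-trial scoring
budgets for supercluster position tuning; the original study used
2000–4000 repetitions and 3–5 spatial seeds.  At these counts a fitted
slope carries a standard error of roughly 0.15–0.25, per-vesicle release
probabilities of order 0.1 carry ~15 % relative error, and a fitted release
time constant carries ~5–8 %.

## Known limitations

* Channels are static points; no lateral mobility, no multi-state or
  inactivating gating, no Ca²⁺-dependent modulation.
* All vesicles share one sensor; no replenishment, no lateral inhibition,
  no slowly-releasing subpopulation — accordingly the model produces only
  fast (~1 ms) release under prolonged depolarisation.
* Soluble-buffer depletion is neglected (validated to be a < 5 % effect in
  the well-mixed regime, but locally the approximation is untested at
  extreme influx).
* The identified fixed-buffer kinetics and sensor on-rate absorb whatever
  difference remains between this implementation's spatial discretisation
  and the original's; they are package-level constants, not measurements.
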