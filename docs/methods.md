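# Methods

This note documents the models, numerical choices, and defaults behind
`nefsim`, and what the test suite does and does not establish.

## Neuron model

The only neuron model is the leaky integrate-and-fire (LIF) neuron in
normalized units: threshold voltage 1, reset 0, input current measured in
threshold units (a constant `J = 1` holds the membrane exactly at
threshold). Defaults are `τ_RC = 20 ms` and `τ_ref = 2 ms`, typical of
regular-spiking cortical pyramidal cells.

- **Rate curve.** `a(J) = 1/(τ_ref + τ_RC ln(1 + 1/(J−1)))` for `J > 1`,
  zero at or below threshold. Continuous and strictly increasing above
  threshold with ceiling `1/τ_ref`.
- **Membrane update.** Exact exponential integration per step,
  `V ← J + (V − J) e^(−δ/τ_RC)`, where `δ` is the portion of the step
  outside the refractory window. When `V` crosses 1 the crossing time
  inside the step is interpolated and the refractory clock starts there
  (fractional-step refractory handling). This keeps measured spiking rates
  within a fraction of a percent of the analytic curve at `dt = 1 ms`;
  the test suite requires 2%.
- **Spikes as impulses.** A spike contributes `1/dt` on its step (unit
  area), so a lowpass-filtered spike train has firing-rate units and
  decoders are independent of the timestep.
- **Gain and bias.** Solved in closed form from each neuron's maximum rate
  and intercept: `J_max = 1/(1 − exp((τ_ref − 1/rate_max)/τ_RC))`,
  `gain = (1 − J_max)/(intercept − 1)`, `bias = 1 − gain·intercept`. This
  places the threshold exactly at the intercept and the requested rate
  exactly at the edge of the represented range. Requested rates at or
  above `1/τ_ref` are rejected.
- **Initial state.** All voltages and refractory clocks start at zero.
  Recurrent attractors still self-start because bias currents produce
  baseline firing regardless of the initial voltage.

## Tuning defaults and randomness

Unspecified ensemble attributes resolve at build time: encoders uniform on
the unit hypersphere, maximum rates uniform in [200, 400] Hz, intercepts
uniform in [−1, 1). These are conventional cortical-response choices; they
are deliberate defaults, not fits.

Every random draw is owned by an object-specific stream derived as
`SeedSequence([model_seed, insertion_index, stream])` (a per-object seed
replaces the first two entries). Consequences: builds are bit-reproducible
given a seed; two models that share object insertion order resolve
identical ensembles (used by the factored-vs-explicit-weights comparison);
and identity decoders for probing are solved once per ensemble on their
own sub-stream, so every probe of the same ensemble sees the same decode.

## Decoders

Decoders solve `min_D ‖AD − Y‖² + m(σ a_max)²‖D‖²` by the normal equations
with a direct symmetric (Cholesky-backed) solve — deterministic, no
iterative tolerance. Defaults: ridge fraction `σ = 0.1` of the maximum
activity; `max(500, 100·d)` evaluation points drawn uniformly from the
unit `d`-ball and scaled by the ensemble radius. Activities come from the
analytic rate curve, not spiking simulation, so decoders are deterministic
given a seed. A fully silent activity matrix (or silent neurons with
`σ = 0`) raises a build error naming the problem.

## Builder and scheduler

The builder compiles each ensemble into signals for its vector input, bias
and total input currents, membrane voltage, refractory clocks, and spikes,
plus constants for scaled encoders (`gain·encoder/radius`), decoders, and
transforms. Connections from ensembles decode into a per-connection signal
that is lowpass-filtered into a *state* signal; the target reads that
state.

Operators are ordered by a dependency toposort under the per-signal
discipline `set < inc < read < update`, with ties broken by operator tag,
so the executed schedule — and therefore the simulation, bit for bit — is
invariant to operator insertion order. State updates commit last: reads of
a filtered signal always see the previous step's value, which is what
makes recurrent connections well defined (the recurrence closes through
the synapse state). Two corollaries are documented behavior:

- An **unfiltered recurrent loop is a scheduling error** (a genuine
  same-step read/write cycle); the error lists the offending operators.
- Unfiltered **feedforward** paths are same-step: a node's output reaches
  its target's neurons within the step it is computed.

Node functions are called with the time at the *end* of the current step
(`t + dt`); probes sample signal values after all operators, so a probe
with a filter equals post-hoc filtering of the unfiltered probe to
round-off (tested at 1e-9).

All simulation state lives in the plan object, so independent plans run
concurrently without interference, and repeated `run` calls continue one
simulation exactly (two 0.5 s runs match one 1 s run bit for bit).

Default timestep `dt = 1 ms`; synaptic filter default 5 ms on
ensemble-sourced connections and none on node-sourced connections (nodes
are ideal signal sources; give them a filter explicitly when modeling a
synapse).

## Dynamics translation

With a first-order synapse `τ`, `ẋ = Ax + Bu` maps to recurrent transform
`τA + I` and input transform `τB`; nonlinear fields use
`g(x) = τ f(x) + x` decoded on the recurrent connection. The integrator
and oscillator networks apply this with the input path filtered by the
same `τ` as the recurrence, as the derivation assumes.

The Lorenz model uses the classic coefficients (σ=10, ρ=28, β=8/3) in
shifted coordinates `z' = z − ρ`, centering the attractor near the origin
so it fits a radius-60 ball; `τ = 0.1 s`, 2000 neurons. The chaotic
trajectory cannot track a reference ODE pointwise, so the tests compare
distributional statistics (boundedness, lobe switching, per-dimension
standard deviations within 50% of a long direct integration).

The oscillator amplitude is set by a 5.0-amplitude, 0.1 s input kick
(integrating to a state magnitude near 0.5); frequency is read from a
zero-padded periodogram peak, which resolves finer than the 1/duration bin
width of the raw FFT.

## Circular convolution

`dft_plan(n)` factors circular convolution over the real/imaginary parts
of the DFT spectrum using conjugate symmetry: real components (frequency
0, and n/2 for even n) contribute one scalar product, complex components
four, giving `2n − 2` products for even `n` (six for `n = 4`) and `2n − 1`
for odd. The factorization is exact to 1e-10 for all tested `n ≤ 16`
against direct summation.

In the neural network each product is a 2-D ensemble decoding `x₀·x₁`.
Operand components are scaled by `1/√2` on the way in (un-scaled in the
inverse transform) so unit-norm operands produce components in [−1, 1];
the product ensembles use radius `√2` because their 2-D input ranges over
the unit square, whose corners have norm `√2`. Defaults: 70 neurons per
product ensemble, no output normalization (callers may pre-normalize
operands).

The packaged `circconv_model` drives the network with constant seeded
unit-norm operand nodes and represents the output in a 200-neuron 4-D
Result ensemble; the full variant with operand ensembles is in
`examples/circular_convolution.py`.

## Stimulus generator

Band-limited Gaussian white noise is built in the frequency domain:
independent complex Gaussian coefficients for all components at or below
the cutoff (the DC coefficient is real), zero above, inverse-transformed
and rescaled to the target rms exactly. Defaults 0–5 Hz, rms 0.5. This is
an idealized stimulus — flat in-band spectrum, exactly zero out-of-band
power, stationary — and stands in for the slowly varying signals the
channel models route; passing tests show tracking of such signals, not of
arbitrary broadband input.

Tracking error for the channel is measured against the stimulus passed
through the same filter cascade as the neural path (one 5 ms stage per
synapse plus the probe filter), which removes the pure filter delay from
the comparison and leaves decode error and spike noise.

## What the synthetic conditions do not show

All inputs are generated (noise, seeded operand vectors, constant drives);
there is no empirical spike data. Results therefore demonstrate the
internal consistency of the method — decoders recover what encoders
represent, dynamics follow their design equations — under idealized,
homogeneous LIF populations. Heterogeneous neuron models, conduction
delays, learning, and biologically measured tuning distributions are out
of scope.

## Problem sizes

Test and acceptance runs use the example models at their stated sizes
(2000-neuron Lorenz for 6 s; 50- and 500-neuron channels for 1 s;
300-neuron oscillators for 6 s; five seeded 0.2 s convolution runs), which
are the sizes the behavioral claims refer to; smaller variants appear only
in structural tests where behavior is not measured.

## Known limitations

- Only LIF neurons; the operator layer is extensible but no other model is
  shipped.
- No learning rules; connection weights are static after build.
- Probes record to memory (CSV export is explicit, after the run).
- The scheduler rejects unfiltered recurrences rather than inserting an
  implicit delay.
- `validate` checks structural invariants; it cannot check that a node
  function returns the declared width until the simulation calls it (that
  raises at run time with the step index and node name).
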