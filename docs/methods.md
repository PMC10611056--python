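# Methods

This note documents the algorithms, the numerical choices, and the limits
of what the tests establish. It is the design record of the package; the
README covers usage.

## Sifting and EMD

One sifting iteration maps a working signal `x'` through a fixed stage
pipeline:

1. **Extrema detection** — interior strict local maxima/minima by neighbour
   comparison. Runs of equal samples (plateaus) count once, at the run's
   first index; record endpoints never qualify. This is one of several
   defensible plateau conventions; it is deterministic and matches common
   practice.
2. **Boundary extension** — see below.
3. **Envelopes** — a natural cubic spline through the (extended) maxima and
   another through the minima. Natural boundary conditions (zero second
   derivative at the end knots) give a strictly diagonally dominant
   tridiagonal system for the knot second derivatives, solved with the
   Thomas algorithm without pivoting; a vanishing pivot (impossible under
   dominance, possible for hand-built systems) raises with the row index.
4. **Midline subtraction** — `x' ← x' − (upper + lower)/2`.

`sift` runs S iterations of this pipeline (S = 10 by default) and returns
the final working copy as the candidate IMF. A fixed iteration count is the
default because it is exactly reproducible and is what the validation
figures assume; a Cauchy-style stop (relative change of the candidate below
a threshold, default 0.2, capped at S iterations) is available via
`SiftConfig(stop_mode="threshold")` but off by default.

If at any point the working signal has fewer than 2 maxima or 2 minima,
envelopes are undefined; the signal is declared *monotonic* and returned
as-is. EMD's outer loop uses the same test on the running residue as its
stop criterion ("no more oscillation"), capping at K modes. Each extracted
mode is subtracted from the residue, so the decomposition telescopes and
completeness (`Σ modes + residue = input`) is exact to rounding for every
input — this is a structural invariant, not a tuned one.

The local-mean operator is defined as `M(x) = x − sift(x)`: the identity
`M(x) == x − sift(x)` is bitwise by construction, and `M(·)` of a residue
is "everything below the first mode", which is how the ensemble recursion
consumes it.

### Boundary handling

Spline envelopes distort near the record ends, where extrema exist on one
side only. The default policy extends the two extrema nearest each end
symmetrically: reflection happens about the outermost extremum (which
preserves the local inter-extrema spacing), except when the record endpoint
lies outside the envelope implied by that reflection (e.g. the signal keeps
rising past its last interior maximum) — then the endpoint itself is
adopted as an extremum and reflection pivots on it; if a pivot fails to
cover the record, reflection falls back to the endpoint. This is the rule
of the widely circulated reference EMD implementations. A naive variant
that always reflects about the endpoint is available as
`boundary_policy="mirror-endpoint"`; it is measurably worse on the
dual-tone benchmark (first-mode artifacts near the ends cost ≈ 0.9
percentage points of similarity), which is why it is not the default.

## Ensemble algorithms

**EEMD** decomposes `x + ε₀ w^(i)` independently for each of I realizations
and averages mode j across the ensemble, zero-padding realizations that
produced fewer modes. EEMD is not intrinsically invertible; the *reported*
residue is defined as `x − Σ(averaged modes)`, which restores completeness
of the reported object while leaving the averaged modes untouched.

**ICEEMDAN** precomputes the noise-mode tensor `E_k(w^(i))` (K × I × N) by
running plain EMD on each seeded white-noise realization, then recurses on
the residue: perturb with `β_{k−1} E_k(w^(i))`, take the local mean of each
realization, average, difference. Modes are differences of consecutive
residues, so completeness is again exact by construction, for every
configuration including single precision.

Noise amplitude: `β_k = ε₀ · std(r_k)` with the population standard
deviation. For the first level an alternative rule divides each
realization's β₀ by the standard deviation of its own first noise mode
(`beta_rule="normalized-first-mode"`), equalising the realized
signal-to-noise ratio; the plain rule is the default. When β = 0 at some
level (zero noise strength, or a zero residue) every realization is
identical and the level is computed as a single local-mean application —
making the zero-noise run bitwise identical to the sequential
iterated-local-mean procedure, which the tests exploit as an oracle.

Batch semantics: `batch_local_mean` over an I × N realization matrix is
*defined* as observationally identical to the per-row loop, and is
implemented as that loop; the data layout (I × N realizations, K × I × N
noise tensor, K × N output) mirrors the data-parallel formulation so a
vectorized or parallel backend could be substituted without changing any
contract.

### Randomness and determinism

One master seed governs a run. Realization i draws from a dedicated
generator keyed on `(seed, i)` (numpy `default_rng([seed, i])`), so row i
of the noise matrix is the same no matter the ensemble size, batch order,
or how many realizations are requested — and identical (input, config,
seed) runs are bitwise identical at double precision.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| I (`n_realizations`) | 500 | ensemble size; hundreds are typical, standard-error of the ensemble average shrinks as 1/√I |
| K (`max_modes`) | 12 | mode cap; ~log₂(N) modes appear naturally for broadband signals |
| S (`n_iterations`) | 10 | fixed sifting iterations per mode |
| ε₀ (`noise_strength`) | 0.2 | noise scale relative to the residue standard deviation (dimensionless) |
| `beta_rule` | "plain" | β₀ = ε₀·std(x); alternative normalizes by std(E₁(w^(i))) |
| `precision` | "double" | "single" stores every stage output as float32, emulating an FP32 pipeline |

The dual-tone benchmark uses normalized frequencies 0.255 and 0.065
cycles/sample; the nominal 1 kHz sampling rate makes these the printed
255 Hz and 65 Hz. The fast component is exactly zero outside its 250-sample
active window (0-based samples 500–749), and both components start their
windows at phase zero.

## Synthetic data

`make_dual_tone` is the mode-mixing benchmark described above — a stated
construction with no free parameters. `make_synthetic_eeg` emulates
resting-EEG structure only loosely: per-band amplitude-modulated sinusoids
(delta 2, theta 6, alpha 10, beta 20 Hz centres, random phase, gentle
0.3 Hz amplitude modulation) over a 1/f (pink) noise floor, channels
independent. It deliberately omits nonstationary band power, artifacts
(blinks, line noise), and cross-channel covariance; green tests on it
establish that the pipeline plumbing handles multichannel band-structured
data, not that the decomposition is validated on real EEG.

## Numerical choices

- Extrema positions are integers; spline knots are stored as floats because
  boundary-mirrored knots can sit at negative or beyond-end positions.
- Spline evaluation outside the knot span continues the end segment's cubic
  ("extrapolate"); with the default boundary extension the knot span always
  covers the record, so extrapolation is never exercised by the envelope
  path. A "clamp" policy (hold end-knot values) exists for direct use.
- The similarity index takes the absolute value of the normalized
  covariance: mode polarity is sign-ambiguous, and the reported range is
  then [0, 1]. The signed value is available (`signed=True`). Constant
  inputs have undefined similarity and raise.
- Similarity on the benchmark is computed over the full 1000-sample record
  (not just the fast component's active window); this is the stricter
  choice since it penalizes leakage outside the window.
- Reconstruction error is relative max-abs; an identically zero input falls
  back to absolute error.
- Single-precision mode stores each stage output as float32; intermediate
  arithmetic may run at higher precision (as on hardware with FP32 storage
  and fused ops). The 1e−9 completeness guarantee applies to double
  precision; float32 runs reconstruct to ~1e−5 relative.

## Known limitations

- No Hilbert spectral analysis / instantaneous frequency extraction; the
  summary's per-mode frequency is a zero-padded FFT peak.
- EDF support is read-only and covers the common case (continuous 16-bit
  EDF); EDF+ annotations and discontinuous records are not parsed.
- The ensemble loop is sequential Python over realizations; the design
  keeps the batch contract explicit so a vectorized backend could be added,
  but no parallel execution is attempted.
- The inner stop criterion of the original IMF definition (extrema/zero
  crossing parity plus small local mean) is measured (`imf_validity`) but
  not used as a stopping rule; fixed-count sifting is the default
  throughout.
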