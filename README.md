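# iceemdan

Empirical mode decomposition for EEG and other nonstationary time series:
plain **EMD**, the noise-assisted **EEMD**, and the **Improved CEEMDAN**
(ICEEMDAN) recursion, implemented from the sifting primitives up
(extrema detection, Thomas-algorithm tridiagonal solves, natural cubic-spline
envelopes) with batch ensemble semantics, validation metrics, synthetic
fixtures, and a command-line interface.

## The problem

EEG rhythms (delta through beta band) are nonstationary and nonlinear, so
fixed-basis transforms blur them. EMD adaptively peels a signal `x` into
intrinsic mode functions (IMFs) — narrow-band oscillations obtained by
subtracting the midline of the upper/lower cubic-spline envelopes until the
candidate oscillates symmetrically ("sifting"). Plain EMD suffers from *mode
mixing* on intermittent signals. ICEEMDAN fixes this by perturbing the
running residue with the k-th EMD mode `E_k(w^(i))` of white Gaussian noise
realizations `w^(i)`, and averaging the local means across the ensemble:

    r_1 = ⟨ M(x + β₀ E₁(w^(i))) ⟩,      d_1 = x − r_1
    r_k = ⟨ M(r_{k−1} + β_{k−1} E_k(w^(i))) ⟩,  d_k = r_{k−1} − r_k   (k ≥ 2)

with `M(·)` the envelope-midline (local mean) operator, `⟨·⟩` the average
over the I realizations, and noise amplitude `β_k = ε₀ · std(r_k)`. The
construction telescopes, so `Σ d_k + r_K` reproduces `x` exactly — the
decomposition is invertible by design, unlike EEMD.

Recovered modes are scored against reference components with the similarity
index `ρ = |cov(x, y)| / √(var(x) var(y)) ∈ [0, 1]`.

## Worked example

```python
from iceemdan import ICEEMDAN, make_dual_tone

fx = make_dual_tone()          # 1000 samples: intermittent 255 Hz + continuous 65 Hz
res = ICEEMDAN(fx.composite, n_realizations=100, seed=1).fit()
print(res.summary())
rep = res.match([fx.component_s1, fx.component_s2])
print([round(p.rho, 4) for p in rep.pairs])
```

prints (numbers from an actual run):

```
ICEEMDAN decomposition results
  N = 1000 samples, 8 modes, fs = 1000 Hz
  reconstruction error = 2.220e-16 (relative max abs)

  mode  energy %  extrema zero-cross      freq Hz
     1     19.91      380        325      254.883
     2     78.45      130        129       64.941
     3      0.04       91         90       39.795
  ...
   res      0.00        -          2            -
[0.9965, 0.9988]
```

Mode 1 carries the intermittent fast tone (peak 254.9 Hz, similarity 0.9965
to the true component), mode 2 the continuous slow tone (64.9 Hz, 0.9988);
the remaining modes hold the residual ensemble noise at < 0.1 % of the
signal energy each, and the modes-plus-residue sum reconstructs the input
to machine precision.

The same pipeline is scriptable from a shell:

```sh
iceemdan simulate --fixture dual-tone -o dual.csv
iceemdan decompose dual.csv --algorithm iceemdan -I 500 -S 10 -e 0.2 --seed 1 -o out/
iceemdan validate -I 500 --seed 1        # similarity report as JSON
```

`decompose` accepts delimited text (samples × channels), raw binary float
matrices with a JSON sidecar, and EDF recordings; it writes a K×N mode
matrix and residue per channel plus a `manifest.json` that reproduces the
run bit-for-bit. `--profile` adds a per-stage wall-clock breakdown of the
sifting pipeline (extrema, tridiagonal solve, spline coefficients,
interpolation, envelope mean, residue update).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the dual-tone benchmark, runs ICEEMDAN from scratch
(I = 500, S = 10, ε₀ = 0.2, the given seed), and writes the similarity
index (%) of each recovered component and the dominant frequency (Hz) of
each matched mode (zero-padded FFT, 1 kHz nominal rate). It takes about a
minute on one CPU core.
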