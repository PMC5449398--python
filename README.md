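# havok — chaos as an intermittently forced linear system

`havok` decomposes a chaotic time series from a **single scalar
measurement** into a linear dynamical system punctuated by intermittent
forcing, and uses that forcing signal to predict rare events such as
attractor lobe switching. It implements the Hankel Alternative View of
Koopman (HAVOK) analysis: delay embedding plus Koopman-style regression.

It is aimed at people analyzing nonlinear time series — from canonical
chaotic systems to physiological or epidemiological records — who want an
interpretable linear model with a measurable "nonlinearity signal"
rather than a black-box forecaster.

## The method

Given samples x(t₁), …, x(t_m) at spacing Δt, stack q-long sliding
windows into a Hankel matrix and factor it:

```
H = [ x(t₁) x(t₂) … x(t_p) ]
    [ x(t₂) x(t₃) … x(t_{p+1}) ]       H = U Σ V*
    [  ⋮      ⋮   ⋱    ⋮     ]
    [ x(t_q) …     … x(t_m)  ]
```

The columns of V are *eigen-time-delay coordinates* v₁(t), v₂(t), …,
ordered by energy. Truncating at rank r, the first r−1 coordinates obey a
linear model almost exactly, while the last, lowest-energy coordinate is
not linearly modelable; it is instead treated as an exogenous forcing:

```
d/dt v(t) = A v(t) + B v_r(t),    v = (v₁, …, v_{r−1})
```

A and B are found by least squares (optionally sequentially thresholded
for sparsity) of 4th-order finite-difference derivatives on the
coordinates. For chaotic attractors the fitted A is dominantly
skew-symmetric with eigenvalues near the imaginary axis: quiescent
stretches are genuinely linear oscillations, and all of the
nonlinearity is concentrated in v_r, which stays near zero while the
trajectory circles one attractor lobe and bursts shortly **before** the
trajectory switches lobes. Thresholding |v_r| therefore yields an early
warning signal for switching, and the induced active/quiescent partition
of phase space can be cross-validated against the almost-invariant sets
of an Ulam-discretized Perron–Frobenius (transfer) operator.

## Worked example

Predict Lorenz lobe switching from the forcing signature (train 100 time
units, evaluate on 200 held-out time units):

```
$ python examples/03_predict_lobe_switching.py
test stretch: 200 time units
switching events       : 115
detected in advance    : 115 (100.00%)
quiet orbits           : 417
false alarms           : 45 (10.79%)
median warning lead    : 1.46 time units (reporting delay is only 0.1)
```

Every switching event was preceded by above-threshold forcing activity
(|v₁₁| > 0.002), about 1.5 time units — roughly two lobe orbits — before
the switch, while ~11% of quiet orbits raised a spurious alarm at this
reduced training size (the full-scale experiment below reaches ~2–3%).
The fitted model itself is almost perfectly skew-symmetric with
near-integer structure:

```
$ python examples/02_forced_linear_model.py
per-equation R^2: [1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 0.99982 0.99982]
A (upper-left 5x5 block):
[[ -0.    -4.98  -0.     0.11  -0.  ]
 [  4.98  -0.   -10.02   0.    -0.19]
 [ -0.    10.03   0.    13.42   0.  ]
 [ -0.12  -0.   -13.43   0.    19.31]
 [  0.01   0.19   0.01 -19.31   0.  ]]
skew ratio ||sym(A)||/||A||      : 0.0001  (0 = perfectly skew)
max real part of eigenvalues     : 0.0009  (<= 0 means stable)
```

The other example scripts cover delay-mode structure
(`01_embed_lorenz.py`), transfer-operator cross-validation
(`04_almost_invariant_sets.py`), forcing-tail statistics
(`05_forcing_statistics.py`) and out-of-sample reconstruction with
measured forcing (`06_out_of_sample_reconstruction.py`).

A thin CLI mirrors the pipeline stages:

```
havok simulate --system lorenz --dt 0.001 --duration 200 --out lorenz.csv
havok embed    --in lorenz.csv --q 100 --r 15 --out emb/
havok fit      --emb emb/ --out model.json
havok predict  --emb emb/ --in test.csv --threshold 0.002 --out report.json
havok run      --seed 1 --out results/
```

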