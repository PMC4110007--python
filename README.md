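# submovekit

Tools for characterizing and predicting the submovement structure of
human 3D arm reaches, for motor-control researchers and developers of
arm neuroprostheses who need a trajectory generator with realistic
mid-flight error corrections.

## The model

A target-directed reach is represented as the sum of N overlapping
**minimum-jerk submovements**. Each submovement j contributes, per
Cartesian dimension d, the bell-shaped velocity pulse

```
v_jd(t) = (A_jd / D_j) · 30 τ² (1 − τ)²,    τ = (t − t0_j) / D_j ∈ [0, 1]
```

with initiation time `t0_j`, duration `D_j ≥ 0.1 s` and amplitude vector
`A_j` (the net displacement, cm). Given a recorded fingertip velocity,
the 5N parameters are fitted by penalized least squares

```
J(N) = Σ_d ∫ (v_rec,d − v_meas,d)² dt + λ Σ_d ∫ (Σ_j |v_jd| − |Σ_j v_jd|) dt
```

(the second term suppresses simultaneous opposing submovements), and N
is chosen at the knee of the J(N) curve — the point furthest below the
diagonal of the min-max-normalized curve.

Three small feed-forward networks (tanh hidden layers of 5/10/10 units,
logistic outputs) then learn to predict, from strictly causal kinematic
features, when a corrective submovement begins, its 3D amplitude
(normalized by DTTAPS, the remaining distance to target implied by all
prior submovements) and its duration. Chained together they form a
closed-loop simulator: the first submovement fires at t = 0, corrections
are triggered from the simulated state every 10 ms, and a reach succeeds
after 1 s of dwell inside the 1.27 cm target sphere.

## Worked example

Decompose one noisy synthetic reach with known ground truth
(`examples/02_decompose_a_reach.py`):

```
$ python examples/02_decompose_a_reach.py
reach of 29.0 cm, velocity noise 0.5 cm/s RMS
cost per candidate N: [313.412  94.025   0.771   0.683   0.603   0.47    0.413   0.338]
knee selects N* = 3 (truth: 3)
reconstruction VAF: 99.92%
               t0 (s)    D (s)  |A| (cm)
        true    0.000    0.386     18.71
        true    0.333    0.281      4.35
        true    0.633    0.241      6.07
      fitted    0.000    0.386     18.75
      fitted    0.332    0.285      4.31
      fitted    0.632    0.244      6.13
```

The cost drops steeply until N reaches the true submovement count, then
flattens; the knee criterion picks the transition, and the fitted
(t0, D, |A|) rows match the generating submovements to within a few
hundredths. The other examples build the minimum-jerk basis
(`01_minimum_jerk_basis.py`), cross-validate the three parameter
predictors (`03_train_predictors.py`) and run the closed-loop simulator
against a corpus (`04_closed_loop_simulation.py`).

A thin CLI wraps the same stages:

```
submovekit synth -n 100 --seed 0 -o corpus.csv --truth truth.json
submovekit decompose corpus.csv -o subs.json --n-max 8 --seed 0
submovekit run-all -n 100 --seed 0 -o out/
```

Recorded datasets are long-format CSVs (columns `trial, t, px, py, pz,
tx, ty, tz`; positions in cm, occluded samples as NaN); the column
layout is configurable through the `schema` argument of `load_dataset`.

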