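# excitatory-perceptron

Theory and simulation of the **analog perceptron with excitatory
(non-negative) synaptic weights** — a model of supervised learning at
the granule-cell → Purkinje-cell synapse of the cerebellum, where
plasticity can change the strength but never the sign of a synapse, and
both inputs and outputs are analog firing rates rather than binary
labels.  It is aimed at computational neuroscientists who want the
replica-symmetric predictions (storage capacity, silent-synapse
fraction, weight distribution, above-capacity error, information-optimal
output statistics) side by side with finite-N learning experiments.

## Model

The perceptron output for pattern μ is linear,

    y^μ = Σ_i w_i x_i^μ − θ,      w_i ≥ 0,

where the x_i^μ ≥ 0 are input rates with moments (μ_x, σ_x), the targets
z^μ ≥ 0 have moments (μ_z, σ_z), and θ is an inhibitory term (molecular
layer interneurons) canceling the leading O(√N) mean excitatory drive.
Learning seeks w ≥ 0 with y^μ = z^μ for all p = αN associations.  In the
large-N limit everything depends on the statistics only through

    B = (μ_x σ_z / (σ_x μ_z))²,

and the maximal load (capacity) is

    α_c = Φ(κ),   with κ ≤ 0 solving  B·I1(κ) + κ = 0,
    I1(κ) = κΦ(κ) + φ(κ),

so α_c(0) = 1/2 — at most half the unconstrained capacity of 1.  At
capacity a fraction F = 1 − α_c of synapses is exactly silent and the
remaining weights follow a truncated Gaussian.  Above capacity the
minimal mean squared error is strictly positive and given by a closed
saddle-point expression (see `docs/methods.md`).  Because capacity alone
favors σ_z → 0, the package also computes the Gaussian-channel
information per synapse, α_c(B(σ_z)) · ½log₂(1 + σ_z²/σ_noise²), and the
output variability that maximizes it.

Finite-N experiments use the biological learning rule — the delta rule
with clipping at zero, Δw_i = η (z^μ − y^μ) x_i^μ followed by
w_i ← max(w_i, 0) — and an exact non-negative least-squares (NNLS)
oracle as ground truth.

## Worked example

`python examples/learning_vs_theory.py` prints

```
N = 500, alpha = 0.8, B = 1.0 (capacity alpha_c = 0.3913)
theory mean squared error      : 0.3975
NNLS oracle mean squared error : 0.3683
delta-rule mean squared error  : 0.3685  (6000 epochs)
silent fraction  theory 0.457 | oracle 0.436
```

At load α = 0.8, twice the capacity α_c(1) ≈ 0.391, the associations
cannot all be stored: the annealed delta rule lands on the same error
floor as the exact constrained optimum (0.3685 vs 0.3683), close to the
large-N prediction 0.3975, and over 40% of the synapses are silenced.
The other examples cover the capacity curve (`capacity_curve.py`), the
weight distribution at capacity (`weight_distribution.py`, silent
fraction 0.609 predicted vs 0.619 simulated at N = 800, KS distance
0.039 for the non-silent part) and the information-optimal output
variability (`information_optimum.py`).

A thin CLI mirrors the library:

```bash
excperc capacity --b-grid 0:5:0.1
excperc capacity-scan --b 0 --n 1000 --alpha 0.3:0.7:0.02 --trials 50 --seed 7
excperc figure --name fig1b --out figures_out --seed 0
```

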