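# cghawkes

Coarse-grained Hawkes processes: a count time-series framework for event
data that are only observed as aggregated bin counts.

## The problem

Self-exciting point processes (Hawkes processes) model event streams in
which each occurrence raises the rate of future occurrences — epidemic case
counts, neural spike trains, financial order flow, crime and aftershock
sequences. The d-variate Hawkes process has conditional intensity

    lambda(t) = mu + int_0^t Phi(t - u) dN(u),

with baseline rates `mu` and excitation kernels
`phi_ij(t) = alpha_ij g_ij(t)`: `alpha_ij` is the branching ratio (expected
number of type-i events triggered by one type-j event) and `g_ij` a
waiting-time density. In practice one rarely observes exact event times;
surveillance systems report counts per day or per week. Fitting a Hawkes
process to such bin counts with a naive discretization goes wrong as soon
as the bin width `dt` is comparable to the kernel timescale, because
excitation *within* a bin is ignored.

`cghawkes` implements the coarse-grained Hawkes process: the continuous
kernel is averaged over source and target bins into weights `{Phi_k}`
whose lag-0 term captures intra-bin excitation. The resulting count model
matches the second-order structure (autocovariances, spectra) of the true
binned Hawkes process to third order in `dt` — one order better than the
binned-Poisson discretization — and supports a fast quasi-likelihood
estimator: center the counts by their empirical mean, minimize

    L(theta) = sum_k r_k' diag(lam)^{-1} r_k - 2 n log|I - Phi_0(theta)|,
    r_k = Y_k - sum_{j>=0} Phi_j(theta) Y_{k-j},

by BFGS, and recover the baseline as `mu = (I - A) lam / dt`. Binned-Poisson
maximum likelihood and INAR(p) conditional least squares are included as
baselines, together with exact simulators (Ogata thinning and a branching
sampler), the full second-order theory, and spectral/information-loss
diagnostics.

Intended users: statisticians and quantitative epidemiologists fitting
self-exciting models to aggregated incidence-style count series, and anyone
needing reference implementations of binned-Hawkes second-order theory.

## Worked example

```python
import numpy as np
from cghawkes import (HawkesModel, KernelMatrixSpec, bin_events, coarse_grain,
                      fit_cg, simulate_thinning, stationary_mean)

# asymmetric bivariate Hawkes model with exponential kernels
model = HawkesModel(
    mu=[1.0, 1.0],
    kernel=KernelMatrixSpec.exponential(
        alpha=[[0.4, 0.5], [0.3, 0.2]],
        beta=[[0.5, 0.7], [0.3, 1.0]]))

ev = simulate_thinning(model, T=4000.0, seed=42)   # exact event times
x = bin_events(ev, dt=2.0)                         # 2000 bins of width 2

ck = coarse_grain(model.kernel, dt=2.0)            # coarse kernel {Phi_k}
print(np.round(ck.phi0, 3))                        # intra-bin weights
print(np.round(stationary_mean(model.mu, ck), 2))  # expected counts/bin

fit = fit_cg(x, family="exponential", seed=0)
print(np.round(np.asarray(fit.theta_hat["alpha"]), 3))
print(np.round(fit.mu_hat, 3))
```

Output:

```
[[0.147 0.231]
 [0.074 0.114]]
[7.88 5.45]
[[0.388 0.54 ]
 [0.31  0.201]]
[0.926 0.99 ]
```

The first matrix is `Phi_0`: at `dt = 2` a sizeable share of each branching
ratio's mass (for example 0.147 of alpha_11 = 0.4) already acts within the
source bin — exactly the part a naive discretization drops. The expected
counts per bin `(7.88, 5.45)` are `(I - A)^{-1} mu dt`. The fitted
branching ratios `(0.388, 0.540, 0.310, 0.201)` sit close to the truth
`(0.4, 0.5, 0.3, 0.2)` even though the bins are coarser than every kernel
timescale, and the recovered baselines are near `(1, 1)`. At the shorter
study horizon T = 1000 single-replicate estimates scatter more widely
(roughly +/-0.05 on branching ratios); medians across replicates center on
the truth.

## Command line

```
cghawkes simulate --config model.yaml --horizon 1000 --dt 2 --seed 7 --out counts.csv
cghawkes spectra  --config model.yaml --dt 1 --which cg,po,hw --out spectra.json
cghawkes fit      --counts counts.csv --dt 2 --method cg --seed 1 --out fit.json
cghawkes study    --config study.yaml --which recovery --out results/
```

`model.yaml` lists `mu` and 1-based kernel entries:

```yaml
mu: [1.0, 1.0]
kernel:
  d: 2
  entries:
    - {i: 1, j: 1, family: exponential, alpha: 0.4, beta: 0.5}
    - {i: 1, j: 2, family: exponential, alpha: 0.5, beta: 0.7}
    - {i: 2, j: 1, family: exponential, alpha: 0.3, beta: 0.3}
    - {i: 2, j: 2, family: exponential, alpha: 0.2, beta: 1.0}
```

Study configs add `dt` (list), `T`, `replicates`, `seed`, `methods`.

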