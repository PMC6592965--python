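# spectraldcm

Dynamic causal modelling of oscillatory (cross-spectral) neural data in
Python: biophysical forward models of coupled neuronal populations,
variational-Laplace inversion, Bayesian model reduction (BMR), parametric
empirical Bayes (PEB) for group studies, and laminar-probe analyses —
current-source-density depth profiling and superficial/deep layer
assignment by Bayesian model comparison.

It is written for electrophysiologists and computational neuroscientists
who want to explain LFP/MEG spectral features — a gamma peak, a 1/f slope,
a laminar asymmetry — in terms of synaptic rate constants and connection
gains rather than descriptive statistics.

## The model

A cortical source is modelled as four populations whose mean
depolarizations v_q follow second-order (synaptic convolution) dynamics

    v̈_q = κ_q f_q(v, U) − 2 κ_q v̇_q − κ_q² v_q

with postsynaptic rate constants κ_q, sigmoid firing rates σ(v) (centred so
σ(0) = 0), signed connection gains a_qp mixing presynaptic rates into
f_q, and exogenous input U.  Linearising at the fixed point gives a
transfer function T(ω) = C (iωI − J)⁻¹ B, and the predicted cross-spectral
density between channels l and m is

    g_lm(ω) = T_l(ω) g_u(ω) T_m(ω)† + g_n(ω)

with white-plus-pink input and channel-noise spectra g(ω) = α + β/ω.  The
neural-field variant replaces each point gain by a spatial connectivity
kernel α e^{−c|x|} conducted at finite speed s, summing modal contributions
over wavenumbers k under a Gaussian lead field exp(−φ²k²/2).

Inversion maximises the variational free energy F — a lower bound on the
log model evidence — over a Gaussian posterior q(θ) and a noise
log-precision λ, by Gauss–Newton ascent with Levenberg–Marquardt damping
(exact on linear-Gaussian problems).  BMR then yields the posterior and
evidence of any model that differs only in its priors, in closed form; PEB
stacks a between-subject linear model θ_i = (x_i ⊗ W)β + ε_i on top of the
subject posteriors and searches the space of group effects with the same
reduction machinery.  Evidence differences are read as log Bayes factors,
with |ln B| > 3 conventionally labelled strong.

## Worked example

Simulate a two-channel laminar recording whose superficial channel has fast
kinetics (gamma-band resonance) and deep channel slow kinetics, then ask
the model which channel is which, and recover two perturbed gains:

```python
import numpy as np
from spectraldcm import (simulate_laminar, laminar_template, CSDForwardModel,
                         layer_assignment_comparison, vl_invert,
                         simulate_subject, MassModelParams)

freqs = np.arange(4.0, 101.0, 2.0)
data, truth = simulate_laminar(freqs=freqs, noise_sd=0.5, seed=1)
model = CSDForwardModel(laminar_template(), ("kappa1", "kappa3", "a14", "a32"),
                        freqs, channel_names=("sup", "deep"))
res = layer_assignment_comparison(data, model)
print(f"assignment: {res.channel_to_layer}")
print(f"log-evidence difference: {res.delta_f:.1f} nats")

base = MassModelParams(Lw=((1.0, 0, 0, 0), (0, 0, 1.0, 0)))
true_offsets = {"a14": 0.30, "a32": -0.20}
data2, _ = simulate_subject(base.with_offsets(true_offsets), freqs,
                            noise_sd=0.5, seed=2)
fit = vl_invert(data2, CSDForwardModel(base, ("a14", "a32"), freqs))
for name, tv in true_offsets.items():
    i = fit.posterior.index_of(name)
    lo, hi = fit.credible_interval(name)
    print(f"{name}: true {tv:+.2f}, posterior {fit.posterior.mean[i]:+.3f} "
          f"[90% CI {lo:+.3f}, {hi:+.3f}]")
```

prints

```
assignment: {'sup': 'superficial', 'deep': 'deep'}
log-evidence difference: 730.3 nats
a14: true +0.30, posterior +0.301 [90% CI +0.290, +0.312]
a32: true -0.20, posterior -0.197 [90% CI -0.246, -0.147]
```

The 730-nat difference says the data overwhelmingly favour mapping the
gamma-peaked channel to the superficial populations (anything above 3 nats
is strong evidence); the gain offsets — log-scalings of the connection
gains — are recovered inside their 90% credible intervals.

Parameter estimation and group inference are also available as
scikit-learn-style estimators (`VariationalLaplace`, `PEB`) with `fit()`
and trailing-underscore attributes, and from the command line:

```sh
spectraldcm simulate laminar --seed 1 --out lam
spectraldcm fit --data lam/spectra.csv --out fit1
spectraldcm csd --lfp lfp.tsv --out csdout
```

Every CLI run saves its resolved configuration and a log, and is
reproducible from that config plus the seed.

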