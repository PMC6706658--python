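# ms2burst

Analysis machinery for transcriptional bursting measured by MS2/MCP live
imaging: closed-form statistics of the two-state (telegraph) promoter model,
an exact stochastic simulator with an MS2-style observation layer, the
trace-processing and burst-calling pipeline, an extrinsic-corrected Fano
factor with a Fano-ratio + autocorrelation diagnostic of kinetic-parameter
changes, and the dual-allele intrinsic/extrinsic decomposition of
transcription onset times.

## The problem

A gene's mean expression can rise in three ways under the telegraph model —
the promoter toggles OFF ↔ ON at rates *K*<sub>on</sub>, *K*<sub>off</sub>
and initiates polymerases at rate *r* while ON, each polymerase contributing
to the nascent-mRNA signal for the elongation time *T*:

&nbsp;&nbsp;&nbsp;&nbsp;⟨m⟩ = r·T·K<sub>on</sub>/κ,  κ = K<sub>on</sub> + K<sub>off</sub>

so a larger mean may come from larger *r*, larger *K*<sub>on</sub> or smaller
*K*<sub>off</sub>, and the mean alone cannot tell which. The fluctuations
can. The stationary Fano factor of the nascent count,

&nbsp;&nbsp;&nbsp;&nbsp;Fano = 1 + (2 r K<sub>off</sub>/κ²) · g(κT),  g(x) = 1 + (e<sup>−x</sup> − 1)/x,

responds with a fixed sign to *r* (up) and to *K*<sub>on</sub> (down, when
κT is not small), but with an indeterminate sign to *K*<sub>off</sub>. The
trace autocorrelation function breaks that degeneracy: slower switching
(smaller κ) makes the ACF decay more slowly, so a *K*<sub>off</sub> decrease
shifts it right while *r* and *K*<sub>on</sub> changes do not move it.
Comparing two conditions whose means differ by a factor α therefore reduces
to a decision table on the Fano-factor ratio (FFRatio) and the ACF:

| observation | inferred change |
|---|---|
| FFRatio > 1, no ACF shift | *r* increased |
| FFRatio < 1, no ACF shift | *K*<sub>on</sub> increased |
| rightward ACF shift (either FFRatio) | *K*<sub>off</sub> decreased |

When switching is fast relative to the frame interval the ACF carries no
switching information and a residual ambiguity with *K*<sub>off</sub>
remains.

On the data side, the empirical Fano factor corrects for extrinsic
(cell-to-cell) variability via the covariance of paired units — two reporter
alleles in the same nucleus, or neighbouring nuclei as a proxy:
Fano = (Var(m) − Cov(m))/⟨m⟩, pooled over the analysis window, with
uncertainties from bootstrap resampling of whole traces. The same
covariance logic decomposes onset-time variance across dual alleles into
intrinsic and extrinsic shares.

## Worked example

Double the mean of a slow-switching gene by lowering *K*<sub>off</sub>, then
ask the diagnostic which parameter moved:

```python
from ms2burst import (KineticParams, SimulationConfig, simulate_ensemble,
                      empirical_fano, autocorrelation, fano_ratio,
                      diagnose_parameter_change, solve_matched_mean)

base = KineticParams(r=0.2, k_on=0.01, k_off=0.03, T=120.0)
boosted = solve_matched_mean(base, "k_off", alpha=2.0)   # k_off 0.030 -> 0.010

summaries, acfs = [], []
for i, params in enumerate((base, boosted)):
    cfg = SimulationConfig(params=params, n_cells=200, seed=100 + i)
    ensemble = simulate_ensemble(cfg)
    summaries.append(empirical_fano(ensemble, window=(params.T, cfg.duration)))
    acfs.append(autocorrelation(ensemble, window=(params.T, cfg.duration)))

ffr = fano_ratio(summaries[0], summaries[1])
result = diagnose_parameter_change(ffr, acfs[0], acfs[1])
```

This prints, via the obvious format strings:

```
Fano factors: 6.63 and 6.87
FFRatio = 1.04 +/- 0.04
ACF decorrelation lag: 67 s -> 78 s (right shift)
verdict: {'koff_down'}
```

The Fano ratio is indistinguishable from 1 — exactly the degenerate
*K*<sub>off</sub> case — but the autocorrelation decays visibly later in the
boosted condition, and the decision table returns the correct verdict.

The same pipeline is scriptable from the shell: `ms2burst simulate`,
`analyze` (burst calling and per-region summaries), `diagnose` (two trace
tables → verdict), `decompose` (dual-allele variance decomposition) and
`validate` (the full regime × parameter self-validation table). Trace
tables are plain long-format CSV; configuration is YAML/JSON
(`ms2burst simulate --help` etc. for details).

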