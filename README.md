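# nmrlineshape

Two-dimensional NMR lineshape analysis of protein–ligand titrations.

When a ligand is titrated into a ^15N-labelled protein, chemical exchange
between free and bound states reshapes every resonance in the 2D
^1H,^15N correlation spectrum. The lineshapes encode the thermodynamics
(the bound population, hence the dissociation constant K_d), the kinetics
(the dissociation rate k_off, through the exchange rate
k_ex = k_on[L] + k_off relative to the shift difference Δω), and the
structure of the bound state (its chemical shifts and linewidths).
`nmrlineshape` extracts all of these by fitting the *entire* 2D spectra of
a titration series, rather than peak positions or 1D cross-sections.

The engine is a **virtual spectrometer**: for every titration point the
equilibrium state populations are solved from a binding model, a
first-order exchange rate matrix **K** is assembled, and magnetization is
propagated through the actual pulse sequence (HSQC, HMQC or SOFAST-HMQC —
INEPT transfers, t1 evolution of single- or multiple-quantum coherence,
zz-filter and gradient delays, acquisition) under the Bloch–McConnell
generators, e.g. for the acquisition dimension

    L = i·diag(Ω_H ± π·J_HNHA) − diag(R2I) + K .

The resulting interferogram is processed exactly like the experimental
data (exponential apodization, zero-fill, FT, phasing, extraction), so the
simulation can be compared with the observed spectra point by point inside
user-defined regions of interest (ROIs). A trust-region least-squares fit
minimizes the noise-weighted chi-square across all spectra simultaneously;
absolute amplitudes are fixed by concentration × scans × receiver gain, so
no per-peak normalization is needed. Uncertainties come from the Jacobian
covariance and from residual-resampling bootstrap.

Binding models include two-state binding (also with flexible
stoichiometry), induced fit, conformational selection, four-state
exchange, monomer–dimer association, and two binding sites with
thermodynamic-cycle closure (K_d,4 = K_d,1·K_d,3/K_d,2).

## Worked example

Simulate a 9-point titration (100 µM protein, K_d = 20 µM,
k_off = 100 s⁻¹, the usual 0 → 1.9 equivalents schedule with dilution
accounting), then refit it from perturbed starting values:

```python
import copy
from nmrlineshape import ModelParameters, TitrationLineshapeModel, uM
from nmrlineshape.examples import two_state_study
from nmrlineshape.synthesis import generate_synthetic_titration

truth, design, config, proc = two_state_study(snr=50.0, seed=7)
dataset = generate_synthetic_titration(truth, design, config, proc)

spins = copy.deepcopy(truth.spins)           # starting guesses
model = TitrationLineshapeModel(
    dataset, "two_state",
    ModelParameters({"K_d": 35 * uM, "k_off": 200.0}), spins)
model.fit(stage="free_state_only")           # stage 1: free-state shifts
results = model.fit(stage="global")          # stage 2: everything else
print(results.summary())
boot = results.bootstrap(n_replicas=50, seed=1)
print(boot.summary())
```

The summary table ends with (abridged):

```
binding model:     two_state
chi-square:        25658.3
reduced chi-sq:    0.961059  (26712 points, 14 free parameters)
parameter                              value         std err
...
K_d                            2.0640682e-05        9.43e-07
k_off                              94.633784            2.32
```

and the bootstrap reports standard errors of 7.1e-07 (0.71 µM) for K_d and
1.92 s⁻¹ for k_off: the data were generated at K_d = 20 µM and
k_off = 100 s⁻¹ with signal-to-noise ≈ 50, so both constants are recovered
within the expected scatter (0.9 and 2.8 standard errors here). On
noiseless data the same protocol returns both constants to better than
0.1%.

The same workflow is available from the shell:

```sh
nmrlineshape design --p0 100 --stock 10000            # titration table
nmrlineshape simulate --config study.yaml --seed 1 --outdir data/
nmrlineshape fit --manifest data/manifest.csv --config study.yaml -o fit.json
nmrlineshape bootstrap --manifest data/manifest.csv --config study.yaml \
    --replicas 50 --seed 1 -o boot.json
nmrlineshape export-fitted --manifest data/manifest.csv --config study.yaml \
    --outdir fitted/
```

See the `config` module docstring for the YAML schema (model parameters in
µM, spin systems with per-state shifts, ROIs as ppm polygons).

## Layout

| module | contents |
| --- | --- |
| `binding` | binding models, equilibria, exchange rate matrices |
| `spins` | spin systems, ROIs, spin groups, parameter packing |
| `spectrometer` | virtual spectrometer (pulse-sequence propagation) |
| `processing` | apodization/FT/phasing chain, noise MLE |
| `nmrpipe` | NMRPipe .ft2 reader/writer, axis arithmetic |
| `fitting` | `TitrationLineshapeModel` / results / bootstrap |
| `synthesis` | titration design, synthetic dataset generator |
| `examples`, `config`, `cli`, `plotting` | ready-made studies, YAML I/O, CLI, plots |

`docs/methods.md` documents the model assumptions, numerical conventions
and known limitations.
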