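# protonwire

Grotthuss proton-wire energetics: locate proton-transfer pathways in
hydrogen-bonded networks, sample them with umbrella biasing along a smooth
excess-charge coordinate, reconstruct free-energy profiles with WHAM and
bootstrap uncertainties, and judge their bioenergetic feasibility.

The package is aimed at computational biophysicists studying proton
translocation through proteins - the motivating system is the quinol
oxidation (Q_o) site of the cytochrome bc1 complex, where protons leave the
substrate through chains of crystal waters and protonable side chains
(Tyr, Glu, His, heme propionate).

## The coordinate and the estimator

The excess proton is tracked by the modified center of excess charge

    eps = sum_i r_Hi - sum_j w_j r_Xj + sum_ij f_sw(d_ij) (r_Xj - r_Hi),
    f_sw(d) = 1/(1 + exp((d - 1.20 A)/0.04 A)),

with weights w equal to each heavy atom's reference proton count (water O
2.0, Tyr O 1.0, His N 0.5, carboxylate/quinone O 0.0), and reduced to the
relative transfer coordinate zeta = d_eD/(d_eD + d_eA) in [0,1] between a
donor (0) and an acceptor (1). Umbrella windows (0.1 apart, k = 1000
kJ/mol per unit zeta^2, 310 K Langevin dynamics with 25 ps^-1 friction and
1 fs steps) are combined by the weighted histogram analysis method; 95%
bands come from a 30-cycle block bootstrap. Profiles classify into five
feasibility categories (plausible / trapped intermediate / infeasible
uphill / dissipative downhill / unstable product) using thresholds from
the Q-cycle's free-energy budget. `docs/methods.md` has the details.

## Worked example

Build a synthetic wire whose exact profile is known, sample it with the
standard window protocol, and compare:

```python
import numpy as np
from protonwire import build_toy_wire, scenario_presets, UmbrellaWHAM
from protonwire.toys import sample_toy_profile

system = build_toy_wire(scenario_presets()["plausible"])
segments = sample_toy_profile(system, steps_per_window=50000, base_seed=42)
result = UmbrellaWHAM.from_segments(segments).fit().bootstrap(n_cycles=30, seed=7)
print(result.summary())

truth = system.reference_profile()          # quadrature-exact
mask = np.isfinite(result.profile.G) & np.isfinite(truth.G)
print("max |G_wham - G_exact| =",
      round(float(np.nanmax(np.abs(result.profile.G - truth.G)[mask])), 2), "kJ/mol")
print(result.classify().category)
```

Output:

```
Umbrella WHAM free-energy profile
================================================
windows:            19
samples:            93568
temperature:        310.0 K
bins (sampled):     100 (100)
WHAM iterations:    1357  (residual 9.93e-09 kJ/mol)
max G (sampled):    39.61 kJ/mol
bootstrap cycles:   30  (median 95% band 2.60 kJ/mol)
max |G_wham - G_exact| = 1.67 kJ/mol
plausible
```

19 windows because the overlap-refinement protocol added stiffer windows
across the steep stretches of the coordinate; the reconstructed profile
agrees with the exact reference to within ~1.7 kJ/mol on sampled bins, and
its features (forward barrier ~36 kJ/mol, reaction free energy ~+6 kJ/mol)
classify the transfer as a plausible, near-thermoneutral step.

The same stages are scriptable from the shell:

```bash
protonwire toy --preset trapped --seed 7 --out run/
protonwire pipeline --config config.yaml --out run/
protonwire wires --structure site.pdb --sites sites.yaml
protonwire classify --profile run/profile.tsv
```

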