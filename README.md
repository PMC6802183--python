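# hypoxsim

Simulation and analysis of how tumor-cell heterogeneity shapes the
response of ERK and Akt signaling to hypoxia and to kinase / VEGF-binding
inhibitors.

Solid tumors contain hypoxic regions, and experimental reports of what
low O₂ does to ERK and Akt activation disagree — increases, decreases and
no change have all been observed, in different cell lines. `hypoxsim`
implements an integrated ordinary-differential-equation model that makes
this disagreement a *prediction*: hypoxia acts on a tumor-signaling
network through two opposing channels, and which one wins depends on
each cell's biomolecule concentrations.

The two channels:

1. **HIF-driven VEGF production.** A HIF-1α module (constitutive
   synthesis, O₂-dependent prolyl-hydroxylase degradation operating near
   saturation, ARNT binding, transcription) raises VEGF mRNA as O₂
   falls. VEGF synthesis in the signaling module scales as
   `k_syn · ([mRNA]/[mRNA₀])^k_α` with `k_α = 2`; VEGF then binds VEGFR,
   the phosphorylated receptor dimer recruits PI3K, and PIP3 activates
   Akt — so *mild* hypoxia raises pAkt.
2. **ATP depletion.** Cellular ATP follows a hyperbolic O₂ relation,
   `[ATP] = ATP_max · f / (0.033 + f)` (f = O₂ as fraction of normoxia;
   half-maximal at 3.3%). Every phosphorylation reaction uses ordered
   bi-substrate kinetics in which ATP binds the kinase first:

   ```
   rate = Vmax·[ATP]·[S] / (K_M,ATP·K^AB + K^AB·[ATP] + [ATP]·[S])
   ```

   Each `K^AB` is calibrated so that `(K_M,ATP/[ATP]_normoxia + 1)·K^AB`
   equals the original model's Michaelis constant `K′`, making the
   integrated model's normoxic behavior identical to its source models.
   Under *severe* hypoxia the effective substrate constant inflates and
   phosphorylation — hence pERK and pAkt — falls.

ATP-competitive inhibitors of RAF, MEK or Akt phosphorylation multiply
the `K_M,ATP·K^AB` term by `(1 + [D]/K_i)`; VEGF-binding inhibitors
divide the receptor-association rate by `(1 + [D]/K_i)`.

Cell-to-cell variability is simulated as a **virtual population**:
Latin-hypercube samples of every signaling-module species over a
100-fold log range around its nominal value, each equilibrated to its
own normoxic steady state before O₂ steps or drugs are applied.
Responses are categorised (decrease / no change / increase, ±10% band)
and shallow decision trees identify which baseline concentrations — in
particular the phospho/total ratios pERK/tERK and pAkt/tAkt — separate
sensitive from insensitive cells.

The shipped model definition is a compact reconstruction (39 species,
43 reactions, every row flagged `provenance=reconstructed` in
`src/hypoxsim/data/`); parsers and assembly accept any species/reaction
table pair in the same schema.

## Worked example

```python
from hypoxsim import builtin_model, Environment, integrate_to_steady_state

net = builtin_model()                       # assembled integrated model
base = integrate_to_steady_state(net, net.initial_state())
for f in (0.05, 0.005, 0.001):              # 5%, 0.5%, 0.1% of normoxia
    ss = integrate_to_steady_state(net, base.state, Environment(o2_fraction=f))
    e, a, v = (net.index[s] for s in ("pERK", "pAkt", "VEGF"))
    print(f"O2 {100*f:>4g}%  pERK ratio {ss.state[e]/base.state[e]:.3f}  "
          f"pAkt ratio {ss.state[a]/base.state[a]:.3f}  "
          f"VEGF fold {ss.state[v]/base.state[v]:.1f}")
```

prints, for the nominal cell:

```
O2    5%  pERK ratio 1.018  pAkt ratio 1.723  VEGF fold 753.5
O2  0.5%  pERK ratio 0.926  pAkt ratio 1.519  VEGF fold 6232.0
O2  0.1%  pERK ratio 0.481  pAkt ratio 0.675  VEGF fold 7615.1
```

Mild hypoxia leaves pERK within the ±10% no-change band while VEGF-driven
signaling raises pAkt 72%; at 0.1% O₂ ATP depletion wins and both
readouts drop. Other sampled cells respond categorically differently —
that heterogeneity is the object of study:

```bash
hypoxsim phenotype --n 200 --seed 11 --o2 5 --o2 0.5 --o2 0.1 --out run/
hypoxsim tree --n 200 --seed 11 --o2 0.5 --out run/
hypoxsim report --out run/
```

The `tree` stage prints the root feature of the change-vs-no-change
tree (`pAkt/tAkt`): cells whose Akt pool is already near-fully
phosphorylated cannot respond to hypoxia in either direction.

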