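# Methods

## Model

The integrated model couples three pieces.

**HIF module.** HIF-1α is synthesized at a constant rate and degraded by
an O₂-coupled Michaelis–Menten hydroxylase term,
`V·f·[HIF]/(K + [HIF])` with `f` the O₂ fraction of normoxia, plus a slow
first-order basal decay. Because the hydroxylase operates near substrate
saturation at normoxia, HIF induction is switch-like: it stays pinned low
until the degradation capacity `V·f` approaches the synthesis rate, then
rises steeply. HIF binds ARNT reversibly and the complex drives mRNA
production through a saturable transcription term. All HIF-module
parameters are held fixed across the virtual population.

**Tumor-signaling module.** VEGF and EGF receptor arms converge on PI3K:
VEGF binds VEGFR (reversible, the inhibitable step), the bound receptor
dimerizes, autophosphorylates, and the phosphorylated dimer recruits and
activates PI3K; EGF–EGFR does the same in parallel. PIP3 produced from
PIP2 recruits both Akt and PDK to the membrane; PDK phosphorylates
membrane Akt. SOS bound to either receptor drives RAF phosphorylation,
then the RAF→MEK→ERK cascade, with pERK-mediated SOS inactivation and
pAkt-mediated RAF inhibition (RAFi) as crosstalk. Rsk and PLCγ branches
carry no feedback but populate the readout set.

**ATP module.** Cellular ATP is an *algebraic* function of O₂,
`[ATP] = ATP_max·f/(f_half + f)` with `ATP_max = 3000 μM` and
`f_half = 0.033` (half-maximal ATP at 3.3% of normoxic O₂). No ATP
dynamics are modeled; O₂ steps change ATP instantaneously. The rationale
is time-scale separation — energy metabolism equilibrates much faster
than the signaling steady states studied here.

**Coupling.** Every phosphorylation reaction is tagged `atp_dependent`
and uses the ordered bi-substrate law with ATP binding first:

    rate = Vmax [ATP][S] / (K_M,ATP·K^AB + K^AB·[ATP] + [ATP]·[S]).

The source models state ATP-implicit kinetics `Vmax·[S]/(K′+[S])`; each
`K^AB` is derived at assembly by `K^AB = K′ / (K_M,ATP/[ATP]_norm + 1)`.
The reference `[ATP]_norm` is the value the ATP–O₂ relation produces at
f = 1 (≈ 2904 μM), not the 3000 μM maximal parameter; only with that
convention is every reaction rate of the assembled model *exactly* equal
to its source-model rate at normoxia (verified to 1e−9 relative in the
tests). The choice is recorded here because the two candidate
conventions differ by ~0.1% in `K^AB`.

VEGF synthesis is rescaled by `([mRNA]/[mRNA₀])^k_α`, `k_α = 2`, with
`mRNA₀` computed by equilibrating the HIF module alone at normoxia at
assembly time (never hard-coded). The VEGF degradation constant is then
set so the integrated model's normoxic VEGF steady state equals the
tumor table's baseline value; when the shipped constant already
satisfies this within 1e−6 relative it is left bit-identical, preserving
exact normoxia equivalence.

**Drugs.** ATP-competitive kinase inhibitors multiply the
`K_M,ATP·K^AB` term by `(1 + [D]/K_i)`; because the other denominator
terms scale with ATP, the same dose inhibits more strongly when ATP is
low — hypoxia potentiates RAF/MEK/Akt inhibitors without any additional
assumption. Inhibition is surmountable (the rate tends to a
drug-insensitive floor `Vmax·[S]/(K^AB+[S])` at saturating ATP·substrate,
never to zero, as the competitive mechanism dictates). VEGF-binding
inhibitors divide the association term of the reversible binding step by
`(1 + [D]/K_i)`; dissociation is unaffected. Drug strength is always the
dimensionless `[D]/K_i`; an absolute `K_i` never enters.

## The reconstructed model tables

The shipped tables (`src/hypoxsim/data/*.tsv`, 39 species / 43
reactions, every row `provenance=reconstructed`) are a compact
reconstruction, not a transcription: the supplementary species/reaction
tables of the source publications were not available, so rate constants
were chosen to reproduce the *qualitative* behavior the integrated
system is known for — switch-like HIF induction, low normoxic VEGF tone
with receptor engagement under hypoxia, EGF-driven baseline ERK/Akt
activity, and graded ATP limitation of the terminal phosphorylation
steps. Species initial values in the tables are the nominal normoxic
steady state of the assembled model, so population sampling is centred
on a self-consistent baseline. Parameter counts for the shipped model:
94 numeric rate constants in the tables, 106 counting each derived
`K^AB` as a distinct constant.

Two structural choices matter most and were made deliberately:

* **Terminal cycles are zero-order-sensitive.** The ERK and Akt
  phosphorylation steps run far from substrate saturation
  (`K′ ≫ [S]`) against *saturable* (Michaelis–Menten) phosphatases.
  In that regime the phospho/total ratio directly encodes a cell's
  robustness to inflation of the effective substrate constant: a cycle
  with ratio r tolerates a fold-inflation `a/a₀` of
  `(K_M,ATP/[ATP]+1)` without leaving the ±10% band iff
  `(1−r)·(a/a₀−1) < 0.1·r`. With `K_M,ATP = 100 μM` this boundary is
  r ≈ 0.68 at 0.5% O₂ and r ≈ 0.9 at 0.1% O₂ — which is why the fitted
  decision trees recover pAkt/tAkt and pERK/tERK as root features with a
  pERK/tERK threshold near 0.9, and why those ratios are the right
  features mechanistically rather than by correlation.
* **Per-reaction ATP K_M.** The library default for `K_M,ATP` is 100 nM
  (the printed value), but at that value `(K_M,ATP/[ATP]+1)` deviates
  from 1 by <0.2% even at 0.1% O₂ — far too weak to move any readout.
  Kinase ATP K_M values measured across many kinases are tens to
  hundreds of μM, so the shipped tables override `K_M,ATP` per reaction
  on that scale (20 μM for receptor-proximal steps, 100 μM for the
  terminal ERK/Akt steps and regulatory phosphorylations). The upstream
  /terminal split makes the terminal-cycle saturation margin — not
  upstream collapse — the locus of cell-to-cell response divergence.

What the generator therefore does and does not show: passing tests
demonstrate that the *mechanisms* (two opposing hypoxia channels,
ratio-governed robustness, ATP-competitive drug potentiation, hypoxic
VEGF excess blunting binding inhibitors) produce the published response
taxonomy; they do not validate the published numeric population
fractions, which depend on the unavailable full parameterisation. The
reconstruction's VEGF dynamic range under severe hypoxia (10²–10⁴-fold)
is larger than the published traces (12–160-fold maximal), a known
divergence accepted to keep the hypoxic VEGF excess large enough to
carry signal through strong binding inhibition.

## Virtual population

Initial concentrations of every tumor-module species (complexes
included) are sampled by Latin hypercube, log₁₀-uniform over
`[x₀/10, 10·x₀]` (100-fold total range centred on the nominal, so the
published nominal is the median), exactly one draw per equal-log-width
bin per species. HIF/ATP-module values stay fixed. Each case is
equilibrated at normoxia; cases whose equilibration does not converge
are flagged and excluded from phenotype denominators (the count is
reported). Conditions (O₂ steps, drugs) always start from the case's own
normoxic steady state and are mutually independent.

Defaults follow the full study (20,000 cases); the shipped tests and
examples use 200–500 cases, which is enough for stable category
orderings and tree roots (binomial 95% intervals are attached to every
fraction for exactly this purpose).

## Numerics

* Stiff integration: LSODA via `scipy.integrate.solve_ivp`, rtol 1e−6,
  atol 1e−9 (nM scale), with an analytic Jacobian assembled per rate law
  (finite-difference Jacobian sweeps would dominate population runtime).
* Steady state: scaled derivative norm `max|dx/dt|/(1+|x|) < 1e−8`
  required at two consecutive geometrically-growing checkpoints
  (t_max 1e6). When the residual is already small, a bounded
  least-squares polish of `dx/dt = 0` — augmented with the conserved-
  moiety constraints anchored at the integrated state, so the root is
  isolated inside the trajectory's stoichiometric compatibility class —
  accelerates convergence; a polish that drifts >5% from the integrated
  state or misses the tolerance is rejected and integration continues.
  `t_elapsed` is recorded so slow transients at the horizon are
  auditable.
* Negative concentrations: entries in (−10·atol, 0) are clamped to zero
  before rate evaluation (stiff-solver round-off); anything below that
  aborts with the species named.
* Ties and boundaries: the no-change band is closed, `[0.9, 1.1]`;
  sensitivity bands at the reference dose are `ratio ≤ 0.6` (sensitive)
  and `ratio ≥ 0.9` (ineffective). Half-inhibition doses are interpolated
  log-linearly and reported absent when a curve never crosses 0.5.
* Decision trees: CART (`scikit-learn`), depth ≤ 3, minimum leaf 5% of
  the sample, fixed seed; features are the *pre-stimulus* (normoxic
  steady-state) concentrations plus derived phospho/total ratios.
  Sampled-initials features are available behind a switch; the
  steady-state convention is used because pre-stimulus levels are what
  the split thresholds refer to physiologically. "Total" protein
  includes complexed forms (PIP3-bound Akt counts toward total Akt) via
  an explicit mapping, keeping ratios in [0, 1].

## Interfaces and scope

Model definitions are two delimited tables (species, reactions) with a
documented schema; parameters are `key=value` lists, species-valued
entries (`enzyme`, `modifiers`) reference table rows and are validated.
The CLI (`hypoxsim build-model | population | phenotype | tree | drug |
report`) is a thin layer over the library; every artifact directory gets
a JSON sidecar with seed, sizes and a config hash. Configuration files
were deliberately dropped in favour of explicit flags plus sidecars —
the flag surface is small and the sidecar reproduces any run.

Known limitations: no parameter fitting to time-course data; no spatial
drug-penetration or tumor-geometry effects; no correlated sampling
between species; no bifurcation analysis (non-converged or oscillatory
cases are excluded and counted, not studied); SBML export is not
provided.
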