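# stempop

Population-balance modeling of mesenchymal stem-cell proliferation and
osteogenic differentiation kinetics, with electrical stimulation entering as
an experimental condition.

## The problem

Human mesenchymal stem cells (hMSCs) cultured on a scaffold proliferate while
differentiating toward osteoblasts; early differentiation is marked by
intracellular alkaline phosphatase (ALP) activity. Time-course assays measure
two population aggregates: the total cell number *N(t)* (LDH assay) and the
total ALP activity *Φ(t)* (ALP assay), typically on days 7, 14, 21 and 28, in
control and electrically stimulated cultures. `stempop` is for modelers and
experimentalists who want to connect those population-level curves to the
rates of *single-cell* processes — division, differentiation, ALP synthesis
and degradation — and to quantify how an applied electric field shifts them.

## The model

The population state is the density *n(a, t)* of cells over per-cell ALP
activity *a*. It evolves under a Smoluchowski-type balance equation

```
∂n/∂t = [division gain/loss with kernel k_d(a, a′)]
        − ∂(s_i(a)·n)/∂a + ∂(d_o(a)·n)/∂a − k_f(a)·n
```

with division kernel *k_d*, differentiation (removal) rate *k_f*, and ALP
synthesis / degradation fluxes *s_i*, *d_o*. The zeroth and first moments of
*n* are exactly the assay observables *N(t)* and *Φ(t)*.

Two closed-form model variants, both with symmetric non-conserved divisions
(daughters copy the parent activity) at effective rate *k_d = 2/t*:

* **PSCD** (progressive differentiation): *d_o(a) = d₀·a*, *k_f = 0* —
  every cell's ALP decays exponentially, so
  *N(t) = N̄₀·t²* and *Φ(t) = Φ̄₀·t²·e^(−d₀·t)*, a rise-and-fall curve
  peaking at *t\* = 2/d₀*.
* **ISCD** (instantaneous differentiation): constant *k_f*, no fluxes —
  *N* and *Φ* are both ∝ *t²*, so *Φ* can never show an interior peak.
  Data with an ALP maximum at an interior day therefore reject ISCD.

The 2/*t* division slowdown, combined with quadratic growth and *ρ = N/V*,
implies a density-dependent division rate *k_d(ρ) = 2·√(N̄₀/(ρV))* — an
inverse-square-root decrease with crowding.

The package provides six building blocks: kernel presets and parameter
containers (`model_core`), a finite-volume PDE solver for *n(a, t)*
(`balance_solver`), the closed forms and derived curves (`analytic`), an
event-driven single-cell simulator serving as an independent stochastic
oracle (`agents`), weighted least-squares fitting with χ² and
condition comparison (`fitting`), and a synthetic assay generator plus CSV
I/O (`synthetic_data`).

## Worked example

Generate a synthetic control/stimulated assay pair and fit the progressive
model:

```
$ stempop synth --model pscd --seed 1 --out assay.csv
wrote assay.csv and assay_stimulated.csv
$ stempop fit --data assay.csv --model pscd --t0 7
```

which prints (abridged):

```json
{
  "condition": "control",
  "cell_counts": {
    "estimates": {"N_bar0": 541.207318354682},
    "standard_errors": {"N_bar0": 7.1572967858473335},
    "chi2_weighted": 0.8063658715807192
  },
  "alp": {
    "estimates": {
      "Phi_bar0": 0.052123623209700924,
      "d0": 0.16987046224455427,
      "inv_d0": 5.886838634490489,
      "Phi0": 0.7777034866117667
    },
    "chi2_weighted": 0.45547175127977824
  }
}
```

Reading the numbers: the quadratic-growth amplitude N̄₀ ≈ 541 cells/day²
(the generator's truth is 535), the ALP decay time 1/d₀ ≈ 5.89 days (truth
5.84), and the day-7 total ALP Φ₀ ≈ 0.78 (truth 0.8007). The implied ALP
peak day is 2/d₀ ≈ 11.8. Fitting the stimulated file the same way gives a
larger 1/d₀ (truth 6.2 days): the field *slows* ALP degradation, i.e. ALP
expression persists longer under stimulation, while the cell-count dynamics
are unchanged.

The same analyses are available as library calls
(`stempop.fit_alp_activity`, `stempop.compare_conditions`,
`stempop.solve_population_balance`, `stempop.simulate_agents`, ...); see the
docstrings and `docs/methods.md`.

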