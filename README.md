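# bindmode

Biophysics-informed modelling of multi-ligand in-vitro selection experiments,
and design of binders with prescribed specificity profiles.

## The problem

In-vitro selection (e.g. phage display of an antibody library against ligands
immobilized on magnetic beads) enriches variants that bind *anything* present
in the tube — the intended ligand, the bead surface, or nothing at all when
a phage stays in solution. When the goal is a binder that discriminates two
chemically similar ligands, or one that binds several ligands at once, the
individual contributions can rarely be separated experimentally. `bindmode`
separates them computationally: it fits a thermodynamic multi-state model to
the sequencing read counts of a set of coordinated selection experiments,
attributing to every variant one binding free energy per **mode** (per
ligand, per surface, plus an unbound state), and then uses those energies to
predict unseen experiments and to design new variants.

## The model

A variant *s* in experiment *t* is selected with probability

```
p_st = Σ_{w∈S_t} exp(μ_wt − E_ws) / Σ_{w∈S_t∪N_t} exp(μ_wt − E_ws)
```

— a Boltzmann law over the selected (`S_t`) and unselected (`N_t`) modes
available in the experiment, with `E_ws` the free energy of variant *s* in
mode *w* (RT units) and `μ_wt` the mode's chemical potential (log relative
ligand concentration). Library composition propagates across selection
rounds as `N_st' ∝ p_st N_st`; read counts are multinomial samples of the
composition at each sequenced step. Energies (parametrized per mode by
additive per-site fields or by a shallow dense network on the one-hot
encoding), chemical potentials and the unobserved initial abundances `N_s0`
are all fitted jointly by maximum likelihood with L2 regularization, by exact
analytic gradients and Adam on mini-batches of sequences. Because the
library varies a handful of contiguous positions (20⁴ = 160,000 variants at
length 4), energies are evaluated exhaustively, and design reduces to exact
ranking of the whole space: minimize the target mode's energy, maximize the
off-target modes' (specific), or minimize the worst target-mode energy
(cross-specific).

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

```python
import numpy as np
import bindmode as bm

# A synthetic two-round campaign with known ground truth: two hairpin
# ligands ("black"/"blue") on beads, presented alone or as a 50-50 mix,
# 8,000-variant library, 100,000 reads per dataset.
campaign = bm.simulate_campaign(bm.SimulationConfig(length=3, depth=100_000, seed=1))

state, report = bm.fit(
    campaign.graph, campaign.counts, campaign.space,
    bm.FitConfig(epochs=80, batch_size=128, learning_rate=0.01, seed=0),
)
print(f"NLL {report.initial_nll:.0f} -> {report.final_nll:.0f}")
rr = bm.recovery_report(campaign, state)
for w in ("black", "blue", "bead"):
    print(w, f"energy Pearson vs truth = {rr[w]['energy_pearson']:.3f}")
```

prints

```
NLL 6284154 -> 6171426
black energy Pearson vs truth = 0.988
blue energy Pearson vs truth = 0.993
bead energy Pearson vs truth = 0.999
```

i.e. the fit recovers each mode's energy landscape almost exactly (Pearson on
centered energies over all 8,000 variants), and the inferred initial
abundances rank-correlate with the truth at 0.99. Designing specific and
cross-specific candidates from these energies and re-selecting them in fresh
simulated experiments places 65–85% of each designed group in its intended
enrichment quadrant, versus 20–30% background occupancy
(`bindmode.simulate.design_validation_experiment`).

The same workflows are scriptable from a shell:

```
bindmode simulate --length 3 --depth 100000 --seed 1 --out sim/
bindmode fit --graph sim/graph.yaml --counts-dir sim --length 3 \
    --epochs 80 --learning-rate 0.01 --out state.json --report report.tsv
bindmode predict --state state.json --node mix_r1 --out pred.tsv \
    --parent-counts sim/library.tsv --child-counts sim/mix_r1.tsv
bindmode design --state state.json --objective cross_specific \
    --target black --target blue --exclude-counts sim/library.tsv \
    --out-prefix designs
```

## Layout

| module | contents |
|---|---|
| `bindmode.space` | enumerable combinatorial sequence space, one-hot codec |
| `bindmode.data_io` | count tables (TSV), FASTQ read extraction + stop-codon/flank filters, model-state files |
| `bindmode.energy_models` | independent-site and shallow-dense energy maps |
| `bindmode.selection_model` | Boltzmann selection law, experiment DAG, propagation |
| `bindmode.inference` | multinomial likelihood, analytic gradients, Adam fit |
| `bindmode.evaluation` | empirical enrichments, correlations, ablation, bias checks |
| `bindmode.design` | specificity objectives, quadrant classification, Fisher validation |
| `bindmode.simulate` | ground-truth campaign generator and recovery reports |
| `bindmode.cli` | `bindmode` command with simulate/fit/predict/design/evaluate |
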