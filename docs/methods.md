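# Methods

## The model

`bindmode` models coupled in-vitro selection experiments (phage display of an
antibody library against combinations of ligands) with a multi-state Boltzmann
selection law. In each experiment *t* a displayed variant *s* can occupy one
of several thermodynamic **modes** *w*: bound to a specific ligand (a DNA
hairpin), bound to the bead surface the ligands are immobilized on, an
optional non-binding *pseudo* mode absorbing production/expression biases, or
unbound in solution. Each mode carries a sequence-dependent free energy
`E_ws` (dimensionless, RT units; lower = stronger binding) and a
per-experiment chemical potential `mu_wt`, interpretable as the log relative
concentration of the free ligand. The probability of being captured is

    p_st = sum_{w in S_t} exp(mu_wt - E_ws)
           / sum_{w in S_t ∪ N_t} exp(mu_wt - E_ws)

where `S_t` / `N_t` are the selected / unselected mode sets of the experiment
(the unbound mode is always unselected). Library composition chains across
experiments as `N_st' ∝ p_st · N_st`, starting from initial abundances
`N_s0` that are *not* observed and are therefore fitted.

Read counts `R_st` at every sequenced step are treated as one multinomial
draw per dataset from the model frequencies `f_st`, giving the loss

    NLL = - sum_{t,s} R_st log f_st + lambda ||params||^2.

The L2 penalty acts on energy parameters and free chemical potentials; the
log-abundance logits are compositional and left unpenalized (shrinking them
would bias frequencies toward uniform).

### Gauge fixing

Two transformations leave every `p_st` invariant: a uniform shift of all
`mu_wt` within one experiment, and a joint shift of one mode's `mu` (in all
experiments) and its `E` (for all sequences). The unbound mode is pinned at
`E ≡ 0, mu ≡ 0`, which fixes the first freedom; the second is softly anchored
by the L2 penalty on energies, and every truth-vs-fit comparison centers
energies per mode before correlating, so the residual gauge never enters a
reported number.

### Energy parameterizations

* `independent_site`: `E(s) = sum_i h[i, s_i]`, 20·L parameters per mode.
* `shallow_dense`: one hidden layer (default 20 tanh units, configurable) on
  the flat one-hot encoding, able to express inter-site couplings. The
  published description of the underlying architecture is not specific about
  width or activation, so these defaults are this package's choice and are
  exposed in `FitConfig`.

Per-mode models share no parameters. Because the library varies only L
contiguous positions (L = 4 in the experiments emulated here, 20^4 = 160,000
variants), every model is evaluated exhaustively over the enumerated space;
a configurable cap (default 10^7) guards against accidental enumeration of
larger spaces.

## Inference

The loss gradient is computed analytically: the multinomial term is
backpropagated through the log-frequency recursion of the experiment DAG and
through the selection law into chemical potentials and energy-model
parameters (softmax Jacobians at each node, scatter-adds into the one-hot
parameter blocks). The gradient is exact — the test suite checks it against
central finite differences of an independently written brute-force likelihood
at 1e-6 relative tolerance — and optimization uses an Adam loop (default step
1e-3; the scaled-down study fits below use 0.01) over mini-batches of 128
sequences, re-shuffled each epoch. A batch contributes
`sum_{s in batch} R_st log f_st` with frequencies normalized over the *full*
space: the multinomial normalizer couples all sequences, and batch-local
normalization would bias the estimator. The regularizer is scaled by the
batch fraction so one epoch applies exactly one unit of `lambda`.

Initialization: abundance logits at `log(R_library + 0.5)` (centered),
energies at zero fields (independent-site) or 1/sqrt(fan-in) Gaussian weights
(dense, seeded), free `mu` at 0. All randomness flows from `FitConfig.seed`;
fits are bitwise reproducible. Divergence (non-finite loss) raises an error
carrying the last finite state.

Chemical potentials are free per (mode, experiment) by default; experiments
can be tied through a shared `mu_tie` key, and known relative concentrations
can be pinned via `fixed_mu` (a 50–50 mixture node inherits each component's
single-ligand `mu` minus ln 2). Bead pre-selection datasets are modeled as
observations of the bead-bound fraction; since depletion is partial, the pool
entering the main selection is the parent pool itself.

## The synthetic-data generator

`simulate` emulates the campaign design the model was built for: an initial
combinatorial library with ~50% of variants absent and log-normal (sigma = 1)
abundance dispersion among present variants; a bead pre-selection dataset;
two successive selection rounds against two closely related ligand complexes
("black", "blue") presented alone or as an equal mixture, with the bead mode
always selected; and multinomial read sampling at 10^5 reads per dataset.
Ground-truth energies are independent-site fields ~ N(0, 1) (optionally with
pairwise couplings for misspecification studies); ligand chemical potentials
default to 0 with the bead mode at −1, reflecting that bead capture is the
weaker, always-present pull (elutions from naked beads are one to two orders
of magnitude smaller than from ligand-coupled beads in the emulated
protocol).

Selection acts deterministically on frequencies; the only noise is read
sampling, matching the likelihood's noise model. Real campaigns additionally
contain physical bottlenecks (finite phage counts, infection), amplification
noise and sequencing errors that the generator deliberately omits — passing
recovery tests therefore demonstrates correctness of inference under the
model's own assumptions, not robustness to those artifacts. Amplification
and codon-bias *checks* are provided in `evaluation` to detect such artifacts
in real data.

## Scaled-down study conditions

Reference computations (test suite and `scripts/acceptance.py`) run on a
length-3 space (8,000 variants) with the full two-round graph at 10^5 reads
per dataset, fitted with independent-site energies for 80 epochs at step
0.01. At these sizes a full fit takes well under a minute on one CPU, and:

* per-mode energies are recovered at Pearson ≈ 0.99 after centering;
* inferred initial abundances rank-correlate with truth at ≈ 0.99;
* the hidden-ligand replay (train on mixture + blue + beads, predict the
  withheld black arm via the mixture's fitted `mu` + ln 2) reaches
  log-enrichment Pearson ≈ 0.97;
* ablating to a single hairpin mode roughly halves the held-out mixture
  correlation, reproducing the need for both modes;
* designed specific / cross-specific candidates land in their intended
  enrichment quadrant at 65–85% versus 20–30% background occupancy.

Raw empirical enrichments are noisy at this depth (~12 reads per variant):
their log-log correlation with the true selection probabilities is ~0.6
over all observed variants and exceeds 0.8 once the parent count is ≥ 20.
Model-based numbers are unaffected because the fit pools information across
datasets and sequences.

## Numerical choices and edge cases

* All sums of exponentials subtract the per-sequence maximum of `mu - E`
  first; probabilities are handled in log space end to end.
* An empty selected set returns p = 0 with a warning (a selection step that
  captures nothing); all-zero survival during propagation is an error naming
  the node.
* Enrichment policies: raw ratio with zero-parent records dropped (default),
  pseudocount, or depth-invariant frequency ratio; the policy is recorded in
  the output.
* Quadrant classification assigns boundary values to the unfavorable side;
  non-finite points are labeled `neither` with a warning.
* Design ties break by enumeration index, making outputs byte-reproducible.
* Count tables are validated on ingestion (non-negative integers, alphabet
  and length checks); duplicate rows are summed. Reads with ambiguous bases
  in the variable region are discarded during extraction (the conservative
  choice; they are counted in the rejection report).

## Calibration of the neutral-selection check

With all energies equal, every dataset is a multinomial draw from the initial
composition; the simulator check runs a chi-square goodness-of-fit per
dataset (bins with expected count ≥ 5) over 20 seeds. Across ~160 tests at
alpha = 0.01 the null itself produces ~1.6 false rejections, so the assertion
bounds the rejection count by the upper binomial tail (≤ 5) rather than
demanding zero — a zero-rejection criterion would fail a correct simulator
about one time in five.

## Known limitations

* No amplification-step likelihood term and no sequencing-error model.
* No epistatic (Potts) energy parameterization; the dense network is the
  only coupling-capable option.
* Mini-batching recomputes the full-space normalizer per batch: exact, but
  the per-epoch cost grows with (space size × batches). Practical up to
  ~10^5–10^6 variants; beyond that, use full-batch mode or fewer batches.
* Chemical potentials of modes absent from all training experiments are
  undefined; predictions for such modes require explicitly fixed `mu`.
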