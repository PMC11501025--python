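"""Synthetic selection campaigns with known ground truth.

The generator emulates the experimental design this package models: a
combinatorial CDR library with heavy-tailed initial abundances and about half
of all variants absent, a bead pre-selection, and two successive rounds of
selection against two closely related ligand complexes ("black", "blue")
presented alone or as an equal mixture, with the bead surface as a third,
always-selected binding mode and an unselected unbound mode.  Selection acts
deterministically on frequencies through the Boltzmann selection probability;
the only stochasticity is multinomial read sampling at the configured depth,
matching the noise model of the likelihood.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .data_io import CountTable
from .energy_models import EnergyModelBase, IndependentSiteModel
from .inference import ModelState
from .selection_model import (
    UNBOUND,
    ExperimentNode,
    Mode,
    SelectionGraph,
    log_selection_probabilities,
)
from .space import AMINO_ACIDS, SequenceSpace

LN2 = math.log(2.0)


class SimulationError(ValueError):
    pass


def standard_campaign_graph(rounds: int = 2) -> SelectionGraph:
    """The default two-round campaign: beads, black, blue and mix arms.

    The root library feeds a bead pre-selection dataset and three round-1
    selections; each hairpin arm then chains into further rounds.  All
    chemical potentials are left free (untied across rounds).
    """
    if rounds < 1:
        raise SimulationError("rounds must be >= 1")
    nodes = [ExperimentNode("library", None)]
    nodes.append(
        ExperimentNode("beads_r1", "library", selected={"bead"})
    )
    arms = {
        "black": {"bead", "black"},
        "blue": {"bead", "blue"},
        "mix": {"bead", "black", "blue"},
    }
    for arm, sel in arms.items():
        parent = "library"
        for r in range(1, rounds + 1):
            nid = f"{arm}_r{r}"
            nodes.append(ExperimentNode(nid, parent, selected=sel))
            parent = nid
    return SelectionGraph(nodes)


class PairwiseFieldModel(EnergyModelBase):
    """Independent-site fields plus pairwise couplings (ground truth only).

    Used to generate epistatic truths for misspecification tests; the fit
    never uses this parameterization.
    """

    kind = "pairwise_field"

    def __init__(self, mode_id: str, space: SequenceSpace,
                 h: np.ndarray, J: np.ndarray):
        self.mode_id = mode_id
        self.space = space
        self.h = h  # (L, A)
        self.J = J  # (L, L, A, A), used for i < j only

    def energies_codes(self, codes: np.ndarray) -> np.ndarray:
        L = self.space.length
        pos = np.arange(L)
        e = self.h[pos[None, :], codes].sum(axis=1)
        for i in range(L):
            for j in range(i + 1, L):
                e = e + self.J[i, j][codes[:, i], codes[:, j]]
        return e

    def get_params(self) -> np.ndarray:  # evaluation-only model
        return np.concatenate([self.h.ravel(), self.J.ravel()])

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mode_id": self.mode_id,
                "h": self.h.tolist(), "J": self.J.tolist()}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic campaign.

    Defaults are the package's reference conditions: a length-3 space (fast,
    full-scale runs use 4), per-site energy fields of unit scale, ligand
    chemical potentials at 0 with the bead mode at -1 (bead binding is the
    weaker, always-present pull), half of all variants absent from the initial
    library, log-normal abundance dispersion of sigma = 1, and 1e5 reads per
    dataset.
    """

    length: int = 3
    alphabet: str = AMINO_ACIDS
    ligand_modes: tuple[str, ...] = ("black", "blue")
    energy_scale: float = 1.0
    pairwise_scale: float = 0.0
    mu: dict = field(default_factory=lambda: {"black": 0.0, "blue": 0.0, "bead": -1.0})
    absent_fraction: float = 0.5
    lognormal_sigma: float = 1.0
    depth: int = 100_000
    rounds: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.energy_scale < 0 or self.pairwise_scale < 0:
            raise SimulationError("energy scales must be non-negative")
        if not 0 <= self.absent_fraction < 1:
            raise SimulationError("absent_fraction must be in [0, 1)")
        if self.depth < 1:
            raise SimulationError("depth must be >= 1")

    @property
    def space(self) -> SequenceSpace:
        return SequenceSpace(self.alphabet, self.length)


@dataclass
class SimulatedCampaign:
    """A complete synthetic campaign with its ground truth."""

    config: SimulationConfig
    space: SequenceSpace
    graph: SelectionGraph
    truth: ModelState
    initial_frequencies: np.ndarray
    true_frequencies: dict[str, np.ndarray]
    counts: dict[str, CountTable]

    def counts_dense(self) -> dict[str, np.ndarray]:
        return {nid: t.dense(self.space) for nid, t in self.counts.items()}

    def true_log_selection(self, node_id: str) -> np.ndarray:
        return log_selection_probabilities(self.graph[node_id], self.truth)


def sample_ground_truth(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ModelState, np.ndarray]:
    """Draw the true model and initial library frequencies.

    Energies: independent per-site fields ~ N(0, energy_scale^2), with
    optional pairwise couplings ~ N(0, pairwise_scale^2).  Initial library:
    a uniformly chosen ``absent_fraction`` of variants is absent (frequency
    exactly 0); present variants get log-normal frequencies.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    space = config.space
    graph = standard_campaign_graph(config.rounds)
    mode_ids = graph.mode_ids()

    energy_models: dict[str, EnergyModelBase] = {}
    for w in mode_ids:
        h = rng.normal(0.0, config.energy_scale, size=(space.length, space.n_letters))
        if config.pairwise_scale > 0:
            L, A = space.length, space.n_letters
            J = np.zeros((L, L, A, A))
            for i in range(L):
                for j in range(i + 1, L):
                    J[i, j] = rng.normal(0.0, config.pairwise_scale, size=(A, A))
            energy_models[w] = PairwiseFieldModel(w, space, h, J)
        else:
            m = IndependentSiteModel(w, space)
            m.h = h
            energy_models[w] = m

    mu: dict[tuple[str, str], float] = {}
    for node in graph:
        if node.is_root:
            continue
        arm_is_mix = node.node_id.startswith("mix")
        for w in sorted(node.available):
            if w == UNBOUND:
                continue
            base = float(config.mu.get(w, 0.0))
            if arm_is_mix and w in config.ligand_modes:
                base -= LN2  # equal-proportion mixture halves each concentration
            mu[(w, node.tie_key())] = base

    n_absent = int(round(config.absent_fraction * space.size))
    absent = rng.choice(space.size, size=n_absent, replace=False)
    raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=space.size)
    raw[absent] = 0.0
    init = raw / raw.sum()

    # The state's softmax logits mirror the true frequencies for present
    # variants; absent ones sit at a floor far below any present variant.
    with np.errstate(divide="ignore"):
        theta = np.log(init)
    theta[~np.isfinite(theta)] = np.log(init[init > 0].min()) - 50.0

    truth = ModelState(
        space=space,
        graph=graph,
        modes=[Mode(UNBOUND, "unbound")] + [Mode(w) for w in mode_ids],
        energy_models=energy_models,
        mu=mu,
        log_initial_abundance=theta,
        training_meta={"ground_truth": True, "seed": config.seed},
    )
    return truth, init


def simulate_campaign(config: SimulationConfig) -> SimulatedCampaign:
    """Propagate the true frequencies through the graph and sample reads.

    Absent variants keep exactly zero frequency at every node; counts at each
    node are one multinomial draw of ``depth`` reads from that node's true
    frequencies.
    """
    rng = np.random.default_rng(config.seed)
    truth, init = sample_ground_truth(config, rng)
    graph = truth.graph
    space = truth.space

    freqs: dict[str, np.ndarray] = {}
    for node in graph:
        if node.is_root:
            freqs[node.node_id] = init
            continue
        p = np.exp(log_selection_probabilities(node, truth))
        f = freqs[node.parent] * p
        total = f.sum()
        if total <= 0:
            raise SimulationError(f"all-zero survival at node {node.node_id!r}")
        freqs[node.node_id] = f / total

    counts = {
        nid: CountTable.from_dense(nid, rng.multinomial(config.depth, f), space)
        for nid, f in freqs.items()
    }
    return SimulatedCampaign(
        config=config, space=space, graph=graph, truth=truth,
        initial_frequencies=init, true_frequencies=freqs, counts=counts,
    )


def recovery_report(
    campaign: SimulatedCampaign, fitted: ModelState
) -> dict[str, dict[str, float]]:
    """How well a fit recovers the simulator's ground truth.

    Per mode: Pearson correlation between true and fitted energies after
    centering each over the space (the additive gauge), and the spread of
    gauge-corrected chemical-potential errors across nodes.  Also reports the
    Spearman rank correlation between true and inferred initial frequencies
    over variants present in the true library.
    """
    out: dict[str, dict[str, float]] = {}
    for w, true_model in campaign.truth.energy_models.items():
        if w not in fitted.energy_models:
            raise SimulationError(f"fitted state lacks mode {w!r}")
        e_true = true_model.energies_over_space()
        e_fit = fitted.energy_models[w].energies_over_space()
        r = pearsonr(e_true - e_true.mean(), e_fit - e_fit.mean()).statistic
        gauge = e_fit.mean() - e_true.mean()
        mu_errs = []
        for (mode, tie), v_true in campaign.truth.mu.items():
            if mode == w and (mode, tie) in fitted.mu:
                mu_errs.append((fitted.mu[(mode, tie)] - v_true) - gauge)
        out[w] = {
            "energy_pearson": float(r),
            "mu_rmse": float(np.sqrt(np.mean(np.square(mu_errs)))) if mu_errs else float("nan"),
        }
    present = campaign.initial_frequencies > 0
    rho = spearmanr(
        campaign.initial_frequencies[present],
        fitted.initial_frequencies()[present],
    ).statistic
    out["initial_abundance"] = {"spearman": float(rho)}
    return out


def hidden_ligand_task(
    campaign: SimulatedCampaign, hidden_arm: str = "black"
) -> tuple[SelectionGraph, dict[str, CountTable], str]:
    """Training inputs for the hidden-ligand replay.

    Removes the ``hidden_arm`` selection datasets from training; the hidden
    ligand's mode remains identifiable through the mixture arm.  Returns the
    training subgraph, its counts, and the held-out round-1 node id.
    """
    drop = {nid for nid in campaign.graph.nodes if nid.startswith(hidden_arm)}
    keep = [nid for nid in campaign.graph.nodes if nid not in drop]
    sub = campaign.graph.subgraph(keep)
    counts = {nid: campaign.counts[nid] for nid in sub.nodes}
    return sub, counts, f"{hidden_arm}_r1"


def design_validation_experiment(
    campaign: SimulatedCampaign,
    designer_state: ModelState | None = None,
    n_per_group: int = 300,
    n_background: int = 1000,
    depth: int = 100_000,
    seed: int = 0,
):
    """Design specific/cross-specific candidates, then validate them in fresh
    simulated selections.

    Candidates are designed from ``designer_state`` energies (the ground truth
    by default), excluding every variant present in the initial library.  A
    validation library of the designed sequences plus a random background is
    selected once against each single-ligand complex under the true model;
    enrichments on the two axes are computed from multinomial reads, the
    quadrant thresholds are the mean enrichments, and each designed group is
    scored against the background occupancy of its intended quadrant.

    Returns ``(report_frame, details)`` where details carries the raw axes,
    thresholds and group indices.
    """
    from .design import (
        DesignSpec,
        design_candidates,
        threshold_from_means,
        validate_designs,
    )

    rng = np.random.default_rng(seed)
    truth = campaign.truth
    designer = designer_state or truth
    space = campaign.space
    matrix = designer.energy_matrix()
    exclusions = {
        space.sequence(int(i))
        for i in np.nonzero(campaign.initial_frequencies > 0)[0]
    }
    specs = {
        "specific_axis1": DesignSpec(
            "specific", ["black"], ["blue"],
            exclusions=exclusions, n_candidates=n_per_group,
        ),
        "specific_axis2": DesignSpec(
            "specific", ["blue"], ["black"],
            exclusions=exclusions, n_candidates=n_per_group,
        ),
        "cross": DesignSpec(
            "cross_specific", ["black", "blue"],
            exclusions=exclusions, n_candidates=n_per_group,
        ),
    }
    designed: dict[str, list[int]] = {}
    member_idx: list[int] = []
    for label, spec in specs.items():
        res = design_candidates(matrix, spec)
        idx = [space.index(s) for s in res.sequences()]
        designed[label] = idx
        member_idx.extend(idx)
    taken = set(member_idx)
    pool = np.array([i for i in range(space.size) if i not in taken])
    background = rng.choice(pool, size=min(n_background, pool.size), replace=False)
    member_idx.extend(int(i) for i in background)
    members = np.array(member_idx)

    # fresh one-round selections of the validation library against each complex
    f0 = np.full(members.size, 1.0 / members.size)
    lib_counts = rng.multinomial(depth, f0)
    axes = {}
    for axis, arm in (("axis1", "black"), ("axis2", "blue")):
        node = campaign.graph[f"{arm}_r1"]
        p = np.exp(log_selection_probabilities(node, truth))[members]
        f1 = f0 * p
        f1 /= f1.sum()
        sel_counts = rng.multinomial(depth, f1)
        with np.errstate(divide="ignore", invalid="ignore"):
            eps = np.where(lib_counts > 0, sel_counts / np.maximum(lib_counts, 1), np.nan)
        axes[axis] = eps
    defined = np.isfinite(axes["axis1"]) & np.isfinite(axes["axis2"])
    pos_of = {int(s): j for j, s in enumerate(members)}
    groups = {
        label: [pos_of[i] for i in idx if defined[pos_of[i]]]
        for label, idx in designed.items()
    }
    thresholds = threshold_from_means(
        axes["axis1"][defined], axes["axis2"][defined]
    )
    a1 = np.where(defined, axes["axis1"], np.nan)
    a2 = np.where(defined, axes["axis2"], np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # NaN rows -> 'neither'
        report = validate_designs(groups, a1, a2, thresholds)
    details = {
        "thresholds": thresholds,
        "axis1": a1,
        "axis2": a2,
        "groups": groups,
        "members": members,
    }
    return report, details


def hidden_arm_prediction_node(
    fitted: ModelState,
    hidden_mode: str = "black",
    mix_node: str = "mix_r1",
    node_id: str | None = None,
) -> ExperimentNode:
    """Single-ligand prediction node built from a fitted mixture arm.

    The hidden ligand was present in the mixture at half concentration, so its
    single-ligand chemical potential is the fitted mixture value plus ln 2;
    the bead potential is inherited from the same mixture experiment.
    """
    key = (hidden_mode, mix_node)
    if key not in fitted.mu:
        raise SimulationError(f"fitted state has no mu for {key}")
    fixed = {hidden_mode: fitted.mu[key] + LN2}
    if ("bead", mix_node) in fitted.mu:
        fixed["bead"] = fitted.mu[("bead", mix_node)]
    return ExperimentNode(
        node_id or f"{hidden_mode}_pred",
        fitted.graph.root.node_id,
        selected=frozenset(fixed),
        fixed_mu=fixed,
    )
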