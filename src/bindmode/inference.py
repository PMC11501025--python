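"""Maximum-likelihood fitting of the multi-mode selection model.

Read counts at every node of the selection graph are modeled as multinomial
samples of the propagated model frequencies, so the loss is

    NLL = - sum_{t,s} R_st log f_st  +  lambda * ||params||^2

where ``f_st`` is the model frequency of sequence ``s`` at node ``t`` obtained
by chaining ``N_st' ∝ p_st N_st`` from the softmax-parametrized initial
abundances ``N_s0`` (which, being unobserved, are fitted like every other
parameter).  The L2 penalty acts on energy-model weights and free chemical
potentials, not on the compositional log-abundances.

Gradients are exact and analytic: the loss is backpropagated through the
log-frequency recursion of the DAG and through Eq 1 into the energy models,
and optimized with Adam on mini-batches of sequences.  A batch contributes
``sum_{s in batch} R_st log f_st`` with ``f_st`` normalized over the *full*
space (the multinomial normalizer couples all sequences; batch-restricted
normalizers would bias the estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import softmax

from .energy_models import EnergyModelBase, make_energy_model
from .selection_model import (
    UNBOUND,
    ExperimentNode,
    Mode,
    SelectionGraph,
)
from .space import SequenceSpace


class FitConfigError(ValueError):
    pass


class FitDivergedError(RuntimeError):
    """Raised when the NLL becomes non-finite; carries the last finite state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """All trainable parameters of a multi-mode selection model.

    ``mu`` maps ``(mode_id, tie_key)`` to a free chemical potential; fixed
    entries live on the graph nodes and are never touched by training.  The
    unbound mode is the gauge anchor: ``E ≡ 0`` and ``mu ≡ 0`` everywhere.
    """

    space: SequenceSpace
    graph: SelectionGraph
    modes: list[Mode]
    energy_models: dict[str, EnergyModelBase]
    mu: dict[tuple[str, str], float]
    log_initial_abundance: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def mode_energies(self, mode_id: str) -> np.ndarray:
        """Energy vector of a mode over the whole space (unbound: zeros)."""
        if mode_id == UNBOUND:
            return np.zeros(self.space.size)
        return self.energy_models[mode_id].energies_over_space()

    def mu_value(self, mode_id: str, node: ExperimentNode) -> float:
        if mode_id == UNBOUND:
            return 0.0
        if mode_id in node.fixed_mu:
            return float(node.fixed_mu[mode_id])
        return self.mu[(mode_id, node.tie_key())]

    def initial_frequencies(self) -> np.ndarray:
        return softmax(self.log_initial_abundance)

    def energy_matrix(self):
        from .energy_models import EnergyMatrix

        mode_ids = sorted(self.energy_models)
        values = np.stack(
            [self.energy_models[w].energies_over_space() for w in mode_ids], axis=1
        )
        return EnergyMatrix(self.space, mode_ids, values)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "space": {"alphabet": self.space.alphabet, "length": self.space.length},
            "graph": self.graph.to_doc(),
            "modes": [{"mode_id": m.mode_id, "kind": m.kind} for m in self.modes],
            "energy_models": {
                w: m.to_dict() for w, m in self.energy_models.items()
            },
            "mu": [[w, tie, float(v)] for (w, tie), v in sorted(self.mu.items())],
            "log_initial_abundance": [float(v) for v in self.log_initial_abundance],
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelState":
        space = SequenceSpace(d["space"]["alphabet"], d["space"]["length"])
        graph = SelectionGraph.from_doc(d["graph"])
        modes = [Mode(m["mode_id"], m["kind"]) for m in d["modes"]]
        energy_models = {
            w: EnergyModelBase.from_dict(md, space)
            for w, md in d["energy_models"].items()
        }
        mu = {(w, tie): float(v) for w, tie, v in d["mu"]}
        return cls(
            space=space,
            graph=graph,
            modes=modes,
            energy_models=energy_models,
            mu=mu,
            log_initial_abundance=np.asarray(d["log_initial_abundance"], dtype=float),
            training_meta=dict(d.get("training_meta", {})),
        )


def infer_initial_abundances(state: ModelState) -> np.ndarray:
    """Inferred initial-library frequencies (softmax of the fitted logits).

    Strictly positive for every sequence, including those with zero reads in
    every dataset; sums to 1.
    """
    return state.initial_frequencies()


# ---------------------------------------------------------------------------
# Fit configuration and report
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    seed: int = 0
    epochs: int = 100
    batch_size: int | None = 128
    learning_rate: float = 1e-3
    lam: float = 0.01
    energy_kind: str = "independent_site"
    hidden: int = 20
    activation: str = "tanh"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    init_abundance_from_counts: bool = True
    pseudocount: float = 0.5

    def validate(self) -> None:
        if self.epochs <= 0:
            raise FitConfigError(f"epochs must be positive, got {self.epochs}")
        if self.batch_size is not None and self.batch_size <= 0:
            raise FitConfigError(f"batch_size must be positive, got {self.batch_size}")
        if self.lam < 0:
            raise FitConfigError("lam must be non-negative")
        if self.learning_rate <= 0:
            raise FitConfigError("learning_rate must be positive")


@dataclass
class FitReport:
    """Per-epoch loss trace plus final diagnostics; reproducible given seed."""

    config: dict
    epoch_nll: list[float] = field(default_factory=list)
    epoch_holdout_nll: list[float] = field(default_factory=list)
    initial_nll: float = float("nan")
    final_nll: float = float("nan")
    param_norms: dict = field(default_factory=dict)
    converged: bool = False

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = ["epoch", "nll"] + (["holdout_nll"] if self.epoch_holdout_nll else [])
            fh.write("\t".join(cols) + "\n")
            for i, v in enumerate(self.epoch_nll):
                row = [str(i + 1), f"{v:.10g}"]
                if self.epoch_holdout_nll:
                    row.append(f"{self.epoch_holdout_nll[i]:.10g}")
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------

class _ParamPack:
    """Flat-vector view over (log_initial_abundance, free mu, energy params)."""

    def __init__(self, state: ModelState):
        self.state = state
        self.mu_keys = sorted(state.mu)
        self.mode_ids = sorted(state.energy_models)
        self.n_theta = state.space.size
        self.n_mu = len(self.mu_keys)
        self.n_energy = {
            w: state.energy_models[w].n_params for w in self.mode_ids
        }
        self.size = self.n_theta + self.n_mu + sum(self.n_energy.values())

    def get(self) -> np.ndarray:
        parts = [self.state.log_initial_abundance,
                 np.array([self.state.mu[k] for k in self.mu_keys])]
        for w in self.mode_ids:
            parts.append(self.state.energy_models[w].get_params())
        return np.concatenate(parts) if parts else np.zeros(0)

    def set(self, flat: np.ndarray) -> None:
        st = self.state
        st.log_initial_abundance = flat[: self.n_theta].copy()
        off = self.n_theta
        for i, k in enumerate(self.mu_keys):
            st.mu[k] = float(flat[off + i])
        off += self.n_mu
        for w in self.mode_ids:
            n = self.n_energy[w]
            st.energy_models[w].set_params(flat[off : off + n])
            off += n

    def reg_mask(self) -> np.ndarray:
        """1 where the L2 penalty applies (mu and energy params, not theta)."""
        m = np.ones(self.size)
        m[: self.n_theta] = 0.0
        return m


# ---------------------------------------------------------------------------
# Loss and gradient
# ---------------------------------------------------------------------------

class _GraphPlan:
    """Static per-node structure reused across every gradient step."""

    def __init__(self, state: ModelState, pack: _ParamPack):
        self.order = []
        mu_index = {k: i for i, k in enumerate(pack.mu_keys)}
        for node in state.graph:
            if node.is_root:
                continue
            modes = sorted(node.available)
            mask = np.array([w in node.selected for w in modes])
            mu_slots = []  # (column, flat mu-parameter index or None)
            for j, w in enumerate(modes):
                if w == UNBOUND or w in node.fixed_mu:
                    mu_slots.append((j, None))
                else:
                    mu_slots.append((j, mu_index[(w, node.tie_key())]))
            self.order.append((node, modes, mask, mu_slots))


def _forward_backward(
    state: ModelState,
    pack: _ParamPack,
    counts_dense: dict[str, np.ndarray],
    lam: float,
    batch_mask: np.ndarray | None = None,
    lam_scale: float = 1.0,
    want_grad: bool = True,
    plan: _GraphPlan | None = None,
) -> tuple[float, np.ndarray | None]:
    graph = state.graph
    space = state.space
    codes = space.codes
    N = space.size
    plan = plan or _GraphPlan(state, pack)

    energies = {w: state.energy_models[w].energies_codes(codes)
                for w in pack.mode_ids}
    energies[UNBOUND] = np.zeros(N)

    # forward: log frequencies through the DAG (stable fused softmax per node)
    lf: dict[str, np.ndarray] = {}
    cache: dict[str, tuple] = {}
    theta = state.log_initial_abundance
    mth = theta.max()
    lf[graph.root.node_id] = theta - (mth + np.log(np.sum(np.exp(theta - mth))))
    for node, modes, mask, _slots in plan.order:
        x = np.empty((N, len(modes)))
        for j, w in enumerate(modes):
            x[:, j] = state.mu_value(w, node) - energies[w]
        mx = x.max(axis=1)
        ex = np.exp(x - mx[:, None])
        s_all = ex.sum(axis=1)
        s_sel = ex[:, mask].sum(axis=1)
        logp = np.log(s_sel) - np.log(s_all)
        a = lf[node.parent] + logp
        ma = a.max()
        lf[node.node_id] = a - (ma + np.log(np.sum(np.exp(a - ma))))
        if want_grad:
            cache[node.node_id] = (ex, s_all, s_sel)

    masked_counts = {}
    for nid, R in counts_dense.items():
        Rm = R.astype(float)
        if batch_mask is not None:
            Rm = Rm * batch_mask
        masked_counts[nid] = Rm

    loss = 0.0
    for nid, Rm in masked_counts.items():
        loss -= float(Rm @ lf[nid])
    params = pack.get()
    rmask = pack.reg_mask()
    loss += lam_scale * lam * float(np.sum((params * rmask) ** 2))

    if not want_grad:
        return loss, None

    # backward through the log-frequency recursion
    g = {nid: np.zeros(N) for nid in graph.nodes}
    for nid, Rm in masked_counts.items():
        g[nid] -= Rm
    glogp: dict[str, np.ndarray] = {}
    for node, _modes, _mask, _slots in reversed(plan.order):
        gn = g[node.node_id]
        da = gn - gn.sum() * np.exp(lf[node.node_id])
        g[node.parent] += da
        glogp[node.node_id] = da

    grad = np.zeros(pack.size)
    groot = g[graph.root.node_id]
    grad[: pack.n_theta] = groot - groot.sum() * np.exp(lf[graph.root.node_id])

    # backward through Eq 1 into mu and energies
    dE = {w: np.zeros(N) for w in pack.mode_ids}
    for node, modes, mask, slots in plan.order:
        ex, s_all, s_sel = cache[node.node_id]
        gp = glogp[node.node_id]
        coef_sel = gp / s_sel
        coef_all = gp / s_all
        for (j, mu_slot), w in zip(slots, modes):
            dxj = ex[:, j] * ((coef_sel if mask[j] else 0.0) - coef_all)
            if w != UNBOUND:
                dE[w] -= dxj
            if mu_slot is not None:
                grad[pack.n_theta + mu_slot] += dxj.sum()

    off = pack.n_theta + pack.n_mu
    for w in pack.mode_ids:
        n = pack.n_energy[w]
        grad[off : off + n] = state.energy_models[w].backprop_codes(codes, dE[w])
        off += n

    grad += 2.0 * lam_scale * lam * params * rmask
    return loss, grad


def negative_log_likelihood(
    state: ModelState, graph: SelectionGraph, counts, lam: float = 0.0
) -> float:
    """Regularized multinomial NLL of read counts under the model.

    The constant multinomial coefficient is omitted.  ``counts`` maps node ids
    to :class:`~bindmode.data_io.CountTable` or dense count vectors.
    """
    counts_dense = densify_counts(counts, state.space, graph)
    if state.graph is not graph:
        state = ModelState(
            space=state.space, graph=graph, modes=state.modes,
            energy_models=state.energy_models, mu=state.mu,
            log_initial_abundance=state.log_initial_abundance,
            training_meta=state.training_meta,
        )
    pack = _ParamPack(state)
    loss, _ = _forward_backward(
        state, pack, counts_dense, lam, want_grad=False
    )
    return loss


def nll_gradient(state: ModelState, counts, lam: float = 0.0) -> np.ndarray:
    """Exact gradient of the regularized NLL in flat-parameter order."""
    counts_dense = densify_counts(counts, state.space, state.graph)
    pack = _ParamPack(state)
    _, grad = _forward_backward(state, pack, counts_dense, lam)
    return grad


def densify_counts(counts, space: SequenceSpace, graph: SelectionGraph):
    out = {}
    for nid, table in counts.items():
        if nid not in graph:
            raise FitConfigError(f"counts for unknown node {nid!r}")
        out[nid] = (
            table.dense(space) if hasattr(table, "dense") else np.asarray(table)
        )
        if out[nid].shape != (space.size,):
            raise FitConfigError(f"counts for {nid!r} do not match the space")
    return out


# ---------------------------------------------------------------------------
# Fit
# ---------------------------------------------------------------------------

def initialize_state(
    graph: SelectionGraph,
    space: SequenceSpace,
    config: FitConfig,
    root_counts: np.ndarray | None = None,
) -> ModelState:
    rng = np.random.default_rng(config.seed)
    mode_ids = graph.mode_ids()
    modes = [Mode(UNBOUND, "unbound")] + [
        Mode(w, "pseudo" if w.startswith("pseudo") else "binding")
        for w in mode_ids
    ]
    energy_models = {
        w: make_energy_model(
            config.energy_kind, w, space,
            hidden=config.hidden, activation=config.activation, rng=rng,
        )
        for w in mode_ids
    }
    mu: dict[tuple[str, str], float] = {}
    for node in graph:
        if node.is_root:
            continue
        for w in sorted(node.available):
            if w == UNBOUND or w in node.fixed_mu:
                continue
            mu.setdefault((w, node.tie_key()), 0.0)
    if root_counts is not None and config.init_abundance_from_counts:
        theta = np.log(root_counts.astype(float) + config.pseudocount)
        theta -= theta.mean()
    else:
        theta = np.zeros(space.size)
    return ModelState(
        space=space, graph=graph, modes=modes, energy_models=energy_models,
        mu=mu, log_initial_abundance=theta,
        training_meta={"seed": config.seed},
    )


def fit(
    graph: SelectionGraph,
    counts,
    space: SequenceSpace,
    config: FitConfig | None = None,
    holdout_counts=None,
) -> tuple[ModelState, FitReport]:
    """Fit energies, chemical potentials and initial abundances by Adam.

    ``counts`` maps node ids (including the root library) to count tables or
    dense vectors.  Mini-batches partition the sequence axis and are
    re-shuffled each epoch; randomness is fully determined by ``config.seed``.
    ``holdout_counts``, if given, is evaluated (not trained on) each epoch.
    """
    config = config or FitConfig()
    config.validate()
    counts_dense = densify_counts(counts, space, graph)
    root_id = graph.root.node_id
    if root_id not in counts_dense:
        raise FitConfigError(f"root library counts ({root_id!r}) are required")
    if not any(nid != root_id for nid in counts_dense):
        raise FitConfigError("counts for at least one selection node are required")

    state = initialize_state(graph, space, config, counts_dense.get(root_id))
    pack = _ParamPack(state)
    plan = _GraphPlan(state, pack)
    params = pack.get()

    holdout_dense = (
        densify_counts(holdout_counts, space, graph) if holdout_counts else None
    )

    def full_nll(p):
        pack.set(p)
        loss, _ = _forward_backward(
            state, pack, counts_dense, config.lam, want_grad=False, plan=plan
        )
        return loss

    report = FitReport(config=asdict(config))
    report.initial_nll = full_nll(params)

    rng = np.random.default_rng(config.seed)
    N = space.size
    m = np.zeros_like(params)
    v = np.zeros_like(params)
    step = 0
    last_finite = params.copy()
    for _epoch in range(config.epochs):
        if config.batch_size is None:
            batches = [None]
        else:
            perm = rng.permutation(N)
            batches = [
                perm[i : i + config.batch_size]
                for i in range(0, N, config.batch_size)
            ]
        for batch in batches:
            if batch is None:
                mask, lam_scale = None, 1.0
            else:
                mask = np.zeros(N)
                mask[batch] = 1.0
                lam_scale = len(batch) / N
            pack.set(params)
            loss, grad = _forward_backward(
                state, pack, counts_dense, config.lam, mask, lam_scale, plan=plan
            )
            if not np.isfinite(loss):
                pack.set(last_finite)
                raise FitDivergedError(
                    f"non-finite loss at step {step}", last_state=state
                )
            last_finite = params.copy()
            step += 1
            m = config.adam_beta1 * m + (1 - config.adam_beta1) * grad
            v = config.adam_beta2 * v + (1 - config.adam_beta2) * grad**2
            mhat = m / (1 - config.adam_beta1**step)
            vhat = v / (1 - config.adam_beta2**step)
            params = params - config.learning_rate * mhat / (
                np.sqrt(vhat) + config.adam_eps
            )
        epoch_nll = full_nll(params)
        if not np.isfinite(epoch_nll):
            pack.set(last_finite)
            raise FitDivergedError(
                f"non-finite NLL after epoch {_epoch + 1}", last_state=state
            )
        report.epoch_nll.append(epoch_nll)
        if holdout_dense is not None:
            hloss, _ = _forward_backward(
                state, pack, holdout_dense, 0.0, want_grad=False, plan=plan
            )
            report.epoch_holdout_nll.append(hloss)

    pack.set(params)
    report.final_nll = report.epoch_nll[-1]
    report.converged = report.final_nll < report.initial_nll
    if not report.converged:
        warnings.warn("fit did not improve on the initialization NLL")
    report.param_norms = {
        "log_initial_abundance": float(np.linalg.norm(state.log_initial_abundance)),
        "mu": float(np.linalg.norm(list(state.mu.values()) or [0.0])),
        **{
            f"energy[{w}]": float(np.linalg.norm(em.get_params()))
            for w, em in state.energy_models.items()
        },
    }
    state.training_meta.update(
        {
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "lam": config.lam,
            "learning_rate": config.learning_rate,
            "energy_kind": config.energy_kind,
            "final_nll": report.final_nll,
        }
    )
    return state, report


# ---------------------------------------------------------------------------
# Holdout utilities
# ---------------------------------------------------------------------------

def abundance_stratified_split(
    counts, space: SequenceSpace, graph: SelectionGraph, top_fraction: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Train on the lowest-count sequences, hold out the most abundant ones.

    Sequences are ranked by their total read count over all datasets; the top
    ``top_fraction`` form the held-out set (boolean masks returned as
    ``(train, test)``).  Ties at the boundary resolve by enumeration index.
    """
    dense = densify_counts(counts, space, graph)
    total = np.sum([v for v in dense.values()], axis=0)
    n_test = int(round(top_fraction * space.size))
    order = np.lexsort((np.arange(space.size), -total))
    test = np.zeros(space.size, dtype=bool)
    test[order[:n_test]] = True
    return ~test, test


def mask_counts(counts, space: SequenceSpace, graph: SelectionGraph, keep_mask):
    """Zero out counts of held-out sequences (they leave the likelihood)."""
    dense = densify_counts(counts, space, graph)
    return {nid: v * keep_mask for nid, v in dense.items()}
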