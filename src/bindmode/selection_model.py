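"""Multi-mode selection probabilities and abundance propagation.

A variant ``s`` in experiment ``t`` can occupy one of several thermodynamic
*modes*: bound to a specific ligand, bound to the bead surface, an optional
non-binding pseudo mode (production/expression biases), or unbound in
solution.  Each mode ``w`` carries a sequence energy ``E_ws`` (RT units) and a
per-experiment chemical potential ``mu_wt`` (log relative free-ligand
concentration).  The probability of being selected is the Boltzmann weight of
the selected modes among all available modes::

    p_st = sum_{w in S_t} exp(mu_wt - E_ws) / sum_{w in S_t ∪ N_t} exp(mu_wt - E_ws)

Selections chain: library abundances evolve between consecutive experiments as
``N_st' ∝ p_st N_st``, which this module propagates through the experiment DAG
(bead pre-selections feeding round-1 nodes feeding round-2 nodes).

Gauge freedoms of the formula (a uniform shift of all ``mu_wt`` within a node;
a joint shift of one mode's ``mu`` and ``E``) leave every ``p_st`` unchanged;
the fit fixes them by pinning the unbound mode at ``E ≡ 0, mu ≡ 0`` and
L2-anchoring binding-mode energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import logsumexp

UNBOUND = "unbound"

MODE_KINDS = ("binding", "pseudo", "unbound")


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class Mode:
    """A thermodynamic state available to a displayed antibody."""

    mode_id: str
    kind: str = "binding"

    def __post_init__(self) -> None:
        if self.kind not in MODE_KINDS:
            raise GraphError(f"unknown mode kind {self.kind!r}")
        if (self.kind == "unbound") != (self.mode_id == UNBOUND):
            raise GraphError("the unbound mode must be named 'unbound'")


@dataclass(frozen=True)
class ExperimentNode:
    """One sequencing dataset / selection step in the campaign DAG.

    ``selected`` (S_t) and ``unselected`` (N_t) are the mode sets available in
    the experiment; the unbound mode is always in N_t for selection nodes.
    ``fixed_mu`` pins chemical potentials declared known (e.g. from relative
    ligand concentrations); all other available modes get free mu parameters,
    shared across nodes with equal ``mu_tie`` keys (default: untied, one per
    node).
    """

    node_id: str
    parent: str | None
    selected: frozenset = frozenset()
    unselected: frozenset = frozenset({UNBOUND})
    fixed_mu: dict = field(default_factory=dict)
    mu_tie: str | None = None
    counts_file: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected", frozenset(self.selected))
        object.__setattr__(self, "unselected", frozenset(self.unselected))
        if self.parent is None:
            # the root library undergoes no selection and carries no modes
            object.__setattr__(self, "selected", frozenset())
            object.__setattr__(self, "unselected", frozenset())
        if self.parent is not None:
            if self.selected & self.unselected:
                raise GraphError(f"{self.node_id}: S_t and N_t overlap")
            if not (self.selected | self.unselected):
                raise GraphError(f"{self.node_id}: no modes available")
            if UNBOUND not in self.unselected:
                raise GraphError(f"{self.node_id}: unbound mode must be in N_t")
        for m in self.fixed_mu:
            if m not in self.selected | self.unselected:
                raise GraphError(f"{self.node_id}: fixed mu for unavailable mode {m}")

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def available(self) -> frozenset:
        return self.selected | self.unselected

    def tie_key(self) -> str:
        return self.mu_tie if self.mu_tie is not None else self.node_id


class SelectionGraph:
    """A rooted tree of experiments (each dataset has one upstream dataset)."""

    def __init__(self, nodes):
        self.nodes: dict[str, ExperimentNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise GraphError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node
        roots = [n for n in self.nodes.values() if n.is_root]
        if len(roots) != 1:
            raise GraphError(f"expected exactly one root node, found {len(roots)}")
        self._root = roots[0]
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise GraphError(f"{node.node_id}: unknown parent {node.parent!r}")
        self._order = self._toposort()

    @property
    def root(self) -> ExperimentNode:
        return self._root

    def _toposort(self) -> list[str]:
        order, seen = [], set()

        def visit(nid, trail):
            if nid in trail:
                raise GraphError(f"cycle through node {nid!r}")
            if nid in seen:
                return
            node = self.nodes[nid]
            if node.parent is not None:
                visit(node.parent, trail | {nid})
            seen.add(nid)
            order.append(nid)

        for nid in self.nodes:
            visit(nid, frozenset())
        return order

    def topological_order(self) -> list[str]:
        return list(self._order)

    def __iter__(self):
        return (self.nodes[nid] for nid in self._order)

    def __getitem__(self, node_id: str) -> ExperimentNode:
        return self.nodes[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def mode_ids(self) -> list[str]:
        """All mode ids appearing in the graph (unbound excluded), sorted."""
        ids = set()
        for node in self.nodes.values():
            ids |= node.available
        ids.discard(UNBOUND)
        return sorted(ids)

    def subgraph(self, keep) -> "SelectionGraph":
        """Restriction to ``keep`` node ids; ancestors are added as needed."""
        keep = set(keep)
        for nid in list(keep):
            node = self.nodes[nid]
            while node.parent is not None:
                keep.add(node.parent)
                node = self.nodes[node.parent]
        return SelectionGraph([self.nodes[nid] for nid in self._order if nid in keep])

    # -- config file --------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "SelectionGraph":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_doc(doc)

    @classmethod
    def from_doc(cls, doc: dict) -> "SelectionGraph":
        nodes = []
        for entry in doc["nodes"]:
            nodes.append(
                ExperimentNode(
                    node_id=entry["id"],
                    parent=entry.get("parent"),
                    selected=frozenset(entry.get("selected", [])),
                    unselected=frozenset(entry.get("unselected", [UNBOUND]))
                    if entry.get("parent") is not None
                    else frozenset(),
                    fixed_mu={k: float(v) for k, v in (entry.get("fixed_mu") or {}).items()},
                    mu_tie=entry.get("mu_tie"),
                    counts_file=entry.get("counts"),
                )
            )
        return cls(nodes)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_doc(), fh, sort_keys=False)

    def to_doc(self) -> dict:
        doc = {"nodes": []}
        for node in self:
            entry: dict = {"id": node.node_id}
            if node.parent is not None:
                entry["parent"] = node.parent
                entry["selected"] = sorted(node.selected)
                entry["unselected"] = sorted(node.unselected)
            if node.fixed_mu:
                entry["fixed_mu"] = dict(node.fixed_mu)
            if node.mu_tie is not None:
                entry["mu_tie"] = node.mu_tie
            if node.counts_file is not None:
                entry["counts"] = node.counts_file
            doc["nodes"].append(entry)
        return doc


# ---------------------------------------------------------------------------
# Eq-1 numerics
# ---------------------------------------------------------------------------

def node_log_selection_probability(
    x: np.ndarray, selected_mask: np.ndarray
) -> np.ndarray:
    """``log p`` for a node, from ``x[s, w] = mu_wt - E_ws`` over available modes.

    Computed as ``logsumexp(x[selected]) - logsumexp(x[all])`` with per-row max
    subtraction, which is stable for any finite x.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite mu - E input to selection probability")
    selected_mask = np.asarray(selected_mask, dtype=bool)
    if not selected_mask.any():
        warnings.warn("empty selected-mode set: p = 0 by convention")
        return np.full(x.shape[0], -np.inf)
    log_num = logsumexp(x[:, selected_mask], axis=1)
    log_den = logsumexp(x, axis=1)
    return log_num - log_den


def node_log_p_backward(
    x: np.ndarray, selected_mask: np.ndarray, grad_logp: np.ndarray
) -> np.ndarray:
    """Gradient of ``sum(grad_logp * log p)`` w.r.t. ``x``.

    ``d log p_s / d x_sw = [w in S] softmax_S(x_s)_w - softmax_all(x_s)_w``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    selected_mask = np.asarray(selected_mask, dtype=bool)
    m = x.max(axis=1, keepdims=True)
    ex = np.exp(x - m)
    p_all = ex / ex.sum(axis=1, keepdims=True)
    ex_sel = ex * selected_mask[None, :]
    p_sel = ex_sel / ex_sel.sum(axis=1, keepdims=True)
    return grad_logp[:, None] * (p_sel - p_all)


def selection_probability(energies: dict, node: ExperimentNode, mu: dict) -> float:
    """Eq-1 probability for a single sequence.

    ``energies`` and ``mu`` map mode ids to values; the unbound mode defaults
    to ``E = 0, mu = 0`` when omitted.
    """
    modes = sorted(node.available)
    e = {UNBOUND: 0.0, **energies}
    m = {UNBOUND: 0.0, **mu}
    x = np.array([[m[w] - e[w] for w in modes]])
    for w in modes:
        if not np.isfinite(e[w]):
            raise ValueError(f"non-finite energy for mode {w}")
    mask = np.array([w in node.selected for w in modes])
    return float(np.exp(node_log_selection_probability(x, mask)[0]))


# ---------------------------------------------------------------------------
# Propagation through the DAG
# ---------------------------------------------------------------------------

def node_mu_energy_matrix(node: ExperimentNode, state) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack ``mu_wt - E_ws`` for the available modes of a node.

    Returns ``(x, selected_mask, mode_order)`` with ``x`` of shape
    ``(space.size, n_available)``; the unbound mode contributes a zero column.
    """
    modes = sorted(node.available)
    cols = []
    for w in modes:
        e = state.mode_energies(w)
        cols.append(state.mu_value(w, node) - e)
    x = np.stack(cols, axis=1)
    mask = np.array([w in node.selected for w in modes])
    return x, mask, modes


def log_selection_probabilities(node: ExperimentNode, state) -> np.ndarray:
    """``log p_st`` for every sequence of the space at a node."""
    x, mask, _ = node_mu_energy_matrix(node, state)
    return node_log_selection_probability(x, mask)


def predicted_enrichment(graph: SelectionGraph, state, node_id: str) -> np.ndarray:
    """Model enrichment at a node: ``p_st`` per sequence (enumeration order).

    ``p_st`` is proportional to the expected child/parent frequency ratio
    across the node (the propagation rule divides by one global normalizer per
    node), so correlations on log values are unaffected by the normalizer.
    """
    if node_id not in graph:
        raise GraphError(f"unknown node {node_id!r}")
    node = graph[node_id]
    if node.is_root:
        raise GraphError("the root library node has no enrichment")
    return np.exp(log_selection_probabilities(node, state))


def propagate_abundances(graph: SelectionGraph, state) -> dict[str, np.ndarray]:
    """Frequencies of every sequence at every node, in topological order.

    Root frequencies are the softmax of the log-initial-abundance parameters;
    each child's frequencies are the parent's times ``p_st``, renormalized.
    Bead pre-selection datasets are plain nodes (observations of bead-bound
    phages); depletion being only partial, the pool entering the main
    selection is modeled as the parent pool itself.
    """
    log_freqs = propagate_log_frequencies(graph, state)
    return {nid: np.exp(lf) for nid, lf in log_freqs.items()}


def propagate_log_frequencies(graph: SelectionGraph, state) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for node in graph:
        if node.is_root:
            theta = state.log_initial_abundance
            out[node.node_id] = theta - logsumexp(theta)
        else:
            a = out[node.parent] + log_selection_probabilities(node, state)
            norm = logsumexp(a)
            if not np.isfinite(norm):
                raise GraphError(f"all-zero survival at node {node.node_id!r}")
            out[node.node_id] = a - norm
    return out


def make_mixture_node(
    node_id: str,
    parent: str,
    component_nodes: list[ExperimentNode],
    state,
    mix_modes: dict[str, str],
    proportions: dict[str, float] | None = None,
) -> ExperimentNode:
    """Construct a prediction node for a mixture of ligand complexes.

    ``mix_modes`` maps each ligand mode to the component node whose fitted mu
    it inherits; with ``mu = ln[ligand]`` and the components mixed at the given
    proportions (default equal), each inherited mu is shifted by
    ``ln(proportion)`` (``-ln 2`` for a 50-50 mix).
    """
    by_id = {n.node_id: n for n in component_nodes}
    selected: set[str] = set()
    fixed: dict[str, float] = {}
    n_comp = len(set(mix_modes.values()))
    for mode, comp_id in mix_modes.items():
        comp = by_id[comp_id]
        prop = (proportions or {}).get(mode, 1.0 / n_comp)
        fixed[mode] = float(state.mu_value(mode, comp)) + float(np.log(prop))
        selected.add(mode)
    for comp in component_nodes:
        for w in comp.selected - set(mix_modes):
            selected.add(w)
            fixed[w] = float(state.mu_value(w, comp))
    return ExperimentNode(
        node_id=node_id,
        parent=parent,
        selected=frozenset(selected),
        unselected=frozenset({UNBOUND}),
        fixed_mu=fixed,
    )
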