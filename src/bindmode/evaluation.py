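"""Empirical enrichments and model-vs-data comparisons.

The empirical enrichment of a sequence across one selection step is the raw
ratio of its read counts after vs before, ``eps_st = R_st' / R_st``; model
predictions (selection probabilities ``p_st``) are proportional to expected
frequency ratios, so the two are compared by Pearson correlation on log
values.  This module also bundles the standard control analyses of a
campaign: single-mode ablation, amplification-bias and codon-bias checks, and
a comparison of energy parameterizations under a common holdout.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .data_io import CountTable
from .inference import FitConfig, ModelState, densify_counts, fit
from .selection_model import (
    UNBOUND,
    ExperimentNode,
    SelectionGraph,
    log_selection_probabilities,
)
from .space import SequenceSpace

ENRICHMENT_POLICIES = ("drop", "pseudocount", "frequency")


class EvaluationError(ValueError):
    pass


def empirical_enrichment(
    parent: CountTable,
    child: CountTable,
    space: SequenceSpace,
    policy: str = "drop",
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Per-sequence empirical enrichment between two count tables.

    Policies: ``drop`` (raw ratio; sequences with zero parent count are
    excluded), ``pseudocount`` (add ``alpha`` to both counts), ``frequency``
    (ratio of frequencies, invariant to sequencing depth).  The applied policy
    is recorded in the frame's attrs.  Only sequences observed in at least one
    of the two tables are returned.
    """
    if policy not in ENRICHMENT_POLICIES:
        raise EvaluationError(f"unknown policy {policy!r}")
    if parent.total_reads == 0:
        raise EvaluationError("parent table is empty")
    rp = parent.dense(space).astype(float)
    rc = child.dense(space).astype(float)
    seen = (rp > 0) | (rc > 0)
    idx = np.nonzero(seen)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        if policy == "drop":
            eps = np.where(rp > 0, rc / np.where(rp > 0, rp, 1.0), np.nan)
        elif policy == "pseudocount":
            eps = (rc + alpha) / (rp + alpha)
        else:
            eps = (rc / rc.sum()) / np.where(rp > 0, rp / rp.sum(), np.nan)
    df = pd.DataFrame(
        {
            "sequence": [space.sequence(int(i)) for i in idx],
            "index": idx,
            "parent_count": rp[idx].astype(int),
            "child_count": rc[idx].astype(int),
            "enrichment": eps[idx],
        }
    )
    if policy == "drop":
        df = df[df.parent_count > 0].reset_index(drop=True)
    df.attrs["policy"] = policy
    df.attrs["alpha"] = alpha
    return df


def correlate_predictions(
    predicted: np.ndarray,
    empirical: np.ndarray,
    min_parent_count: int = 1,
    parent_counts: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson r (and Student-t p-value) between log enrichment and log p.

    Invariant to rescaling the predictions by any positive constant (a log
    shift).  Pairs with non-finite or non-positive values are dropped; fewer
    than 3 surviving pairs is an error.
    """
    predicted = np.asarray(predicted, dtype=float)
    empirical = np.asarray(empirical, dtype=float)
    if predicted.shape != empirical.shape:
        raise EvaluationError("prediction/observation length mismatch")
    keep = (
        np.isfinite(predicted) & np.isfinite(empirical)
        & (predicted > 0) & (empirical > 0)
    )
    if parent_counts is not None:
        keep &= np.asarray(parent_counts) >= min_parent_count
    if keep.sum() < 3:
        raise EvaluationError(f"only {int(keep.sum())} valid pairs; need >= 3")
    res = pearsonr(np.log(predicted[keep]), np.log(empirical[keep]))
    return {"r": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(keep.sum())}


def masked_node(node: ExperimentNode, allowed_modes: set[str]) -> ExperimentNode:
    """Restrict a node's mode sets to ``allowed_modes`` (unbound always kept)."""
    selected = frozenset(node.selected & allowed_modes)
    unselected = frozenset((node.unselected & allowed_modes) | {UNBOUND})
    fixed = {w: v for w, v in node.fixed_mu.items() if w in selected | unselected}
    return replace(node, selected=selected, unselected=unselected, fixed_mu=fixed)


def single_mode_ablation(
    state: ModelState,
    eval_node: ExperimentNode,
    empirical: np.ndarray,
    parent_counts: np.ndarray | None = None,
    mode_subsets: list[set[str]] | None = None,
    min_parent_count: int = 1,
) -> pd.DataFrame:
    """Correlation with observed enrichment per allowed-mode subset.

    Default subsets: the full selected-mode set of the node, then each
    selected mode alone (re-prediction with masked modes from the same fitted
    state — no refit).  A mode absent from the node's available set leaves
    predictions unchanged by construction.
    """
    if mode_subsets is None:
        full = set(state.energy_models) | {UNBOUND}
        mode_subsets = [full] + [
            {w, UNBOUND} for w in sorted(eval_node.selected)
        ]
    rows = []
    for subset in mode_subsets:
        node = masked_node(eval_node, set(subset))
        if not node.selected:
            warnings.warn(f"subset {subset} selects nothing at {eval_node.node_id}")
            continue
        pred = np.exp(log_selection_probabilities(node, state))
        stats = correlate_predictions(
            pred, empirical, min_parent_count, parent_counts
        )
        label = "+".join(sorted(w for w in subset if w != UNBOUND))
        rows.append({"modes": label, **stats})
    return pd.DataFrame(rows)


def check_amplification_bias(
    before: CountTable,
    after: CountTable,
    space: SequenceSpace,
    overdispersion_threshold: float = 3.0,
    max_z_threshold: float = 6.0,
) -> dict[str, float | bool]:
    """Compare counts across an amplification step that should be neutral.

    Reports the Pearson correlation of log counts on sequences present in
    both tables, and an overdispersion index: the variance of centered log
    frequency ratios divided by their Poisson sampling expectation
    ``1/R_before + 1/R_after``.  Pure resampling gives an index near 1; the
    flag raises when the index or the largest per-sequence z-score exceeds
    its threshold.
    """
    rb = before.dense(space).astype(float)
    ra = after.dense(space).astype(float)
    both = (rb > 0) & (ra > 0)
    if not both.any():
        raise EvaluationError("no sequence observed in both tables")
    rb, ra = rb[both], ra[both]
    if both.sum() >= 3 and np.std(rb) > 0 and np.std(ra) > 0:
        r = float(pearsonr(np.log(rb), np.log(ra)).statistic)
    else:
        r = float("nan")
    log_ratio = np.log(ra / ra.sum()) - np.log(rb / rb.sum())
    log_ratio = log_ratio - log_ratio.mean()
    expected_var = 1.0 / rb + 1.0 / ra
    z = log_ratio / np.sqrt(expected_var)
    overdispersion = float(np.mean(log_ratio**2) / np.mean(expected_var))
    max_z = float(np.max(np.abs(z)))
    return {
        "n_common": int(both.sum()),
        "log_count_pearson": r,
        "overdispersion": overdispersion,
        "max_abs_z": max_z,
        "dispersion_sd": float(np.std(log_ratio)),
        "flag": overdispersion > overdispersion_threshold
        or max_z > max_z_threshold,
    }


def codon_vs_aa_enrichment(
    codon_parent: CountTable,
    codon_child: CountTable,
    genetic_code: dict[str, str],
    within_to_between_threshold: float = 0.5,
) -> dict:
    """Test whether synonymous codon variants enrich like their amino acids.

    For each amino-acid variant with at least two synonymous codon variants
    observed before and after selection, the log enrichments of its synonyms
    are compared.  If selection acts on the protein only, within-group spread
    reflects sampling noise and is small relative to the between-variant
    spread of amino-acid enrichments; the flag raises when the pooled
    within-group standard deviation exceeds ``threshold`` times the between
    spread.  Amino-acid enrichments are exactly the count-weighted aggregates
    of their synonymous codon counts.
    """

    def translate(nt: str) -> str | None:
        aas = [genetic_code.get(nt[i : i + 3]) for i in range(0, len(nt), 3)]
        if None in aas or "*" in aas:
            return None
        return "".join(aas)

    groups: dict[str, list[tuple[float, float]]] = {}
    for nt, cb in codon_parent.counts.items():
        ca = codon_child.count(nt)
        if cb > 0 and ca > 0:
            aa = translate(nt)
            if aa is not None:
                groups.setdefault(aa, []).append((cb, ca))

    within_sq, within_n, aa_logeps = [], 0, []
    for aa, pairs in groups.items():
        cb = np.array([p[0] for p in pairs], dtype=float)
        ca = np.array([p[1] for p in pairs], dtype=float)
        aa_logeps.append(np.log(ca.sum() / cb.sum()))
        if len(pairs) >= 2:
            le = np.log(ca / cb)
            within_sq.extend((le - le.mean()) ** 2)
            within_n += len(pairs) - 1
    if not aa_logeps:
        raise EvaluationError("no amino-acid group observed in both tables")
    between_sd = float(np.std(aa_logeps))
    within_sd = (
        float(np.sqrt(np.sum(within_sq) / within_n)) if within_n else 0.0
    )
    ratio = within_sd / between_sd if between_sd > 0 else float("inf")
    return {
        "n_groups": len(groups),
        "n_groups_multi_codon": sum(len(p) >= 2 for p in groups.values()),
        "within_sd": within_sd,
        "between_sd": between_sd,
        "within_to_between": ratio,
        "flag": within_n > 0 and between_sd > 0
        and ratio > within_to_between_threshold,
    }


def compare_parameterizations(
    graph: SelectionGraph,
    counts,
    space: SequenceSpace,
    eval_node_id: str,
    kinds: list[str],
    config: FitConfig | None = None,
    holdout_fraction: float = 0.1,
) -> pd.DataFrame:
    """Held-out correlation per energy-model parameterization.

    A seeded random fraction of sequences is removed from every training
    likelihood term (identical split for every kind); each kind is then fitted
    and its predicted enrichment at ``eval_node_id`` is correlated with the
    empirical enrichment of the held-out sequences.
    """
    if len(kinds) < 2:
        raise EvaluationError("need at least two parameterizations to compare")
    base = config or FitConfig()
    dense = densify_counts(counts, space, graph)
    rng = np.random.default_rng(base.seed)
    heldout = rng.random(space.size) < holdout_fraction
    train_counts = {nid: v * (~heldout) for nid, v in dense.items()}

    node = graph[eval_node_id]
    parent_c = dense[node.parent].astype(float)
    child_c = dense[eval_node_id].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(parent_c > 0, child_c / np.where(parent_c > 0, parent_c, 1), np.nan)
    sel = heldout & (parent_c > 0) & (child_c > 0)

    rows = []
    for kind in kinds:
        cfg = replace(base, energy_kind=kind)
        state, _ = fit(graph, train_counts, space, cfg)
        pred = np.exp(log_selection_probabilities(node, state))
        stats = correlate_predictions(
            np.where(sel, pred, np.nan), np.where(sel, eps, np.nan)
        )
        rows.append({"kind": kind, **stats})
    return pd.DataFrame(rows)
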