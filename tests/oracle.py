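"""Independent brute-force reference for selection probabilities and the NLL.

Deliberately written with plain Python loops and ``math`` only, sharing no
code with the package: it recomputes the Boltzmann selection probability, the
frequency propagation and the regularized multinomial NLL directly from their
definitions, for tiny problems.
"""

import math


def oracle_selection_probability(mu_sel, e_sel, mu_unsel, e_unsel):
    """p = sum_S exp(mu-E) / (sum_S exp(mu-E) + sum_N exp(mu-E))."""
    num = sum(math.exp(m - e) for m, e in zip(mu_sel, e_sel))
    den = num + sum(math.exp(m - e) for m, e in zip(mu_unsel, e_unsel))
    return num / den


def oracle_frequencies(nodes, theta, energies, mu):
    """Frequencies per node by direct propagation.

    nodes: list of dicts {id, parent (None for root), selected: [mode...],
    unselected: [mode...]} in an order where parents precede children.
    theta: list of log initial abundances.  energies: mode -> list per
    sequence (the unbound mode need not be listed; E = 0).  mu: (mode, node
    id) -> value (unbound implicit 0).
    """
    n = len(theta)
    z = sum(math.exp(t) for t in theta)
    freqs = {}
    for node in nodes:
        if node["parent"] is None:
            freqs[node["id"]] = [math.exp(t) / z for t in theta]
            continue
        parent = freqs[node["parent"]]
        child = []
        for s in range(n):
            num = 0.0
            den = 0.0
            for w in node["selected"]:
                e = 0.0 if w == "unbound" else energies[w][s]
                m = 0.0 if w == "unbound" else mu[(w, node["id"])]
                num += math.exp(m - e)
            den = num
            for w in node["unselected"]:
                e = 0.0 if w == "unbound" else energies[w][s]
                m = 0.0 if w == "unbound" else mu[(w, node["id"])]
                den += math.exp(m - e)
            child.append(parent[s] * num / den)
        total = sum(child)
        freqs[node["id"]] = [c / total for c in child]
    return freqs


def oracle_nll(nodes, theta, energies, mu, counts, lam, reg_params):
    """-sum_t sum_s R_st log f_st + lam * sum(reg_params^2)."""
    freqs = oracle_frequencies(nodes, theta, energies, mu)
    nll = 0.0
    for node_id, r in counts.items():
        f = freqs[node_id]
        for s, c in enumerate(r):
            if c:
                nll -= c * math.log(f[s])
    nll += lam * sum(p * p for p in reg_params)
    return nll


def oracle_fisher_greater(a, b, c, d):
    """One-sided (greater) Fisher exact p by hypergeometric enumeration.

    For the 2x2 table [[a, b], [c, d]]: probability of >= a successes in a
    sample of a+b from a population of a+b+c+d containing a+c successes.
    """
    n = a + b + c + d
    K = a + c  # successes in population
    m = a + b  # sample size
    p = 0.0
    for k in range(a, min(K, m) + 1):
        p += (
            math.comb(K, k) * math.comb(n - K, m - k) / math.comb(n, m)
        )
    return min(p, 1.0)
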