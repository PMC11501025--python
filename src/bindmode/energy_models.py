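"""Sequence-to-energy maps for binding modes.

Each binding mode ``w`` assigns every sequence ``s`` a free energy ``E_ws`` in
RT units (lower = stronger binding); selection probabilities only ever use
``mu - E`` differences, so no absolute temperature appears anywhere.  Two
interchangeable parameterizations are provided:

* :class:`IndependentSiteModel` — additive per-position, per-letter fields
  ``h[i][a]``; 20·L parameters.
* :class:`ShallowDenseModel` — a one-hidden-layer dense network on the one-hot
  encoding, able to capture inter-site couplings.

Both evaluate exhaustively over an enumerated :class:`~bindmode.space.SequenceSpace`
and expose analytic backpropagation of per-sequence energy gradients into
parameter gradients, which is what the likelihood fit consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .space import SequenceSpace, codes_of

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


class EnergyModelError(ValueError):
    pass


class EnergyModelBase:
    """Common surface: evaluate energies and backpropagate their gradients."""

    kind: str
    mode_id: str
    space: SequenceSpace

    # -- evaluation ---------------------------------------------------------
    def energies_codes(self, codes: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def energy(self, sequence: str) -> float:
        """Energy of one sequence (RT units)."""
        return float(self.energies_codes(self.space.encode(sequence)[None, :])[0])

    def energies_over_space(self, cap: int | None = None) -> np.ndarray:
        """Energies of every sequence, in enumeration order."""
        from .space import DEFAULT_ENUMERATION_CAP

        cap = DEFAULT_ENUMERATION_CAP if cap is None else cap
        if self.space.size > cap:
            raise EnergyModelError(
                f"space size {self.space.size} exceeds cap {cap}; "
                "evaluate on a subsample instead"
            )
        return self.energies_codes(self.space.codes)

    def energies(self, sequences) -> np.ndarray:
        return self.energies_codes(codes_of(self.space, list(sequences)))

    # -- parameters as a flat vector (optimizer interface) ------------------
    def get_params(self) -> np.ndarray:
        raise NotImplementedError

    def set_params(self, flat: np.ndarray) -> None:
        raise NotImplementedError

    def backprop_codes(self, codes: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        """Gradient of ``sum(grad_out * E)`` w.r.t. the flat parameter vector."""
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return self.get_params().size

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict, space: SequenceSpace) -> "EnergyModelBase":
        kind = d.get("kind")
        if kind == "independent_site":
            m = IndependentSiteModel(d["mode_id"], space)
            m.h = np.asarray(d["h"], dtype=float)
            if m.h.shape != (space.length, space.n_letters):
                raise EnergyModelError("field matrix shape mismatch")
            return m
        if kind == "shallow_dense":
            m = ShallowDenseModel(
                d["mode_id"], space, hidden=len(d["b1"]), activation=d["activation"]
            )
            m.W1 = np.asarray(d["W1"], dtype=float)
            m.b1 = np.asarray(d["b1"], dtype=float)
            m.v = np.asarray(d["v"], dtype=float)
            m.c = float(d["c"])
            return m
        raise EnergyModelError(f"unknown energy-model kind {kind!r}")


class IndependentSiteModel(EnergyModelBase):
    """Additive model: ``E(s) = sum_i h[i, s_i]``.

    Fields initialize at zero; differences between sequences differing at one
    position depend only on that position's letters.
    """

    kind = "independent_site"

    def __init__(self, mode_id: str, space: SequenceSpace):
        self.mode_id = mode_id
        self.space = space
        self.h = np.zeros((space.length, space.n_letters))

    def energies_codes(self, codes: np.ndarray) -> np.ndarray:
        pos = np.arange(self.space.length)
        return self.h[pos[None, :], codes].sum(axis=1)

    def get_params(self) -> np.ndarray:
        return self.h.ravel().copy()

    def set_params(self, flat: np.ndarray) -> None:
        self.h = np.asarray(flat, dtype=float).reshape(self.h.shape).copy()

    def backprop_codes(self, codes: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        gh = np.zeros_like(self.h)
        for i in range(self.space.length):
            np.add.at(gh[i], codes[:, i], grad_out)
        return gh.ravel()

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mode_id": self.mode_id, "h": self.h.tolist()}


class ShallowDenseModel(EnergyModelBase):
    """One-hidden-layer dense network on the one-hot encoding.

    ``E(s) = activation(x W1 + b1) · v + c`` with ``x`` the flat one-hot vector.
    Because ``x`` has exactly one 1 per position block, ``x W1`` is computed by
    gathering and summing rows of ``W1`` — the one-hot matrix is never
    materialized.  Default width 20 and tanh activation; both configurable.
    """

    kind = "shallow_dense"

    def __init__(
        self,
        mode_id: str,
        space: SequenceSpace,
        hidden: int = 20,
        activation: str = "tanh",
        rng: np.random.Generator | None = None,
    ):
        if activation not in _ACTIVATIONS:
            raise EnergyModelError(f"unknown activation {activation!r}")
        self.mode_id = mode_id
        self.space = space
        self.hidden = hidden
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        fan_in = space.length * space.n_letters
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, hidden))
        self.b1 = np.zeros(hidden)
        self.v = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.c = 0.0

    def _flat_codes(self, codes: np.ndarray) -> np.ndarray:
        offsets = np.arange(self.space.length) * self.space.n_letters
        return codes + offsets[None, :]

    def _pre(self, codes: np.ndarray) -> np.ndarray:
        flat = self._flat_codes(codes)
        return self.W1[flat].sum(axis=1) + self.b1

    def energies_codes(self, codes: np.ndarray) -> np.ndarray:
        act, _ = _ACTIVATIONS[self.activation]
        return act(self._pre(codes)) @ self.v + self.c

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.v, np.array([self.c])]
        )

    def set_params(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        n1 = self.W1.size
        n2 = n1 + self.b1.size
        n3 = n2 + self.v.size
        self.W1 = flat[:n1].reshape(self.W1.shape).copy()
        self.b1 = flat[n1:n2].copy()
        self.v = flat[n2:n3].copy()
        self.c = float(flat[n3])

    def backprop_codes(self, codes: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        act, dact = _ACTIVATIONS[self.activation]
        pre = self._pre(codes)
        hid = act(pre)
        gc = grad_out.sum()
        gv = hid.T @ grad_out
        gpre = (grad_out[:, None] * self.v[None, :]) * dact(pre)
        gb1 = gpre.sum(axis=0)
        gW1 = np.zeros_like(self.W1)
        flat = self._flat_codes(codes)
        for i in range(self.space.length):
            np.add.at(gW1, flat[:, i], gpre)
        return np.concatenate([gW1.ravel(), gb1, gv, np.array([gc])])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mode_id": self.mode_id,
            "activation": self.activation,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "v": self.v.tolist(),
            "c": self.c,
        }


def make_energy_model(
    kind: str,
    mode_id: str,
    space: SequenceSpace,
    hidden: int = 20,
    activation: str = "tanh",
    rng: np.random.Generator | None = None,
) -> EnergyModelBase:
    if kind == "independent_site":
        return IndependentSiteModel(mode_id, space)
    if kind == "shallow_dense":
        return ShallowDenseModel(mode_id, space, hidden=hidden,
                                 activation=activation, rng=rng)
    raise EnergyModelError(f"unknown energy-model kind {kind!r}")


@dataclass
class EnergyMatrix:
    """Energies of every sequence (rows, enumeration order) per mode (columns)."""

    space: SequenceSpace
    modes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.size, len(self.modes)):
            raise EnergyModelError(
                f"energy matrix shape {self.values.shape} does not match "
                f"({self.space.size}, {len(self.modes)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise EnergyModelError("energy matrix must be finite")

    def column(self, mode_id: str) -> np.ndarray:
        return self.values[:, self.modes.index(mode_id)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\t" + "\t".join(self.modes) + "\n")
            for i in range(self.space.size):
                row = "\t".join(f"{v:.6g}" for v in self.values[i])
                fh.write(f"{self.space.sequence(i)}\t{row}\n")
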