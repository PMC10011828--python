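"""Markov-chain stimulus specifications and theoretical conditional entropy.

A stimulus chain has five tone states; from every state the next tone is one
of exactly two successors, taken with probability ``p_high`` (the "high" TP
branch) or ``1 - p_high`` (the "low" branch).  Both successor maps are
bijections on the state set, so the transition matrix is doubly stochastic
and the stationary distribution is uniform.  Under that structure the
conditional entropy of the next tone given any length of history equals the
binary entropy of ``p_high`` — conditioning on more past adds nothing for a
genuinely first-order chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "MarkovSpec",
    "EntropyReport",
    "binary_entropy",
    "theoretical_conditional_entropy",
    "build_chain_variant",
    "SEQUENCE_RATIOS",
    "SEQUENCE_LABELS",
]

#: The three TP ratios of the study design, keyed by uncertainty label.
#: The high-uncertainty ratio is stored as the exact fraction 2:1 — its
#: percentage display is "67:33", but the target TP is 2/3 (binary entropy
#: 0.9183 bits, printed 0.92; and 300 per-state transitions split exactly
#: as 200:100).
SEQUENCE_RATIOS: dict[str, tuple[int, int]] = {
    "low": (90, 10),
    "intermediate": (80, 20),
    "high": (2, 1),
}
SEQUENCE_LABELS: tuple[str, ...] = ("low", "intermediate", "high")


def binary_entropy(p: float) -> float:
    """Entropy in bits of a Bernoulli(p) branch choice.

    Parameters
    ----------
    p : float
        Probability in [0, 1].

    Returns
    -------
    float
        ``-(p log2 p + (1-p) log2 (1-p))`` with ``0 log2 0 := 0``.

    Raises
    ------
    ValueError
        If ``p`` is outside [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range [0, 1]: {p}")
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * np.log2(q)
    return float(h)


@dataclass(frozen=True)
class MarkovSpec:
    """A five-state two-branch first-order Markov chain.

    Attributes
    ----------
    n_states : int
        Number of tone identities (states are ``0 .. n_states-1``).
    ratio : (int, int)
        The high:low TP ratio as printed, e.g. ``(90, 10)``; probabilities
        are stored exactly as ``high / (high + low)``.
    high_successor, low_successor : tuple[int, ...]
        Successor maps, each a self-loop-free bijection on the state set,
        disagreeing at every state.
    variant_id : int
        Counterbalancing label (chains are counterbalanced across subjects).
    """

    n_states: int
    ratio: tuple[int, int]
    high_successor: tuple[int, ...]
    low_successor: tuple[int, ...]
    variant_id: int = 1

    @property
    def p_high(self) -> float:
        h, l = self.ratio
        return h / (h + l)

    @property
    def p_low(self) -> float:
        return 1.0 - self.p_high

    @property
    def ratio_label(self) -> str:
        """Percentage display of the TP ratio, e.g. '90:10' or '67:33'."""
        return f"{round(self.p_high * 100)}:{round(self.p_low * 100)}"

    @property
    def states(self) -> range:
        return range(self.n_states)

    def __post_init__(self) -> None:
        n = self.n_states
        for name in ("high_successor", "low_successor"):
            succ = getattr(self, name)
            if len(succ) != n or sorted(succ) != list(range(n)):
                raise ValueError(f"{name} is not a bijection on 0..{n - 1}")
            if any(succ[s] == s for s in range(n)):
                raise ValueError(f"{name} contains a self-loop")
        if any(h == l for h, l in zip(self.high_successor, self.low_successor)):
            raise ValueError("high and low successors coincide at some state")
        if not (0.5 < self.p_high < 1.0 or self.ratio == (50, 50)):
            # 50:50 admitted for degenerate/toy use; the study ratios all
            # satisfy 0.5 < p_high < 1.
            if not 0.5 <= self.p_high <= 1.0:
                raise ValueError(f"p_high must lie in (0.5, 1): {self.p_high}")
        if not _strongly_connected(self.high_successor, self.low_successor):
            raise ValueError("union transition graph is not strongly connected")

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "ratio": list(self.ratio),
            "p_high": self.p_high,
            "high_successor": list(self.high_successor),
            "low_successor": list(self.low_successor),
            "variant_id": self.variant_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovSpec":
        return cls(
            n_states=int(d["n_states"]),
            ratio=(int(d["ratio"][0]), int(d["ratio"][1])),
            high_successor=tuple(int(x) for x in d["high_successor"]),
            low_successor=tuple(int(x) for x in d["low_successor"]),
            variant_id=int(d.get("variant_id", 1)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MarkovSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class EntropyReport:
    """A conditional-entropy value for an order-n predictive model."""

    order: int
    value_bits: float
    kind: Literal["theoretical", "empirical"]
    sequence_label: str | None = None
    n_states: int | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.value_bits < -1e-12:
            raise ValueError("entropy cannot be negative")
        if self.n_states is not None and self.value_bits > np.log2(self.n_states) + 1e-9:
            raise ValueError("entropy exceeds log2(n_states)")


def theoretical_conditional_entropy(spec: MarkovSpec, order: int = 1) -> EntropyReport:
    """Conditional entropy H(X_{t+1} | X_t, ..., X_{t-order+1}) under the true chain.

    For a first-order chain with a uniform stationary distribution and two
    successors per state, every context of length >= 1 determines the same
    two-point branch distribution, so the value is ``binary_entropy(p_high)``
    for every order.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    label = _label_for_ratio(spec.ratio)
    return EntropyReport(
        order=order,
        value_bits=binary_entropy(spec.p_high),
        kind="theoretical",
        sequence_label=label,
        n_states=spec.n_states,
    )


def _label_for_ratio(ratio: tuple[int, int]) -> str | None:
    for label, r in SEQUENCE_RATIOS.items():
        if r == tuple(ratio):
            return label
    return None


def _strongly_connected(high: tuple[int, ...], low: tuple[int, ...]) -> bool:
    n = len(high)
    fwd = [{high[s], low[s]} for s in range(n)]
    bwd = [set() for _ in range(n)]
    for s in range(n):
        for t in fwd[s]:
            bwd[t].add(s)

    def reach(adj):
        seen = {0}
        stack = [0]
        while stack:
            for t in adj[stack.pop()]:
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        return len(seen) == n

    return reach(fwd) and reach(bwd)


def build_chain_variant(
    ratio: tuple[int, int],
    variant_seed: int,
    n_states: int = 5,
    variant_id: int | None = None,
) -> MarkovSpec:
    """Draw a chain variant satisfying every structural invariant.

    The high and low successor maps are random self-loop-free bijections
    that disagree at every state; candidates are redrawn until the union
    graph is strongly connected.  Distinct seeds give distinct maps (with
    overwhelming probability), which is how the counterbalanced chain
    variants of the study are produced.
    """
    if n_states < 3:
        raise ValueError("need n_states >= 3 for two disjoint self-loop-free bijections")
    if tuple(ratio) == (67, 33):
        ratio = (2, 1)  # "67:33" is the percentage display of the exact 2:1 ratio
    high_i, low_i = int(ratio[0]), int(ratio[1])
    if high_i <= 0 or low_i <= 0 or high_i < low_i:
        raise ValueError(f"invalid TP ratio {ratio}; expected high >= low > 0")
    rng = np.random.default_rng(variant_seed)
    for _ in range(10_000):
        high = _random_derangement(rng, n_states)
        low = _random_derangement(rng, n_states)
        if any(h == l for h, l in zip(high, low)):
            continue
        if not _strongly_connected(high, low):
            continue
        return MarkovSpec(
            n_states=n_states,
            ratio=(high_i, low_i),
            high_successor=high,
            low_successor=low,
            variant_id=variant_id if variant_id is not None else (variant_seed % 3) + 1,
        )
    raise RuntimeError("could not construct a valid chain variant")  # pragma: no cover


def _random_derangement(rng: np.random.Generator, n: int) -> tuple[int, ...]:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return tuple(int(x) for x in perm)
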