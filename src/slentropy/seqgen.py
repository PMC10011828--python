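"""Exact-count tone-sequence generation and stimulus timeline construction.

A 1500-tone stream has 1499 transitions, which cannot split five states'
outgoing transitions into exact 270:30 (or 240:60, 201:99) blocks.  The
generator therefore lays the required edge multiset out as a closed Eulerian
circuit of the transition multigraph (possible because both successor maps
are bijections, so in-degree equals out-degree everywhere) and drops the
final, circuit-closing edge.  Every per-state transition count then matches
its exact target except for the single cut edge.

The timeline attaches a constant 0.6 s onset asynchrony, one extra 0.6 s
silent period per 50-tone block, and optionally renders the stream to audio
(300 ms pure tones, 10 ms linear rise, 200 ms linear fall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MarkovSpec

__all__ = [
    "ToneSequence",
    "StimulusTimeline",
    "edge_multiplicities",
    "generate_exact_sequence",
    "insert_silences",
    "tone_frequency",
    "build_timeline",
    "synthesize_audio",
    "assign_counterbalance",
    "PHASE_NAMES",
]

PHASE_NAMES: tuple[str, ...] = ("first", "middle", "last")

SOA_S = 0.6
TONE_DURATION_S = 0.300
RISE_S = 0.010
FALL_S = 0.200
SILENCE_S = 0.600
F0_HZ = 350.0


@dataclass(frozen=True)
class ToneSequence:
    """An ordered stream of tone states generated from a chain spec."""

    events: tuple[int, ...]
    spec: MarkovSpec
    phase_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.events)
        (a0, a1), (b0, b1), (c0, c1) = self.phase_bounds
        if not (a0 == 0 and a1 == b0 and b1 == c0 and c1 == n):
            raise ValueError("phase bounds must partition 0..length contiguously")
        hs, ls = self.spec.high_successor, self.spec.low_successor
        for u, v in zip(self.events, self.events[1:]):
            if v != hs[u] and v != ls[u]:
                raise ValueError(f"transition {u}->{v} is not an edge of the chain")

    def __len__(self) -> int:
        return len(self.events)

    def phase_of(self, index: int) -> str:
        for name, (lo, hi) in zip(PHASE_NAMES, self.phase_bounds):
            if lo <= index < hi:
                return name
        raise IndexError(index)

    def phase_slice(self, phase: str) -> slice:
        if phase == "all":
            return slice(0, len(self.events))
        lo, hi = self.phase_bounds[PHASE_NAMES.index(phase)]
        return slice(lo, hi)

    def phase_array(self) -> np.ndarray:
        out = np.empty(len(self.events), dtype=object)
        for name, (lo, hi) in zip(PHASE_NAMES, self.phase_bounds):
            out[lo:hi] = name
        return out


@dataclass(frozen=True)
class StimulusTimeline:
    """Per-event onsets plus the silence schedule."""

    onsets: tuple[float, ...]
    silence_positions: frozenset[int]
    soa: float = SOA_S
    tone_duration: float = TONE_DURATION_S
    rise: float = RISE_S
    fall: float = FALL_S

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets)
        gaps = np.diff(on)
        if np.any(gaps <= 0):
            raise ValueError("onsets must be strictly increasing")
        for i, g in enumerate(gaps):
            expected = self.soa + (SILENCE_S if i in self.silence_positions else 0.0)
            if abs(g - expected) > 1e-9:
                raise ValueError(f"onset gap {i} is {g}, expected {expected}")

    @property
    def total_duration(self) -> float:
        """Time from first onset to the end of the last event's SOA slot."""
        extra = SILENCE_S if (len(self.onsets) - 1) in self.silence_positions else 0.0
        return self.onsets[-1] + self.soa + extra


def edge_multiplicities(
    spec: MarkovSpec, per_state_transitions: int, allow_rounding: bool = False
) -> dict[tuple[int, int], int]:
    """Exact per-edge copy counts for the transition multigraph.

    Each state emits ``per_state_transitions * p_high`` copies of its high
    edge and the remainder low copies.  The split must be integral (it is
    for 300 transitions at every study ratio); pass ``allow_rounding=True``
    to accept a largest-remainder split otherwise.
    """
    hi, lo = spec.ratio
    num = per_state_transitions * hi
    den = hi + lo
    if num % den != 0:
        if not allow_rounding:
            raise ValueError(
                f"{per_state_transitions} transitions cannot split exactly at "
                f"ratio {hi}:{lo}; pass allow_rounding=True for a "
                "largest-remainder split"
            )
        m_high = round(num / den)
    else:
        m_high = num // den
    m_low = per_state_transitions - m_high
    counts: dict[tuple[int, int], int] = {}
    for u in spec.states:
        counts[(u, spec.high_successor[u])] = m_high
        counts[(u, spec.low_successor[u])] = counts.get((u, spec.low_successor[u]), 0) + m_low
    return counts


def _hierholzer_circuit(
    adjacency: dict[int, list[int]], start: int, n_edges: int
) -> list[int]:
    """Eulerian circuit as a node sequence of length ``n_edges + 1``.

    ``adjacency`` holds, per node, a mutable stack of out-neighbours (with
    multiplicity, pre-shuffled for randomisation); it is consumed.
    """
    stack = [start]
    circuit: list[int] = []
    while stack:
        u = stack[-1]
        if adjacency[u]:
            stack.append(adjacency[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    if len(circuit) != n_edges + 1:
        raise ValueError("transition multigraph is not connected")
    return circuit


def generate_exact_sequence(
    spec: MarkovSpec, length: int = 1500, seed: int | None = None
) -> ToneSequence:
    """Generate a tone stream whose transition counts are exact up to one edge.

    Builds the multigraph from :func:`edge_multiplicities`, draws a
    uniformly-seeded Eulerian circuit (independent shuffle of each node's
    edge stack, Hierholzer construction, random start state), and returns
    the first ``length`` node visits of the circuit.  The single unused edge
    is the one closing the circuit.
    """
    if length % spec.n_states != 0:
        raise ValueError(
            f"length {length} must be divisible by n_states={spec.n_states}"
        )
    per_state = length // spec.n_states
    counts = edge_multiplicities(spec, per_state)
    rng = np.random.default_rng(seed)
    adjacency: dict[int, list[int]] = {u: [] for u in spec.states}
    for (u, v), m in counts.items():
        adjacency[u].extend([v] * m)
    for u in spec.states:
        rng.shuffle(adjacency[u])
    start = int(rng.integers(spec.n_states))
    circuit = _hierholzer_circuit(adjacency, start, n_edges=length)
    events = tuple(circuit[:length])
    third = length // 3
    bounds = ((0, third), (third, 2 * third), (2 * third, length))
    return ToneSequence(events=events, spec=spec, phase_bounds=bounds, seed=seed)


def insert_silences(
    length: int = 1500, block: int = 50, seed: int | None = None
) -> tuple[int, ...]:
    """One silent-period position per non-overlapping ``block``-tone set.

    Returned positions are inter-tone gap indices: position ``g`` inserts a
    0.6 s pause after tone ``g``, drawn uniformly within each block.
    """
    if block > length:
        raise ValueError("block larger than sequence")
    if length % block != 0:
        raise ValueError("block must divide length")
    rng = np.random.default_rng(seed)
    return tuple(
        int(b * block + rng.integers(block)) for b in range(length // block)
    )


def tone_frequency(index: int, n_states: int = 5, f0: float = F0_HZ) -> float:
    """Fundamental of tone ``index`` (1-based) on the five-tone equal-temperament scale.

    ``f0 * 2**((index-1)/n_states)`` — 350, 402, 462, 531 and 609 Hz after
    rounding to integer Hz for the default scale.
    """
    if not 1 <= index <= n_states:
        raise ValueError(f"tone index {index} outside 1..{n_states}")
    return float(f0 * 2.0 ** ((index - 1) / n_states))


def build_timeline(
    seq: ToneSequence | int, silences: tuple[int, ...] = ()
) -> StimulusTimeline:
    """Attach onsets to a sequence: constant SOA plus scheduled silences."""
    n = seq if isinstance(seq, int) else len(seq)
    silence_set = frozenset(int(s) for s in silences)
    if silence_set and max(silence_set) >= n:
        raise ValueError("silence position beyond sequence")
    onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        onsets[i] = t
        t += SOA_S + (SILENCE_S if i in silence_set else 0.0)
    return StimulusTimeline(onsets=tuple(float(x) for x in onsets), silence_positions=silence_set)


def synthesize_audio(
    seq: ToneSequence,
    timeline: StimulusTimeline,
    sample_rate: int = 44100,
    amplitude: float = 0.5,
) -> np.ndarray:
    """Render the stream as mono audio: enveloped sine per tone, silence elsewhere.

    Each tone is a sine at its scale frequency with a linear 10 ms rise and
    200 ms fall inside a 300 ms gate; tone onsets follow the timeline.  The
    returned buffer is float64 in [-amplitude, amplitude]; write it with
    :func:`slentropy.io_cli.write_wav`.
    """
    if timeline.tone_duration > timeline.soa:
        raise ValueError("tones would overlap: duration exceeds SOA")
    n_samples = int(np.ceil(timeline.total_duration * sample_rate))
    audio = np.zeros(n_samples)
    n_tone = int(round(TONE_DURATION_S * sample_rate))
    t = np.arange(n_tone) / sample_rate
    envelope = np.ones(n_tone)
    rise_n = int(round(RISE_S * sample_rate))
    fall_n = int(round(FALL_S * sample_rate))
    envelope[:rise_n] = np.arange(rise_n) / rise_n
    envelope[-fall_n:] = np.linspace(1.0, 0.0, fall_n)
    for state, onset in zip(seq.events, timeline.onsets):
        f = tone_frequency(state + 1, seq.spec.n_states)
        i0 = int(round(onset * sample_rate))
        audio[i0 : i0 + n_tone] += amplitude * envelope * np.sin(2 * np.pi * f * t)
    peak = np.max(np.abs(audio))
    if peak > 0:
        audio *= amplitude / peak
    return audio


def assign_counterbalance(n_subjects: int) -> pd.DataFrame:
    """Balanced assignment of sequence order and chain variant across subjects.

    Cycles through the six permutations of (low, intermediate, high) and the
    three chain variants so that every permutation is used ``n // 6`` or
    ``n // 6 + 1`` times, mirroring the study's counterbalancing.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    from itertools import permutations

    perms = list(permutations(("low", "intermediate", "high")))
    rows = []
    for s in range(n_subjects):
        rows.append(
            {
                "subject": s,
                "sequence_order": perms[s % 6],
                "chain_variant": (s % 3) + 1,
            }
        )
    return pd.DataFrame(rows)
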