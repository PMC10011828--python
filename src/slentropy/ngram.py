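"""n-gram re-analysis of tone sequences.

The same first-order stream can be read through predictive models of any
order n: slide a window of n context tones plus one outcome tone, count the
occurrences of every (context, outcome) pattern, and summarise the model's
residual uncertainty with the plug-in conditional entropy

    H = sum_c P(c) * sum_o -P(o|c) log2 P(o|c).

Two labelling schemes feed the evoked-response analyses:

* order 1 — every transition is "high" or "low" according to the branch of
  the generating chain it takes (model TPs, not empirical counts);
* order n >= 2 — outcome tones are grouped into comparison pairs: two
  contexts that differ only in their first (oldest) tone and lead to the
  same outcome.  Because the pair shares every statistic of order < n, the
  contrast between its frequent ("high") and rare ("low") member isolates
  genuinely order-n knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .design import EntropyReport
from .seqgen import ToneSequence

__all__ = [
    "NGramTable",
    "ComparisonPair",
    "ComparisonPairSet",
    "EventLabels",
    "count_ngrams",
    "empirical_conditional_entropy",
    "label_events_first_order",
    "select_comparison_pairs",
    "label_events_higher_order",
]

Context = tuple[int, ...]


@dataclass(frozen=True)
class NGramTable:
    """Order-n (context -> outcome) occurrence counts for one phase."""

    order: int
    phase: str
    counts: dict[tuple[Context, int], int]
    n_states: int

    def total(self) -> int:
        return sum(self.counts.values())

    def context_totals(self) -> dict[Context, int]:
        out: dict[Context, int] = {}
        for (ctx, _), c in self.counts.items():
            out[ctx] = out.get(ctx, 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "context": "-".join(str(s) for s in ctx),
                "outcome": out,
                "count": c,
            }
            for (ctx, out), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["context", "outcome", "count"])

    def to_matrix(self) -> pd.DataFrame:
        """Contexts x outcomes occurrence matrix (the per-phase count matrices)."""
        frame = self.to_frame()
        return frame.pivot_table(
            index="context", columns="outcome", values="count", fill_value=0
        )


@dataclass(frozen=True)
class ComparisonPair:
    """Two order-n patterns differing only in the oldest context tone."""

    context_high: Context
    context_low: Context
    outcome: int
    count_high: int
    count_low: int
    tie: bool = False

    def __post_init__(self) -> None:
        if self.context_high[1:] != self.context_low[1:]:
            raise ValueError("pair contexts must share all but their first tone")
        if self.context_high[0] == self.context_low[0]:
            raise ValueError("pair contexts must differ in their first tone")
        if self.count_high < self.count_low:
            raise ValueError("high side must carry the larger count")


@dataclass(frozen=True)
class ComparisonPairSet:
    order: int
    pairs: tuple[ComparisonPair, ...]
    phase: str = "all"
    min_count: int = 5

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("comparison pairs require order >= 2")
        seen: set[tuple[Context, int]] = set()
        for p in self.pairs:
            for key in ((p.context_high, p.outcome), (p.context_low, p.outcome)):
                if key in seen:
                    raise ValueError(f"pattern {key} claimed by two pairs")
                seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def empty(self) -> bool:
        return len(self.pairs) == 0


@dataclass(frozen=True)
class EventLabels:
    """Per-event condition classes for selective averaging at one order."""

    order: int
    classes: tuple[str, ...]  # "high" | "low" | "excluded"
    pair_ids: tuple[int, ...]  # -1 where not applicable
    surprisal_bits: tuple[float, ...]  # nan where excluded
    phase: str = "all"

    def __post_init__(self) -> None:
        if not (len(self.classes) == len(self.pair_ids) == len(self.surprisal_bits)):
            raise ValueError("label arrays must be aligned")
        for cls in self.classes:
            if cls not in ("high", "low", "excluded"):
                raise ValueError(f"unknown class {cls!r}")

    def __len__(self) -> int:
        return len(self.classes)

    def class_counts(self) -> dict[str, int]:
        out = {"high": 0, "low": 0, "excluded": 0}
        for cls in self.classes:
            out[cls] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event": np.arange(len(self.classes)),
                "order": self.order,
                "class": self.classes,
                "pair_id": self.pair_ids,
                "surprisal_bits": self.surprisal_bits,
            }
        )


def _silence_break_ok(window_start: int, window_end: int, silences) -> bool:
    if silences is None:
        return True
    return not any(window_start <= g < window_end - 1 for g in silences)


def count_ngrams(
    seq: ToneSequence,
    order: int,
    phase: str = "all",
    silences: tuple[int, ...] | None = None,
) -> NGramTable:
    """Slide an (order+1)-window over the in-phase events and count patterns.

    Windows crossing a phase boundary are dropped (each phase's matrix is
    self-contained).  By default the tone stream is treated as continuous
    across silent periods; pass the silence positions to drop windows that
    span one.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    sl = seq.phase_slice(phase)
    events = seq.events[sl]
    if order >= len(events):
        raise ValueError(f"order {order} >= phase length {len(events)}")
    counts: dict[tuple[Context, int], int] = {}
    for i in range(len(events) - order):
        if not _silence_break_ok(sl.start + i, sl.start + i + order + 1, silences):
            continue
        ctx = tuple(events[i : i + order])
        out = events[i + order]
        counts[(ctx, out)] = counts.get((ctx, out), 0) + 1
    return NGramTable(order=order, phase=phase, counts=counts, n_states=seq.spec.n_states)


def empirical_conditional_entropy(table: NGramTable, label: str | None = None) -> EntropyReport:
    """Plug-in conditional entropy of the outcome given the order-n context, in bits."""
    total = table.total()
    if total == 0:
        raise ValueError("empty n-gram table")
    h = 0.0
    per_ctx: dict[Context, list[int]] = {}
    for (ctx, _out), n in table.counts.items():
        per_ctx.setdefault(ctx, []).append(n)
    for ctx, outcome_counts in per_ctx.items():
        ctx_total = sum(outcome_counts)
        p_ctx = ctx_total / total
        for n in outcome_counts:
            p = n / ctx_total
            if p > 0:
                h -= p_ctx * p * np.log2(p)
    return EntropyReport(
        order=table.order,
        value_bits=float(h),
        kind="empirical",
        sequence_label=label,
        n_states=table.n_states,
    )


def label_events_first_order(seq: ToneSequence, phase: str = "all") -> EventLabels:
    """Label each transition high/low by the branch of the generating chain.

    Surprisal is the model value -log2 p of the branch taken.  The first
    event of the sequence (or of the phase, for phase-restricted labelling)
    has no context and is excluded.
    """
    spec = seq.spec
    s_high = -np.log2(spec.p_high)
    s_low = -np.log2(spec.p_low) if spec.p_low > 0 else np.inf
    n = len(seq)
    classes = ["excluded"] * n
    surprisal = [float("nan")] * n
    sl = seq.phase_slice(phase)
    for i in range(sl.start + 1, sl.stop):
        u, v = seq.events[i - 1], seq.events[i]
        if v == spec.high_successor[u]:
            classes[i] = "high"
            surprisal[i] = s_high
        elif v == spec.low_successor[u]:
            classes[i] = "low"
            surprisal[i] = s_low
        else:  # pragma: no cover - ToneSequence validates transitions
            raise ValueError(f"transition {u}->{v} not in chain")
    return EventLabels(
        order=1,
        classes=tuple(classes),
        pair_ids=tuple([-1] * n),
        surprisal_bits=tuple(surprisal),
        phase=phase,
    )


def select_comparison_pairs(
    table: NGramTable, min_count: int = 5, keep_ties: bool = False
) -> ComparisonPairSet:
    """Enumerate comparison pairs: same outcome, contexts differing in the first tone.

    Within each (shared context tail, outcome) group, contexts are ranked by
    occurrence count and the top two qualifying ones form a pair, the larger
    count on the high side.  Both sides must reach ``min_count``; exact ties
    are flagged and dropped unless ``keep_ties``.
    """
    if table.order < 2:
        raise ValueError("comparison pairs require order >= 2")
    groups: dict[tuple[Context, int], list[tuple[Context, int]]] = {}
    for (ctx, out), n in table.counts.items():
        groups.setdefault((ctx[1:], out), []).append((ctx, n))
    pairs: list[ComparisonPair] = []
    for (_tail, out), members in sorted(groups.items()):
        qualifying = sorted(
            (m for m in members if m[1] >= min_count),
            key=lambda m: (-m[1], m[0]),
        )
        if len(qualifying) < 2:
            continue
        (ctx_h, n_h), (ctx_l, n_l) = qualifying[0], qualifying[1]
        tie = n_h == n_l
        if tie and not keep_ties:
            continue
        pairs.append(
            ComparisonPair(
                context_high=ctx_h,
                context_low=ctx_l,
                outcome=out,
                count_high=n_h,
                count_low=n_l,
                tie=tie,
            )
        )
    return ComparisonPairSet(
        order=table.order, pairs=tuple(pairs), phase=table.phase, min_count=min_count
    )


def label_events_higher_order(
    seq: ToneSequence, pairs: ComparisonPairSet, phase: str | None = None
) -> EventLabels:
    """Assign outcome events to the high/low side of their comparison pair.

    An event is labelled when its preceding order-length context (within the
    labelling phase) matches one side of a pair; everything else is
    excluded.  Surprisal is the within-pair empirical value
    ``-log2(count_side / (count_high + count_low))`` — for these chains an
    estimate of the branch probability of the oldest transition in the
    window, the quantity the pair contrast isolates.
    """
    phase = pairs.phase if phase is None else phase
    order = pairs.order
    lookup: dict[tuple[Context, int], tuple[str, int, float]] = {}
    for pid, p in enumerate(pairs.pairs):
        total = p.count_high + p.count_low
        lookup[(p.context_high, p.outcome)] = (
            "high",
            pid,
            float(-np.log2(p.count_high / total)),
        )
        lookup[(p.context_low, p.outcome)] = (
            "low",
            pid,
            float(-np.log2(p.count_low / total)),
        )
    n = len(seq)
    classes = ["excluded"] * n
    pair_ids = [-1] * n
    surprisal = [float("nan")] * n
    sl = seq.phase_slice(phase)
    for i in range(sl.start + order, sl.stop):
        ctx = tuple(seq.events[i - order : i])
        hit = lookup.get((ctx, seq.events[i]))
        if hit is not None:
            classes[i], pair_ids[i], surprisal[i] = hit
    return EventLabels(
        order=order,
        classes=tuple(classes),
        pair_ids=tuple(pair_ids),
        surprisal_bits=tuple(surprisal),
        phase=phase,
    )
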