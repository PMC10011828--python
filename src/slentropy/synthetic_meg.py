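"""Surprisal-modulated synthetic source-strength epochs.

Emulates per-tone evoked responses (two hemispheres' auditory-cortex source
strength, nAm) for a listener whose order-n statistical model drives the
N1m: each event's response is a Gaussian bump near 100 ms whose amplitude
grows linearly with the event's order-n surprisal and whose latency shifts
with it, scaled by phase-wise habituation and a hemisphere gain, on top of
white noise.  Epochs span -100..+500 ms at 600 samples/s (360 samples), a
typical MEG epoching geometry for auditory evoked fields.

This is a forward model for parameter recovery, not a waveform-realistic
simulator: noise is white (no 1/f or sensor structure), the bump is
unimodal, and habituation is a per-phase multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ngram import EventLabels, count_ngrams, label_events_first_order, label_events_higher_order, select_comparison_pairs
from .seqgen import ToneSequence, assign_counterbalance

__all__ = [
    "SimConfig",
    "SubjectDataset",
    "epoch_times",
    "labels_for_order",
    "simulate_subject",
    "simulate_cohort",
]

SFREQ = 600.0
EPOCH_START_S = -0.100
EPOCH_STOP_S = 0.500
N_SAMPLES = int(round((EPOCH_STOP_S - EPOCH_START_S) * SFREQ))  # 360

HEMISPHERES = ("left", "right")


def epoch_times(sfreq: float = SFREQ) -> np.ndarray:
    """Epoch time axis in seconds, -100 ms inclusive, step 1/sfreq."""
    n = int(round((EPOCH_STOP_S - EPOCH_START_S) * sfreq))
    return EPOCH_START_S + np.arange(n) / sfreq


@dataclass(frozen=True)
class SimConfig:
    """Forward-model parameters.

    Defaults encode the qualitative structure auditory statistical-learning
    experiments report: habituation of amplitude across the three sequence
    phases, a right-hemisphere gain advantage, and a positive amplitude
    (and latency) effect of surprisal.  Units: amplitudes in nAm,
    latencies in ms, ``beta_amp`` in fractional gain per bit, ``gamma_lat``
    in ms per bit.
    """

    true_order: int = 1
    base_amp: float = 20.0  # nAm, typical auditory N1m source strength
    beta_amp: float = 0.10  # fractional amplitude gain per bit of surprisal
    gamma_lat: float = 5.0  # ms latency shift per bit
    peak_latency0: float = 100.0  # ms
    peak_width: float = 20.0  # ms (Gaussian sigma)
    habituation: tuple[float, float, float] = (1.0, 0.85, 0.75)
    hemi_gain: tuple[float, float] = (1.0, 1.3)  # (left, right)
    noise_sd: float = 5.0  # nAm per sample, white
    trial_jitter_sd: float = 0.05  # fractional amplitude jitter per trial
    subject_amp_sd: float = 3.0  # nAm, between-subject random effect on base_amp
    spike_rate: float = 0.0  # fraction of epochs receiving a large artifact
    spike_amp: float = 500.0  # nAm artifact amplitude
    sfreq: float = SFREQ
    min_pair_count: int = 5

    def __post_init__(self) -> None:
        if self.peak_width <= 0 or self.sfreq <= 0:
            raise ValueError("peak_width and sfreq must be positive")
        if any(h <= 0 for h in self.habituation):
            raise ValueError("habituation multipliers must be positive")
        if self.true_order < 1:
            raise ValueError("true_order must be >= 1")


@dataclass
class SubjectDataset:
    """Per-event two-hemisphere epochs with event metadata."""

    subject: int
    sequence_label: str
    epochs: np.ndarray  # (n_events, 2, n_samples) nAm
    events: pd.DataFrame  # columns: event, tone, phase
    seq: ToneSequence
    times: np.ndarray = field(default_factory=epoch_times)
    spike_events: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.epochs.shape[1] != 2 or self.epochs.shape[2] != len(self.times):
            raise ValueError("epochs must be (events, 2 hemispheres, samples)")
        if self.epochs.shape[0] != len(self.events):
            raise ValueError("metadata rows must match epochs")

    @property
    def n_events(self) -> int:
        return self.epochs.shape[0]


def labels_for_order(
    seq: ToneSequence, order: int, phase: str = "all", min_count: int = 5
) -> EventLabels:
    """Event labels at any analysis order (branch labels at 1, pairs at >= 2)."""
    if order == 1:
        return label_events_first_order(seq, phase=phase)
    table = count_ngrams(seq, order, phase=phase)
    pairs = select_comparison_pairs(table, min_count=min_count)
    return label_events_higher_order(seq, pairs, phase=phase)


def simulate_subject(
    seq: ToneSequence,
    cfg: SimConfig,
    subject_seed: int,
    labels: EventLabels | None = None,
    subject: int = 0,
    sequence_label: str | None = None,
) -> SubjectDataset:
    """Simulate one subject's epochs for one sequence.

    Per event and hemisphere the signal is
    ``A * exp(-(t - lam)^2 / (2 w^2))`` for t >= 0, with
    ``A = base_amp * hemi_gain * habituation[phase] * (1 + beta_amp * s) * (1 + jitter)``
    and ``lam = peak_latency0 + gamma_lat * s`` where s is the event's
    surprisal at ``cfg.true_order`` (0 for events excluded at that order).
    White noise of sd ``noise_sd`` covers the whole epoch, baseline
    included.  Deterministic under ``subject_seed``.
    """
    if labels is None:
        labels = labels_for_order(seq, cfg.true_order, min_count=cfg.min_pair_count)
    if labels.order != cfg.true_order:
        raise ValueError("labels were computed at a different order than cfg.true_order")
    rng = np.random.default_rng(subject_seed)
    times_ms = epoch_times(cfg.sfreq) * 1000.0
    n_samples = times_ms.size
    n_events = len(seq)

    surprisal = np.asarray(labels.surprisal_bits, dtype=float)
    surprisal = np.where(np.isfinite(surprisal), surprisal, 0.0)
    phase_idx = np.fromiter(
        (("first", "middle", "last").index(seq.phase_of(i)) for i in range(n_events)),
        dtype=int,
        count=n_events,
    )
    hab = np.asarray(cfg.habituation)[phase_idx]  # (events,)
    jitter = (
        rng.normal(0.0, cfg.trial_jitter_sd, size=n_events)
        if cfg.trial_jitter_sd > 0
        else np.zeros(n_events)
    )
    amp_base = cfg.base_amp * hab * (1.0 + cfg.beta_amp * surprisal) * (1.0 + jitter)
    lam = cfg.peak_latency0 + cfg.gamma_lat * surprisal  # (events,) ms

    post = times_ms >= 0.0
    bump = np.exp(
        -((times_ms[None, :] - lam[:, None]) ** 2) / (2.0 * cfg.peak_width**2)
    )
    bump[:, ~post] = 0.0
    gains = np.asarray(cfg.hemi_gain)  # (2,)
    epochs = amp_base[:, None, None] * gains[None, :, None] * bump[:, None, :]
    if cfg.noise_sd > 0:
        epochs = epochs + rng.normal(0.0, cfg.noise_sd, size=epochs.shape)

    spike_events: tuple[int, ...] = ()
    if cfg.spike_rate > 0:
        mask = rng.random(n_events) < cfg.spike_rate
        idx = np.nonzero(mask)[0]
        for i in idx:
            h = int(rng.integers(2))
            t = int(rng.integers(n_samples))
            epochs[i, h, t] += cfg.spike_amp * (1 if rng.random() < 0.5 else -1)
        spike_events = tuple(int(i) for i in idx)

    events = pd.DataFrame(
        {
            "event": np.arange(n_events),
            "tone": list(seq.events),
            "phase": [seq.phase_of(i) for i in range(n_events)],
        }
    )
    return SubjectDataset(
        subject=subject,
        sequence_label=sequence_label or "",
        epochs=epochs,
        events=events,
        seq=seq,
        times=epoch_times(cfg.sfreq),
        spike_events=spike_events,
    )


def simulate_cohort(
    sequences: dict[str, ToneSequence] | dict[str, dict[int, ToneSequence]],
    cfg: SimConfig,
    n_subjects: int = 13,
    seed: int = 0,
) -> list[SubjectDataset]:
    """Simulate a counterbalanced cohort across the three sequences.

    ``sequences`` maps sequence label -> ToneSequence (shared by all
    subjects) or label -> {variant_id: ToneSequence} to honour chain
    counterbalancing.  Each subject receives an independent random effect
    on ``base_amp`` (sd ``cfg.subject_amp_sd``) and independent noise;
    everything is reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    cb = assign_counterbalance(n_subjects)
    label_cache: dict[int, EventLabels] = {}
    out: list[SubjectDataset] = []
    for _, row in cb.iterrows():
        s = int(row["subject"])
        shift = rng.normal(0.0, cfg.subject_amp_sd) if cfg.subject_amp_sd > 0 else 0.0
        subj_cfg = replace(cfg, base_amp=max(cfg.base_amp + shift, 1e-3))
        for seq_label in row["sequence_order"]:
            if seq_label not in sequences:
                continue  # reduced designs may simulate a subset of sequences
            entry = sequences[seq_label]
            if isinstance(entry, dict):
                variants = sorted(entry)
                seq = entry[variants[(row["chain_variant"] - 1) % len(variants)]]
            else:
                seq = entry
            key = id(seq)
            if key not in label_cache:
                label_cache[key] = labels_for_order(
                    seq, cfg.true_order, min_count=cfg.min_pair_count
                )
            subject_seed = int(rng.integers(2**31 - 1))
            out.append(
                simulate_subject(
                    seq,
                    subj_cfg,
                    subject_seed=subject_seed,
                    labels=label_cache[key],
                    subject=s,
                    sequence_label=seq_label,
                )
            )
    return out
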