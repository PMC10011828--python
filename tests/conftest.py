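import numpy as np
import pytest

from slentropy.design import SEQUENCE_LABELS, SEQUENCE_RATIOS, MarkovSpec, build_chain_variant
from slentropy.seqgen import ToneSequence, generate_exact_sequence

VARIANT_SEEDS = {"low": 11, "intermediate": 12, "high": 13}
SEQUENCE_SEEDS = {"low": 21, "intermediate": 22, "high": 23}


@pytest.fixture(scope="session")
def specs() -> dict[str, MarkovSpec]:
    return {
        label: build_chain_variant(SEQUENCE_RATIOS[label], VARIANT_SEEDS[label])
        for label in SEQUENCE_LABELS
    }


@pytest.fixture(scope="session")
def sequences(specs) -> dict[str, ToneSequence]:
    return {
        label: generate_exact_sequence(specs[label], 1500, seed=SEQUENCE_SEEDS[label])
        for label in SEQUENCE_LABELS
    }


@pytest.fixture(scope="session")
def spec90(specs) -> MarkovSpec:
    return specs["low"]


@pytest.fixture(scope="session")
def seq90(sequences) -> ToneSequence:
    return sequences["low"]


def make_toy_sequence(events, spec: MarkovSpec, seed=None) -> ToneSequence:
    """Wrap an explicit event list in a ToneSequence with equal-third phases."""
    n = len(events)
    third = n // 3
    return ToneSequence(
        events=tuple(events),
        spec=spec,
        phase_bounds=((0, third), (third, 2 * third), (2 * third, n)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def melody_sequence() -> ToneSequence:
    """The 2nd-order-predictable melody: repeating unit C-D-E-F-D.

    With states C=0, D=1, E=2, F=3 (plus an unused fifth state to close the
    successor bijections): D is followed by C or E at 50:50, a note after
    (C, D) is always E, and a note after (F, D) is always C — first-order
    prediction of the note after D is at chance while second-order
    prediction is perfect.
    """
    spec = MarkovSpec(
        n_states=5,
        ratio=(50, 50),
        high_successor=(1, 2, 3, 4, 0),  # C>D, D>E, E>F, F>G, G>C
        low_successor=(2, 0, 4, 1, 3),  # C>E, D>C, E>G, F>D, G>F
    )
    unit = (0, 1, 2, 3, 1)  # C D E F D, then wraps D->C
    return make_toy_sequence(unit * 6, spec)


@pytest.fixture(scope="session")
def toy3_spec() -> MarkovSpec:
    """Three-state chain small enough for exhaustive Eulerian-circuit checks."""
    return MarkovSpec(
        n_states=3,
        ratio=(2, 1),
        high_successor=(1, 2, 0),
        low_successor=(2, 0, 1),
    )
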