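import numpy as np
import pytest

from cholbind.contacts import ContactParameters, detect_contacts
from cholbind.synthetic import default_spec, generate_membrane_trajectory


@pytest.fixture(scope="session")
def small_system():
    """Default two-site synthetic system at reduced length (in-memory)."""
    return generate_membrane_trajectory(default_spec(seed=3, n_frames=4000))


@pytest.fixture(scope="session")
def small_contacts(small_system):
    return detect_contacts(
        small_system.trajectory, small_system.topology, "cholesterol",
        ContactParameters(),
    )


def hysteresis_oracle(distances, lower, upper):
    """Reference single-pass state machine for the dual-cutoff rule."""
    bound = False
    out = []
    for d in distances:
        if bound and d >= upper:
            bound = False
        elif not bound and d < lower:
            bound = True
        out.append(bound)
    return np.array(out, dtype=bool)


def runs_oracle(bound):
    """Reference maximal-run finder: list of (start, length, censored)."""
    out = []
    start = None
    for i, b in enumerate(bound):
        if b and start is None:
            start = i
        elif not b and start is not None:
            out.append((start, i - start, False))
            start = None
    if start is not None:
        out.append((start, len(bound) - start, True))
    return out
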