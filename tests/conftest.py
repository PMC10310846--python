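import numpy as np
import pytest

from sqifc import circuits, psd, synthesis as syn


@pytest.fixture
def validation_circuit():
    """10 kΩ in series with (4.7 kΩ ∥ 100 pF): the validation circuit."""
    return circuits.validation_circuit()


@pytest.fixture
def excitation():
    """Default chain: 50 mV half-amplitude, 10 kΩ TIA, 6 odd harmonics."""
    return psd.ExcitationConfig()


def random_rc_tree(rng, depth=0):
    """Random small series/parallel RC network containing at least one resistor."""
    def build(depth):
        if depth >= 2 or rng.random() < 0.4:
            if rng.random() < 0.6:
                return circuits.resistor(10 ** rng.uniform(2.5, 4.5))
            return circuits.capacitor(10 ** rng.uniform(-11, -9.5))
        kids = [build(depth + 1) for _ in range(rng.integers(2, 4))]
        comb = circuits.series if rng.random() < 0.5 else circuits.parallel
        return comb(*kids)

    def has_resistor(m):
        return m.kind == "resistor" or any(has_resistor(c) for c in m.children)

    tree = build(depth)
    while not has_resistor(tree):
        tree = build(depth)
    return tree


def nodal_impedance(model, frequencies):
    """Independent oracle: input impedance by nodal analysis.

    The tree is flattened to two-terminal elements on numbered nodes, the
    complex admittance matrix assembled, and V/I solved with the output
    terminal grounded — no series/parallel reduction involved.
    """
    elements = []
    counter = [1]

    def flatten(m, a, b):
        if m.kind in ("resistor", "capacitor"):
            elements.append((a, b, m))
        elif m.kind == "series":
            prev = a
            for child in m.children[:-1]:
                counter[0] += 1
                nxt = counter[0]
                flatten(child, prev, nxt)
                prev = nxt
            flatten(m.children[-1], prev, b)
        else:
            for child in m.children:
                flatten(child, a, b)

    flatten(model, 1, 0)
    n_nodes = counter[0]
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    z_in = np.empty(f.shape, dtype=complex)
    for k, fk in enumerate(f):
        omega = 2 * np.pi * fk
        y = np.zeros((n_nodes, n_nodes), dtype=complex)
        for a, b, el in elements:
            g = 1.0 / el.value if el.kind == "resistor" else 1j * omega * el.value
            for p, q in ((a, b), (b, a)):
                if p > 0:
                    y[p - 1, p - 1] += g
                    if q > 0:
                        y[p - 1, q - 1] -= g
        current = np.zeros(n_nodes, dtype=complex)
        current[0] = 1.0  # 1 A into the input node, output grounded
        v = np.linalg.solve(y, current)
        z_in[k] = v[0]
    return z_in


@pytest.fixture
def bead_stream():
    """200 beads, 63–83 µm, 0.14 m/s, 2% amplitude noise — with truth table."""
    cfg = syn.StreamConfig(seed=7)
    particles = syn.random_particles(cfg, n_beads=200, seed=7)
    stream, truth = syn.synthesize_stream(cfg, particles)
    return cfg, stream, truth


def match_events_to_truth(events, truth):
    """Attach the nearest-in-time truth row to each paired event."""
    paired = events[events["paired"].astype(bool)].reset_index(drop=True)
    tp = truth["t_peak1_s"].to_numpy()
    j = np.abs(paired["t1_s"].to_numpy()[:, None] - tp[None, :]).argmin(axis=1)
    matched = truth.iloc[j].reset_index(drop=True)
    matched.columns = ["true_" + c for c in matched.columns]
    out = paired.join(matched)
    return out
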