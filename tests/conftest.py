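"""Shared fixtures: small molecules built programmatically."""

import math

import numpy as np
import pytest

from pcsbonds import Geometry, lookup_element


def _g(symbols, coords, label=""):
    return Geometry(
        tuple(lookup_element(s) for s in symbols), np.array(coords), label=label
    )


@pytest.fixture
def h2():
    return _g(["H", "H"], [[0, 0, 0], [0.74, 0, 0]], "H2")


@pytest.fixture
def water():
    # r(OH) = 0.9572 Å, angle 104.52 deg
    a = math.radians(104.52)
    return _g(
        ["O", "H", "H"],
        [[0, 0, 0], [0.9572, 0, 0], [0.9572 * math.cos(a), 0.9572 * math.sin(a), 0]],
        "water",
    )


@pytest.fixture
def methane():
    # tetrahedral, r(CH) = 1.09 Å
    d = 1.09 / math.sqrt(3)
    return _g(
        ["C", "H", "H", "H", "H"],
        [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]],
        "methane",
    )


def make_benzene(rcc=1.39, rch=1.08):
    """Idealized regular-hexagon benzene with radial C-H bonds."""
    coords, symbols = [], []
    for ring_r, sym in ((rcc, "C"), (rcc + rch, "H")):
        for nth in range(6):
            a = math.radians(60 * nth)
            coords.append([ring_r * math.cos(a), ring_r * math.sin(a), 0.0])
            symbols.append(sym)
    return _g(symbols, coords, "benzene")


@pytest.fixture
def benzene():
    return make_benzene()


def random_cluster(rng, n_atoms, symbols=("C", "C", "O", "N", "H", "C"),
                   min_sep=0.8, box=1.8):
    """Random well-separated cluster for derivative oracles."""
    while True:
        coords = rng.uniform(-box, box, (n_atoms, 3))
        diff = coords[:, None] - coords[None, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > min_sep:
            return _g(list(symbols[:n_atoms]), coords)
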