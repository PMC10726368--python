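"""Rotational constants: rigid-rotor values and ground-state assembly.

Equilibrium constants follow from the principal moments of inertia of
the mass distribution, ``B_i = kappa / I_i`` with ``I`` in amu Å² and
``kappa = h / (8 pi^2)`` in the matching units; they are labeled
a, b, c in descending order (A >= B >= C).

What experiment measures are *ground-state* constants.  The dominant
shift is vibrational averaging: to second order in vibrational
perturbation theory,

    B0 = B_eq - 1/2 * sum_r alpha_r ,

with the vibration-rotation interaction constants ``alpha`` supplied
externally (their computation needs an anharmonic force field and is
outside this package).  A much smaller electronic term couples the
rotational g tensor to each constant,

    dB_el = (m_e / M_p) * g_ii * B_i ,

with ``g_ii`` in nuclear magnetons; it follows the sign of g and is
typically below the 0.1% accuracy target, so assembled ground-state
estimates exclude it by convention (it is reported separately).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np

from .geometry import Geometry

__all__ = [
    "KAPPA_MHZ_AMU_A2",
    "ELECTRON_PROTON_MASS_RATIO",
    "RotationalConstants",
    "ConstantsRecord",
    "GTensorDiagonal",
    "LinearMoleculeWarning",
    "equilibrium_constants",
    "inertia_moments",
    "inertia_defect",
    "vibrational_shift",
    "electronic_shift",
    "assemble_ground_state",
]

#: h / (8 pi^2) in MHz * amu * Å^2, from CODATA h and the 2022 amu;
#: frozen to 10 significant digits for cross-platform reproducibility.
KAPPA_MHZ_AMU_A2 = 505379.0084

#: m_e / M_p (CODATA 2022).
ELECTRON_PROTON_MASS_RATIO = 5.446170215e-4

#: Moments smaller than this fraction of the largest are treated as zero
#: (linear molecule).
_LINEAR_TOL = 1e-10


class LinearMoleculeWarning(UserWarning):
    pass


class RotationalConstants(NamedTuple):
    """Principal constants in MHz, descending (a is inf for linear tops)."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class GTensorDiagonal:
    """Diagonal rotational g-tensor, nuclear-magneton units."""

    g_aa: float
    g_bb: float
    g_cc: float

    def __post_init__(self) -> None:
        for g in (self.g_aa, self.g_bb, self.g_cc):
            if not math.isfinite(g):
                raise ValueError("g-tensor elements must be finite")


@dataclass(frozen=True)
class ConstantsRecord:
    """One axis of one molecule: equilibrium constant plus corrections.

    All values in MHz.  ``b0`` is the assembled ground-state estimate
    B_eq + dB_CVB + dB_VB + dB_vib — the electronic term is excluded by
    convention and kept only for reporting.
    """

    molecule: str
    axis: str
    b_eq: float
    delta_cvb: float | None = None
    delta_vb: float | None = None
    delta_vib: float | None = None
    delta_el: float | None = None
    b0: float | None = None
    b_exp: float | None = None

    def __post_init__(self) -> None:
        if self.axis not in ("a", "b", "c"):
            raise ValueError("axis must be one of a, b, c")


def inertia_moments(
    geometry: Geometry, masses: Iterable[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Principal moments (amu Å², ascending) and axes (columns).

    Masses default to the most-abundant-isotope values carried by the
    geometry's atoms; pass an explicit sequence for isotopologues.
    """
    m = np.asarray(list(masses) if masses is not None else geometry.masses)
    if len(m) != geometry.n_atoms:
        raise ValueError("one mass per atom required")
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    x = geometry.coordinates - np.average(
        geometry.coordinates, axis=0, weights=m
    )
    r2 = np.sum(x**2, axis=1)
    tensor = np.einsum("n,ij->ij", m * r2, np.eye(3)) - np.einsum(
        "n,ni,nj->ij", m, x, x
    )
    moments, axes = np.linalg.eigh(tensor)
    return moments, axes


def equilibrium_constants(
    geometry: Geometry, masses: Iterable[float] | None = None
) -> RotationalConstants:
    """Rigid-rotor constants of a geometry, MHz, sorted A >= B >= C.

    Invariant under rigid motions and atom reordering; scales as
    1/lambda² under uniform coordinate scaling by lambda.  A linear
    molecule yields ``a = inf`` (with a warning) and ``b = c``; a
    single atom has no defined constants and raises.
    """
    if geometry.n_atoms < 2:
        raise ValueError("rotational constants undefined for a single atom")
    moments, _ = inertia_moments(geometry, masses)
    largest = moments[-1]
    if largest <= 0:
        raise ValueError("degenerate mass distribution")
    out = []
    for i_val in moments:
        if i_val < _LINEAR_TOL * largest:
            warnings.warn(
                "vanishing principal moment: linear molecule, A reported "
                "as infinite",
                LinearMoleculeWarning,
                stacklevel=2,
            )
            out.append(math.inf)
        else:
            out.append(KAPPA_MHZ_AMU_A2 / float(i_val))
    out.sort(reverse=True)
    return RotationalConstants(*out)


def inertia_defect(
    geometry: Geometry, masses: Iterable[float] | None = None
) -> float:
    """Inertia defect Delta = I_c - I_a - I_b (amu Å²); ~0 for planar bodies."""
    moments, _ = inertia_moments(geometry, masses)
    return float(moments[2] - moments[1] - moments[0])


def vibrational_shift(alphas: Iterable[float]) -> float:
    """Vibrational correction dB_vib = -1/2 sum_r alpha_r (MHz).

    ``alphas`` are the vibration-rotation interaction constants of one
    inertial axis, one per vibrational mode.  An empty list yields 0
    with a warning (a polyatomic should have 3N-6 of them).
    """
    values = [float(a) for a in alphas]
    if not all(math.isfinite(v) for v in values):
        raise ValueError("alpha constants must be finite")
    if not values:
        warnings.warn("no alpha constants supplied; dB_vib = 0", stacklevel=2)
        return 0.0
    return -0.5 * sum(values)


def electronic_shift(b: float, g: float) -> float:
    """Electronic correction dB_el = (m_e/M_p) * g * B (MHz).

    Linear in both arguments and bounded by ~5.45e-4 * |g| * B; the
    correction carries the sign of g.
    """
    if not (math.isfinite(b) and math.isfinite(g)):
        raise ValueError("inputs must be finite")
    return ELECTRON_PROTON_MASS_RATIO * g * b


def assemble_ground_state(record: ConstantsRecord) -> ConstantsRecord:
    """Fill ``b0 = b_eq + delta_cvb + delta_vb + delta_vib``.

    The electronic term is retained separately and never folded in.
    Missing components raise rather than defaulting to zero.
    """
    missing = [
        name
        for name in ("delta_cvb", "delta_vb", "delta_vib")
        if getattr(record, name) is None
    ]
    if missing:
        raise ValueError(
            f"cannot assemble B0 for {record.molecule}/{record.axis}: "
            f"missing {', '.join(missing)}"
        )
    b0 = record.b_eq + record.delta_cvb + record.delta_vb + record.delta_vib
    return replace(record, b0=b0)
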