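"""Per-element reference constants.

The correction formulas and the inertia tensor need three numbers per
element: the period (principal quantum number of the valence shell), a
single-bond covalent radius, and an atomic mass.  The supported set is
deliberately small — H, C, N, O, S — matching the organic molecules the
method was calibrated on; any other symbol raises
:class:`UnsupportedElementError` rather than silently extrapolating.

Covalent radii default to the Cordero et al. (2008) single-bond values
(for carbon the generic 0.76 Å radius, not the hybridization-specific
ones).  Masses are those of the most abundant isotope (1H, 12C, 14N,
16O, 32S), so that computed rotational constants refer to the parent
isotopologue measured in microwave work.  Both tables can be overridden
per call for isotopologue or sensitivity studies, but the defaults are
immutable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Element",
    "UnsupportedElementError",
    "lookup_element",
    "COVALENT_RADII",
    "ISOTOPE_MASSES",
    "PERIODS",
    "ATOMIC_NUMBERS",
    "element_from_atomic_number",
]


class UnsupportedElementError(ValueError):
    """Raised for element symbols outside the supported H/C/N/O/S set."""


@dataclass(frozen=True)
class Element:
    """Immutable per-species constants.

    Attributes
    ----------
    symbol : str
        Chemical symbol, canonical capitalization.
    atomic_number : int
        Nuclear charge.
    principal_quantum_number : int
        Period of the element; enters the core-valence correction through
        the product ``n_i * n_j``.
    covalent_radius : float
        Single-bond covalent radius in Å; enters both the Pauling bond
        order and the core-valence correction.
    mass : float
        Most-abundant-isotope mass in unified amu.
    """

    symbol: str
    atomic_number: int
    principal_quantum_number: int
    covalent_radius: float
    mass: float

    def __post_init__(self) -> None:
        if self.principal_quantum_number < 1:
            raise ValueError("principal quantum number must be >= 1")
        if self.covalent_radius <= 0 or self.mass <= 0:
            raise ValueError("covalent radius and mass must be positive")


# Cordero et al., Dalton Trans. 2008 single-bond radii (Å).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
}

# Hybridization-specific carbon radii from the same source, exposed for
# sensitivity checks; the generic value above is the default everywhere.
CARBON_RADII_BY_HYBRIDIZATION: dict[str, float] = {
    "sp3": 0.76,
    "sp2": 0.73,
    "sp": 0.69,
}

# Most abundant isotope masses, unified amu (AME2020).
ISOTOPE_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207117,
}

PERIODS: dict[str, int] = {"H": 1, "C": 2, "N": 2, "O": 2, "S": 3}

ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}

_BY_NUMBER = {z: s for s, z in ATOMIC_NUMBERS.items()}

_CACHE: dict[tuple, Element] = {}


def lookup_element(
    symbol: str,
    *,
    covalent_radius: float | None = None,
    mass: float | None = None,
) -> Element:
    """Return the reference record for ``symbol``.

    Parameters
    ----------
    symbol : str
        Chemical symbol; case is normalized ("c", "C" and " C " agree).
    covalent_radius, mass : float, optional
        Per-call overrides of the default tables (e.g. deuterium via
        ``mass=2.0141``); the defaults themselves are never mutated.

    Raises
    ------
    UnsupportedElementError
        If the symbol is not one of H, C, N, O, S.
    """
    key = symbol.strip().capitalize()
    if key not in COVALENT_RADII:
        raise UnsupportedElementError(
            f"element {symbol!r} is not supported (supported: H, C, N, O, S)"
        )
    cache_key = (key, covalent_radius, mass)
    if cache_key not in _CACHE:
        _CACHE[cache_key] = Element(
            symbol=key,
            atomic_number=ATOMIC_NUMBERS[key],
            principal_quantum_number=PERIODS[key],
            covalent_radius=(
                COVALENT_RADII[key] if covalent_radius is None else covalent_radius
            ),
            mass=ISOTOPE_MASSES[key] if mass is None else mass,
        )
    return _CACHE[cache_key]


def element_from_atomic_number(z: int) -> Element:
    """Map an atomic number (as printed in QC-engine logs) to an Element."""
    if z not in _BY_NUMBER:
        raise UnsupportedElementError(
            f"atomic number {z} is not supported (supported: 1, 6, 7, 8, 16)"
        )
    return lookup_element(_BY_NUMBER[z])
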