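"""Per-bond length corrections (the PCS/Bonds recipe).

Starting from a double-hybrid DFT optimized structure, each bond length
is shifted by two small additive terms,

    r_target = r + Δr_CVB + Δr_VB ,

where Δr_CVB accounts for core-valence correlation (absent in
frozen-core optimizations) and Δr_VB mops up the residual valence
error of the functional, which for the reference rDSD/3F12- level is
non-negligible only for multiple carbon-carbon bonds.

Core-valence term.  CV correlation contracts bonds by a few mÅ, more so
the deeper the cores involved.  With ``n_i`` the period of atom *i* and
``n_ij = n_i * n_j``,

    Δr_CVB = -k * sqrt(n_ij - 1) * (r_i^cov + r_j^cov),   k = 0.0011 ,

which vanishes identically for bonds between hydrogen-row atoms
(n_ij = 1) and uses covalent radii rather than the actual bond length,
making the estimate independent of the electronic-structure method that
produced the geometry.

Valence term.  With ``P`` the Pauling bond order computed from the
actual geometry,

    Δr_VB = a * (P**2 - 1) * [both atoms are carbon],   a = 0.0007 ,

a smooth positive stretch that vanishes for single bonds (P near 1) and
grows for aromatic, double and triple CC bonds, countering DFT's slight
overestimation of conjugation.  Precise order values are not critical;
only their rough magnitude matters.

Valence and dihedral angles receive no correction: CV effects on angles
are entirely negligible at this level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .connectivity import Bond, InternalCoordinateSet
from .elements import Element
from .geometry import Geometry

__all__ = [
    "CV_CORRECTION_K",
    "VB_CORRECTION_COEFF",
    "BondCorrection",
    "delta_r_cvb",
    "delta_r_vb",
    "corrected_bond_targets",
    "corrections_report",
]

#: One-parameter core-valence coefficient k (Å per Å of radii sum).
CV_CORRECTION_K = 0.0011

#: Valence-correction coefficient for multiple CC bonds (Å).
VB_CORRECTION_COEFF = 0.0007


@dataclass(frozen=True)
class BondCorrection:
    """Correction bookkeeping for a single bond.

    ``target_length = bond.length + delta_cvb + delta_vb`` holds as an
    exact arithmetic identity; ``n_product`` is n_i * n_j.
    """

    bond: Bond
    delta_cvb: float
    delta_vb: float
    target_length: float
    n_product: int

    def __post_init__(self) -> None:
        if self.target_length <= 0:
            raise ValueError("corrected bond length must stay positive")


def delta_r_cvb(
    e_i: Element, e_j: Element, *, k: float = CV_CORRECTION_K
) -> float:
    """Core-valence bond-length correction (Å), symmetric in its arguments.

    Zero for hydrogen-row pairs; always non-positive (CV correlation
    contracts bonds).  Depends only on element identities, not on the
    bond length.
    """
    n_ij = e_i.principal_quantum_number * e_j.principal_quantum_number
    return -k * (n_ij - 1) ** 0.5 * (e_i.covalent_radius + e_j.covalent_radius)


def delta_r_vb(
    bond: Bond,
    e_i: Element,
    e_j: Element,
    *,
    coefficient: float = VB_CORRECTION_COEFF,
) -> float:
    """Valence bond-length correction (Å); nonzero only for C-C bonds.

    Uses the Pauling order carried by the bond (computed from the input
    geometry, not an assigned formal order).
    """
    if e_i.symbol != "C" or e_j.symbol != "C":
        return 0.0
    if bond.order <= 1.0:
        return 0.0
    return coefficient * (bond.order**2 - 1.0)


def corrected_bond_targets(
    geometry: Geometry,
    internals: InternalCoordinateSet,
    *,
    k: float = CV_CORRECTION_K,
    vb_coefficient: float = VB_CORRECTION_COEFF,
) -> tuple[BondCorrection, ...]:
    """One :class:`BondCorrection` per bond of the internal set.

    Angles are untouched; only the bond list is read.
    """
    out = []
    for bond in internals.bonds:
        e_i, e_j = geometry.atoms[bond.i], geometry.atoms[bond.j]
        cvb = delta_r_cvb(e_i, e_j, k=k)
        vb = delta_r_vb(bond, e_i, e_j, coefficient=vb_coefficient)
        out.append(
            BondCorrection(
                bond=bond,
                delta_cvb=cvb,
                delta_vb=vb,
                target_length=bond.length + cvb + vb,
                n_product=(
                    e_i.principal_quantum_number * e_j.principal_quantum_number
                ),
            )
        )
    return tuple(out)


def corrections_report(
    geometry: Geometry, corrections: tuple[BondCorrection, ...]
) -> str:
    """Tab-separated per-bond correction table."""
    lines = ["pair\tlength_A\torder\tdelta_cvb_A\tdelta_vb_A\ttarget_A"]
    for c in corrections:
        si = geometry.atoms[c.bond.i].symbol
        sj = geometry.atoms[c.bond.j].symbol
        lines.append(
            f"{si}{c.bond.i + 1}-{sj}{c.bond.j + 1}\t{c.bond.length:.4f}\t"
            f"{c.bond.order:.3f}\t{c.delta_cvb:+.4f}\t{c.delta_vb:+.4f}\t"
            f"{c.target_length:.4f}"
        )
    return "\n".join(lines) + "\n"
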