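"""Molecular geometry container and XYZ / QC-log readers.

A :class:`Geometry` is an ordered list of atoms with Cartesian
coordinates in Å — the object every stage of the pipeline transforms.
Input comes either from a standard XYZ file or from the last
orientation block of a quantum-chemistry engine log (the final
optimized structure).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .elements import Element, element_from_atomic_number, lookup_element

__all__ = [
    "Geometry",
    "GeometryParseError",
    "read_xyz",
    "write_xyz",
    "read_engine_orientation",
]


class GeometryParseError(ValueError):
    """Malformed XYZ or log content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Geometry:
    """Ordered atoms plus per-atom Cartesian coordinates (Å).

    ``coordinates`` is an (N, 3) float array; a defensive copy is taken
    and the stored array is marked read-only, so a Geometry is a value
    object.  Construction fails if coordinates are non-finite, the atom
    and coordinate counts disagree, or two atoms sit closer than 0.1 Å
    (pass ``degenerate=True`` to admit such pathological inputs
    knowingly, e.g. for error-path tests).
    """

    atoms: tuple[Element, ...]
    coordinates: np.ndarray
    label: str = ""
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.array(self.coordinates, dtype=float).reshape(-1, 3)
        if len(coords) != len(self.atoms):
            raise ValueError(
                f"{len(self.atoms)} atoms but {len(coords)} coordinate rows"
            )
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if not self.degenerate and len(coords) > 1:
            diff = coords[:, None, :] - coords[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            if dist.min() <= 0.1:
                i, j = np.unravel_index(int(dist.argmin()), dist.shape)
                raise ValueError(
                    f"atoms {i} and {j} nearly coincide ({dist.min():.3f} Å)"
                )
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(a.symbol for a in self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))

    def with_coordinates(self, coordinates: np.ndarray) -> "Geometry":
        """Same atoms and label, new coordinates."""
        return Geometry(self.atoms, coordinates, self.label, self.degenerate)


def read_xyz(text: str) -> Geometry:
    """Parse standard XYZ content into a Geometry.

    First line: atom count; second line: free-form comment (kept as the
    geometry label); then one ``symbol x y z`` line per atom, in Å.
    Errors cite the 1-based line number of the offending line.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise GeometryParseError("missing atom-count line", line=1)
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise GeometryParseError(
            f"atom count expected, got {lines[0].strip()!r}", line=1
        ) from None
    if count < 0:
        raise GeometryParseError("negative atom count", line=1)
    label = lines[1].rstrip() if len(lines) > 1 else ""
    atoms: list[Element] = []
    coords: list[list[float]] = []
    for n in range(count):
        lineno = 3 + n
        if lineno - 1 >= len(lines) or not lines[lineno - 1].strip():
            last = min(lineno, len(lines))  # cite the last line present
            raise GeometryParseError(
                f"declared {count} atoms but file ends after {n}", line=last
            )
        parts = lines[lineno - 1].split()
        if len(parts) < 4:
            raise GeometryParseError(
                f"expected 'symbol x y z', got {lines[lineno - 1]!r}", line=lineno
            )
        try:
            atoms.append(lookup_element(parts[0]))
        except ValueError as exc:
            raise GeometryParseError(str(exc), line=lineno) from exc
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise GeometryParseError(
                f"non-numeric coordinate in {lines[lineno - 1]!r}", line=lineno
            ) from None
    return Geometry(tuple(atoms), np.array(coords).reshape(-1, 3), label=label)


def write_xyz(geometry: Geometry, *, decimals: int = 8) -> str:
    """Serialize to XYZ text (element symbols, >= 6 decimals)."""
    if decimals < 6:
        raise ValueError("XYZ output keeps at least 6 decimals")
    out = [str(geometry.n_atoms), geometry.label]
    for atom, xyz in zip(geometry.atoms, geometry.coordinates):
        out.append(
            f"{atom.symbol:<2s} "
            + " ".join(f"{c:{decimals + 7}.{decimals}f}" for c in xyz)
        )
    return "\n".join(out) + "\n"


_ORIENTATION_HEADER = re.compile(r"(Standard|Input|Z-Matrix) orientation")
_DASHES = re.compile(r"^\s*-{10,}\s*$")


def read_engine_orientation(text: str) -> Geometry:
    """Geometry from the LAST orientation block of a Gaussian-style log.

    Orientation blocks look like::

        Standard orientation:
        ---------------------------------------------------------------
        Center  Atomic  Atomic           Coordinates (Angstroms)
        Number  Number   Type        X           Y           Z
        ---------------------------------------------------------------
           1       6       0        0.000000    0.000000    0.000000
        ...
        ---------------------------------------------------------------

    Only these blocks are parsed; the last one is the final optimized
    structure.  A truncated block raises rather than returning a silent
    partial geometry.
    """
    lines = text.splitlines()
    block_starts = [
        i for i, ln in enumerate(lines) if _ORIENTATION_HEADER.search(ln)
    ]
    if not block_starts:
        raise GeometryParseError("no orientation block found in log content")
    start = block_starts[-1]
    # Skip header: dashes, two title lines, dashes.
    i = start + 1
    dash_count = 0
    while i < len(lines) and dash_count < 2:
        if _DASHES.match(lines[i]):
            dash_count += 1
        i += 1
    if dash_count < 2:
        raise GeometryParseError(
            "orientation block header truncated", line=start + 1
        )
    atoms: list[Element] = []
    coords: list[list[float]] = []
    closed = False
    while i < len(lines):
        if _DASHES.match(lines[i]):
            closed = True
            break
        parts = lines[i].split()
        if len(parts) < 6:
            raise GeometryParseError(
                f"malformed orientation row {lines[i]!r}", line=i + 1
            )
        try:
            z = int(parts[1])
            xyz = [float(p) for p in parts[-3:]]
        except ValueError:
            raise GeometryParseError(
                f"malformed orientation row {lines[i]!r}", line=i + 1
            ) from None
        atoms.append(element_from_atomic_number(z))
        coords.append(xyz)
        i += 1
    if not closed:
        raise GeometryParseError("orientation block truncated", line=len(lines))
    if not atoms:
        raise GeometryParseError("orientation block is empty", line=start + 1)
    return Geometry(
        tuple(atoms), np.array(coords), label="engine log orientation"
    )
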