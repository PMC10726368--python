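"""Error statistics of computed vs experimental rotational constants.

Accuracy is quoted as unsigned relative errors in percent: per-constant
``100 |calc - exp| / exp``, summarized by their mean (MUE%) and maximum
(MAX%) over a benchmark set, and visualized as a normal-distribution
error profile

    rho(x) = N_c * exp(-(x - d_av)^2 / (2 d_std^2)) ,

where ``d_av`` and ``d_std`` are the mean and standard deviation of the
relative errors and ``N_c`` normalizes the density to unit area.  By
default the profile is built from the unsigned errors (matching the
"relative unsigned mean error" convention); a signed variant is
available since systematic over/underestimation is visible only there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tables import BenchmarkRow, load_builtin_table

__all__ = [
    "ErrorProfile",
    "percent_error",
    "summary_stats",
    "table_stats",
    "per_row_errors",
    "load_builtin_table",
]


def percent_error(calculated: float, experimental: float) -> float:
    """Unsigned relative deviation in percent, 100|calc - exp|/exp."""
    if experimental == 0:
        raise ValueError("experimental value must be nonzero")
    return 100.0 * abs(calculated - experimental) / experimental


@dataclass(frozen=True)
class ErrorProfile:
    """Gaussian error profile over the percent-error axis."""

    delta_av: float
    delta_std: float
    normalization: float

    def __post_init__(self) -> None:
        if self.delta_std < 0:
            raise ValueError("standard deviation cannot be negative")

    def density(self, x) -> np.ndarray:
        """Profile values at percent-error abscissae ``x``."""
        x = np.asarray(x, dtype=float)
        if self.delta_std == 0:
            return np.where(np.isclose(x, self.delta_av), np.inf, 0.0)
        z = (x - self.delta_av) / self.delta_std
        return self.normalization * np.exp(-0.5 * z**2)


def _profile(errors: np.ndarray) -> ErrorProfile:
    av = float(np.mean(errors))
    std = float(np.std(errors, ddof=1)) if len(errors) > 1 else 0.0
    norm = 1.0 / (std * math.sqrt(2 * math.pi)) if std > 0 else math.inf
    return ErrorProfile(delta_av=av, delta_std=std, normalization=norm)


def summary_stats(
    pairs: Iterable[tuple[float, float]], *, signed_profile: bool = False
) -> tuple[float, float, ErrorProfile]:
    """MUE%, MAX% and the error profile of (calculated, experimental) pairs.

    Invariant under reordering of the pairs.  With
    ``signed_profile=True`` the Gaussian is fitted to the signed
    relative errors instead of the unsigned ones (MUE/MAX are always
    unsigned).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one (calculated, experimental) pair needed")
    unsigned = np.array([percent_error(c, e) for c, e in pairs])
    if signed_profile:
        signed = np.array([100.0 * (c - e) / e for c, e in pairs])
        profile = _profile(signed)
    else:
        profile = _profile(unsigned)
    return float(unsigned.mean()), float(unsigned.max()), profile


def per_row_errors(
    rows: Sequence[BenchmarkRow], column: str = "tot"
) -> list[tuple[BenchmarkRow, float]]:
    """Percent error of each row's chosen column against experiment."""
    out = []
    for row in rows:
        calc = row.total if column == "tot" else row.b_eq
        out.append((row, percent_error(calc, row.experiment)))
    return out


def table_stats(
    name: str,
    column: str = "tot",
    *,
    honor_exclusions: bool = True,
    signed_profile: bool = False,
) -> tuple[float, float, ErrorProfile]:
    """Footer statistics of a builtin benchmark table.

    ``column`` selects the corrected totals ("tot") or the uncorrected
    equilibrium constants ("rdsd").  ``honor_exclusions`` drops the rows
    the source excludes from its own footers (the phenanthrene outlier).
    """
    if column not in ("tot", "rdsd"):
        raise ValueError("column must be 'tot' or 'rdsd'")
    rows = load_builtin_table(name)
    if not rows or not isinstance(rows[0], BenchmarkRow):
        raise ValueError(f"{name} is not a rotational-constant table")
    kept = [r for r in rows if not (honor_exclusions and r.excluded)]
    pairs = [
        (r.total if column == "tot" else r.b_eq, r.experiment) for r in kept
    ]
    return summary_stats(pairs, signed_profile=signed_profile)
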