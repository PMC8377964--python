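"""Discrete molecular-weight distributions and their summary statistics.

Hyaluronan preparations are polydisperse: a sample is a mixture of chains
spanning orders of magnitude in mass.  Both the gel-densitometry and the
nanopore stages reduce their raw signal to a discretized molecular-weight
distribution, summarized by the weight-average molecular weight

    Mw = sum_i(w_i * M_i) / sum_i(w_i),

the number-average molecular weight

    Mn = sum_i(w_i) / sum_i(w_i / M_i),

and the polydispersity index PDI = Mw / Mn >= 1, where ``w_i`` is the mass
(not molar) abundance at grid mass ``M_i``.  Stain intensity on a gel is
mass-proportional, so gel profiles enter as mass weights directly; nanopore
events are counted per molecule and are converted (``number_to_mass``)
before the same formulas apply.

Masses are in kDa throughout; ``from_da`` converts on input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MWDistribution",
    "InvalidDistributionError",
    "weight_average_mw",
    "number_average_mw",
    "polydispersity",
    "complex_mass",
    "number_to_mass",
]


class InvalidDistributionError(ValueError):
    """Raised when a distribution violates its invariants."""


@dataclass(frozen=True)
class MWDistribution:
    """A discretized molecular-weight distribution.

    Parameters
    ----------
    masses:
        Strictly positive, strictly ascending grid of molecular weights, kDa.
    weights:
        Non-negative abundance per grid point with at least one positive
        entry.  Interpretation is set by ``weighting``: ``"mass"`` means
        mass-proportional abundance (the convention for stain intensity),
        ``"number"`` means molecule counts.
    """

    masses: np.ndarray
    weights: np.ndarray
    weighting: Literal["mass", "number"] = "mass"

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "weights", weights)
        if masses.ndim != 1 or weights.ndim != 1:
            raise InvalidDistributionError("masses and weights must be 1-D")
        if len(masses) != len(weights):
            raise InvalidDistributionError(
                f"length mismatch: {len(masses)} masses vs {len(weights)} weights"
            )
        if len(masses) == 0:
            raise InvalidDistributionError("empty distribution")
        if not np.all(np.isfinite(masses)) or not np.all(np.isfinite(weights)):
            raise InvalidDistributionError("non-finite mass or weight")
        if np.any(masses <= 0):
            raise InvalidDistributionError("all masses must be > 0")
        if np.any(np.diff(masses) <= 0):
            raise InvalidDistributionError("masses must be strictly ascending")
        if np.any(weights < 0):
            raise InvalidDistributionError("weights must be non-negative")
        if not np.any(weights > 0):
            raise InvalidDistributionError("all weights are zero")
        if self.weighting not in ("mass", "number"):
            raise InvalidDistributionError(f"unknown weighting {self.weighting!r}")

    @classmethod
    def from_da(
        cls,
        masses_da: Sequence[float],
        weights: Sequence[float],
        weighting: Literal["mass", "number"] = "mass",
    ) -> "MWDistribution":
        """Build a distribution from masses given in Da."""
        return cls(np.asarray(masses_da, dtype=float) / 1000.0, np.asarray(weights), weighting)

    # -- serialization -------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write as CSV with a ``# weighting:`` metadata line."""
        header = f"# weighting: {self.weighting}\nmass_kda,weight\n"
        body = "".join(f"{m:.17g},{w:.17g}\n" for m, w in zip(self.masses, self.weights))
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + body)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + body)

    @classmethod
    def read_csv(cls, path_or_buf) -> "MWDistribution":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = text.splitlines()
        weighting = "mass"
        rows = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "weighting:" in line:
                    weighting = line.split("weighting:")[1].strip()
                continue
            if line.startswith("mass_kda"):
                continue
            m, w = line.split(",")
            rows.append((float(m), float(w)))
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], weighting)  # type: ignore[arg-type]


def _require_mass_weighted(d: MWDistribution) -> None:
    if d.weighting != "mass":
        raise InvalidDistributionError(
            "summary statistics are defined on mass weighting; "
            "convert number-weighted data with number_to_mass() first"
        )


def weight_average_mw(d: MWDistribution) -> float:
    """Weight-average molecular weight Mw = sum(w*M)/sum(w), kDa.

    Invariant to uniform rescaling of the weights.
    """
    _require_mass_weighted(d)
    return float(np.sum(d.weights * d.masses) / np.sum(d.weights))


def number_average_mw(d: MWDistribution) -> float:
    """Number-average molecular weight Mn = sum(w)/sum(w/M), kDa."""
    _require_mass_weighted(d)
    return float(np.sum(d.weights) / np.sum(d.weights / d.masses))


def polydispersity(d: MWDistribution) -> float:
    """Polydispersity index PDI = Mw/Mn (dimensionless, >= 1)."""
    return weight_average_mw(d) / number_average_mw(d)


def complex_mass(component_masses: Sequence[float]) -> float:
    """Theoretical mass of a covalent complex: the sum of its components, kDa.

    E.g. one heavy chain (75 kDa) on a 150 kDa HA chain gives a 225 kDa
    HC-HA complex.
    """
    masses = np.asarray(list(component_masses), dtype=float)
    if masses.size == 0:
        raise ValueError("component_masses must be non-empty")
    if np.any(masses <= 0) or not np.all(np.isfinite(masses)):
        raise ValueError("component masses must be positive and finite")
    return float(masses.sum())


def number_to_mass(d: MWDistribution) -> MWDistribution:
    """Convert a number-weighted distribution to mass weighting (w_i ∝ n_i·M_i)."""
    if d.weighting == "mass":
        return d
    return MWDistribution(d.masses, d.weights * d.masses, "mass")
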