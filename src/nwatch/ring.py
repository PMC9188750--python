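"""Periodic 1-D ring of marginal zone cells and bead perturbations.

The marginal zone is modelled as a ring of ``n_cells`` cells (default
600).  Cell 0 sits at the posterior pole (the endogenous streak site) and
cell ``n_cells // 2`` at the anterior pole.  Each cell carries two
non-negative concentration proxies: ``V`` for the streak inducer
(cVG1/ACTIVIN -> SMAD2/3) and ``B`` for the inhibitor (BMP -> SMAD1/5/8).

Baseline profiles reflect the expression patterns at pre-streak stages: a
posterior Gaussian crescent of inducer and a shallow, anterior-high
parabola of inhibitor.  A grafted bead or cell pellet adds (or, for an
antagonist, subtracts) a constant amount over its footprint, decaying
exponentially with distance beyond the footprint edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Footprint width in cells of a ~100 um microbead (1 cell ~ 12 um).
MICROBEAD_WIDTH = 9
#: Footprint width in cells of a 500-1000 cell pellet.
PELLET_WIDTH = 27

COMPOUNDS = ("inducer_source", "inhibitor_source", "inhibitor_antagonist", "neutral")


def ring_distance(i, j, n_cells: int):
    """Shortest distance between cells ``i`` and ``j`` on a periodic ring.

    Accepts scalars or arrays; result is ``min(|i-j|, n_cells-|i-j|)``.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(i >= n_cells) or np.any(j < 0) or np.any(j >= n_cells):
        raise IndexError(f"cell index out of range for ring of {n_cells} cells")
    d = np.abs(i - j)
    out = np.minimum(d, n_cells - d)
    return out if out.ndim else int(out)


@dataclass(frozen=True)
class BaselineProfileParams:
    """Shape parameters of the unperturbed inducer/inhibitor profiles.

    The absolute amplitude is irrelevant downstream (it is absorbed by the
    inferred scalings ``a_V`` and ``a_B``); only the shapes matter.
    """

    inducer_peak_cell: int = 0
    inducer_sigma: float = 40.0
    inducer_amplitude: float = 1.0
    inhibitor_min: float = 0.1
    inhibitor_max: float = 1.0

    def __post_init__(self) -> None:
        if self.inducer_sigma <= 0:
            raise ValueError("inducer_sigma must be > 0")
        if self.inducer_amplitude <= 0:
            raise ValueError("inducer_amplitude must be > 0")
        if not (0 <= self.inhibitor_min <= self.inhibitor_max):
            raise ValueError("require 0 <= inhibitor_min <= inhibitor_max")


@dataclass(frozen=True)
class BeadSpec:
    """A perturbation source grafted onto the ring.

    ``compound`` selects the target profile: an ``inducer_source`` adds to
    V, an ``inhibitor_source`` adds to B, an ``inhibitor_antagonist``
    (e.g. dorsomorphin) subtracts from B, and a ``neutral`` control bead
    does nothing.  The added amount is ``concentration`` across the
    ``width``-cell footprint and ``concentration * exp(-d / spread)`` for
    a cell ``d`` cells beyond the footprint edge.
    """

    compound: str
    center: int
    width: int = MICROBEAD_WIDTH
    concentration: float = 1.0
    spread: float = 5.0

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be a positive odd integer")
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    def delta(self, n_cells: int) -> np.ndarray:
        """Signed per-cell change this bead induces on its target profile."""
        d = ring_distance(np.arange(n_cells), self.center, n_cells)
        beyond = np.maximum(d - self.width // 2, 0)
        mag = self.concentration * np.exp(-beyond / self.spread)
        if self.compound == "neutral":
            return np.zeros(n_cells)
        sign = -1.0 if self.compound == "inhibitor_antagonist" else 1.0
        return sign * mag

    def targets_inducer(self) -> bool:
        return self.compound == "inducer_source"


@dataclass
class RingField:
    """Per-cell inducer (V) and inhibitor (B) levels on the ring."""

    n_cells: int
    V: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if len(self.V) != self.n_cells or len(self.B) != self.n_cells:
            raise ValueError("V and B must each have length n_cells")
        if np.any(self.V < 0) or np.any(self.B < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def zeros(cls, n_cells: int) -> "RingField":
        return cls(n_cells, np.zeros(n_cells), np.zeros(n_cells))

    @property
    def anterior_pole(self) -> int:
        return self.n_cells // 2

    def anterior_half(self) -> np.ndarray:
        """Cells closer to the anterior pole than n_cells/4 (the graft region)."""
        idx = np.arange(self.n_cells)
        d = ring_distance(idx, self.anterior_pole, self.n_cells)
        return idx[d < self.n_cells // 4]

    def copy(self) -> "RingField":
        return RingField(self.n_cells, self.V.copy(), self.B.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_index": np.arange(self.n_cells), "V": self.V, "B": self.B}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_baseline(
    params: BaselineProfileParams = BaselineProfileParams(), n_cells: int = 600
) -> RingField:
    """Build the unperturbed field: Gaussian inducer, parabolic inhibitor.

    ``V_i = A exp(-d_i^2 / (2 sigma^2))`` with ``d_i`` the ring distance to
    the inducer peak (posterior pole); ``B_i`` rises quadratically from
    ``inhibitor_min`` at that pole to ``inhibitor_max`` at the antipode.
    """
    idx = np.arange(n_cells)
    d = ring_distance(idx, params.inducer_peak_cell % n_cells, n_cells).astype(float)
    V = params.inducer_amplitude * np.exp(-(d**2) / (2 * params.inducer_sigma**2))
    half = n_cells // 2
    B = params.inhibitor_min + (params.inhibitor_max - params.inhibitor_min) * (
        d / half
    ) ** 2
    return RingField(n_cells, V, B)


def _summed_deltas(n_cells: int, beads: Iterable[BeadSpec]):
    dV = np.zeros(n_cells)
    dB = np.zeros(n_cells)
    for bead in beads:
        delta = bead.delta(n_cells)
        if bead.targets_inducer():
            dV += delta
        else:
            dB += delta
    return dV, dB


def apply_design(field: RingField, beads: Sequence[BeadSpec]) -> RingField:
    """Apply a layout of beads; effects sum, then clamp at zero.

    Additive before clamping, hence order-independent.  The input field is
    not modified.
    """
    dV, dB = _summed_deltas(field.n_cells, beads)
    return RingField(
        field.n_cells,
        np.maximum(field.V + dV, 0.0),
        np.maximum(field.B + dB, 0.0),
    )


def apply_bead(field: RingField, bead: BeadSpec) -> RingField:
    """Apply one bead to the field (returns a new field)."""
    return apply_design(field, [bead])


# ---------------------------------------------------------------------------
# YAML round-trip for fields-with-design configs


def bead_to_dict(bead: BeadSpec) -> dict:
    return {
        "compound": bead.compound,
        "center": int(bead.center),
        "width": int(bead.width),
        "concentration": float(bead.concentration),
        "spread": float(bead.spread),
    }


def bead_from_dict(d: dict) -> BeadSpec:
    return BeadSpec(
        compound=d["compound"],
        center=int(d["center"]),
        width=int(d["width"]),
        concentration=float(d["concentration"]),
        spread=float(d["spread"]),
    )


def baseline_to_dict(p: BaselineProfileParams) -> dict:
    return {
        "inducer_peak_cell": int(p.inducer_peak_cell),
        "inducer_sigma": float(p.inducer_sigma),
        "inducer_amplitude": float(p.inducer_amplitude),
        "inhibitor_min": float(p.inhibitor_min),
        "inhibitor_max": float(p.inhibitor_max),
    }


def baseline_from_dict(d: dict) -> BaselineProfileParams:
    return BaselineProfileParams(**d)


def config_dump(
    n_cells: int,
    baseline: BaselineProfileParams,
    beads: Sequence[BeadSpec],
    stream=None,
) -> str | None:
    doc = {
        "n_cells": int(n_cells),
        "baseline": baseline_to_dict(baseline),
        "beads": [bead_to_dict(b) for b in beads],
    }
    return yaml.safe_dump(doc, stream, sort_keys=False)


def config_load(stream):
    doc = yaml.safe_load(stream)
    return (
        int(doc["n_cells"]),
        baseline_from_dict(doc["baseline"]),
        [bead_from_dict(b) for b in doc.get("beads", [])],
    )
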