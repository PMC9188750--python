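"""Per-cell SMAD-value and the two rival streak-initiation rules.

Inducer- and inhibitor-linked SMAD complexes compete for a fixed pool of
SMAD4.  With scaled concentrations ``a_V V_i`` and ``a_B B_i`` the total
SMAD4 partitions as ``1 + a_V V_i + a_B B_i`` (unbound, inducer-bound,
inhibitor-bound), so the proportion of streak-inducing complex — the
SMAD-value — is

    F_i = a_V V_i / (1 + a_V V_i + a_B B_i),          0 <= F_i < 1.

Model A: cell ``i`` initiates a streak iff ``F_i > alpha`` for a fixed
threshold ``alpha``, with no reference to neighbours.

Model B ("neighbourhood watch"): cell ``i`` initiates a streak iff
``F_i > beta * F_nbhd(i)``, where ``F_nbhd(i)`` is the mean SMAD-value
over the (2n+1)-cell window centred on ``i`` (focal cell included).

Each rule also yields a signed threshold distance ``f_i`` (positive iff
the cell streaks) used by the smoothed-step likelihood: for Model A
``f_i = F_i - alpha``; for Model B the default is
``f_i = F_i - beta * F_nbhd(i)`` (f is literally the distance of F to
its threshold, as in Model A), with the fold-change form
``F_i / F_nbhd(i) - beta`` available — both give identical masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from nwatch.ring import RingField

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of Model A or Model B.

    ``model_id`` is "A" (fixed threshold ``alpha``) or "B" (fold
    threshold ``beta`` and neighbourhood half-width ``n``); ``a_V`` and
    ``a_B`` scale the inducer and inhibitor concentration proxies.
    """

    model_id: str
    a_V: float
    a_B: float
    alpha: Optional[float] = None
    beta: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model_id not in ("A", "B"):
            raise ValueError("model_id must be 'A' or 'B'")
        if self.a_V <= 0 or self.a_B <= 0:
            raise ValueError("a_V and a_B must be > 0")
        if self.model_id == "A":
            if self.alpha is None or self.beta is not None or self.n is not None:
                raise ValueError("Model A takes alpha only")
            if not 0 < self.alpha < 1:
                raise ValueError("alpha must lie in (0, 1)")
        else:
            if self.beta is None or self.n is None or self.alpha is not None:
                raise ValueError("Model B takes beta and n only")
            if self.beta <= 0:
                raise ValueError("beta must be > 0")
            if self.n < 0 or self.n != int(self.n):
                raise ValueError("n must be a non-negative integer")


@dataclass
class DecisionProfile:
    """Outcome of one decision rule on one field."""

    F: np.ndarray
    f: np.ndarray
    streak_mask: np.ndarray
    nbhd_mean: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_index": np.arange(len(self.F)),
                "F": self.F,
                "f": self.f,
                "streak": self.streak_mask.astype(int),
            }
        )
        if self.nbhd_mean is not None:
            df.insert(2, "nbhd_mean", self.nbhd_mean)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def smad_value(field: RingField, a_V: float, a_B: float) -> np.ndarray:
    """Per-cell SMAD-value F in [0, 1)."""
    if a_V <= 0 or a_B <= 0:
        raise ValueError("a_V and a_B must be > 0")
    sV = a_V * field.V
    return sV / (1.0 + sV + a_B * field.B)


def decide_model_A(F: np.ndarray, alpha: float) -> DecisionProfile:
    """Cell-autonomous threshold rule: streak iff F_i > alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    f = F - alpha
    return DecisionProfile(F=F, f=f, streak_mask=f > 0)


def neighbourhood_mean(F: np.ndarray, n: int) -> np.ndarray:
    """Mean of F over the (2n+1)-cell periodic window centred on each cell."""
    m = len(F)
    if 2 * n + 1 > m:
        raise ValueError(f"window 2n+1 = {2 * n + 1} exceeds ring size {m}")
    if n == 0:
        return F.astype(float).copy()
    # periodic windowed sum via cumulative sums of the wrapped vector
    ext = np.concatenate([F[-n:], F, F[:n]])
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return (c[2 * n + 1 :] - c[: m]) / (2 * n + 1)


def decide_model_B(
    F: np.ndarray, beta: float, n: int, form: str = "difference"
) -> DecisionProfile:
    """Neighbourhood comparison rule: streak iff F_i > beta * F_nbhd(i).

    ``form`` selects the threshold-distance convention entering the
    likelihood: "difference" gives ``f_i = F_i - beta*F_nbhd``; "ratio"
    gives ``f_i = F_i/F_nbhd - beta``.  The streak mask is identical.
    Cells whose window mean is zero carry no evidence either way and get
    ``f_i = 0``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if form not in ("ratio", "difference"):
        raise ValueError("form must be 'ratio' or 'difference'")
    nb = neighbourhood_mean(F, n)
    if form == "ratio":
        zero = nb == 0
        if np.any(zero):
            logger.debug("%d cells have zero neighbourhood mean; f set to 0", zero.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(zero, 0.0, F / np.where(zero, 1.0, nb) - beta)
    else:
        f = F - beta * nb
    return DecisionProfile(F=F, f=f, streak_mask=f > 0, nbhd_mean=nb)


def decide(field: RingField, params: ModelParams, form: str = "difference") -> DecisionProfile:
    """Run the parameterised decision rule on a field."""
    F = smad_value(field, params.a_V, params.a_B)
    if params.model_id == "A":
        return decide_model_A(F, params.alpha)
    return decide_model_B(F, params.beta, int(params.n), form=form)


def streak_components(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True cells under periodic adjacency.

    Returns ``(start, end)`` inclusive index pairs; a run crossing the
    origin is reported once with ``end < start``.  An all-True mask is a
    single component covering the ring.
    """
    mask = np.asarray(mask, dtype=bool)
    m = len(mask)
    if not mask.any():
        return []
    if mask.all():
        return [(0, m - 1)]
    # rotate so position 0 is False, find runs, rotate back
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    padded = np.concatenate([[False], rolled, [False]]).astype(int)
    diff = np.diff(padded)
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0] - 1
    return [
        ((s + first_false) % m, (e + first_false) % m) for s, e in zip(starts, ends)
    ]


def component_cells(comp: tuple[int, int], n_cells: int) -> np.ndarray:
    """Cell indices covered by a periodic (start, end) component."""
    s, e = comp
    if e >= s:
        return np.arange(s, e + 1)
    return np.concatenate([np.arange(s, n_cells), np.arange(0, e + 1)])
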