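"""Encoded bead-graft experiments and synthetic design generators.

Each :class:`DesignSpec` pairs a layout of perturbation sources on the
ring with the binary per-cell target outcome observed (or hypothesised)
for that layout: ``+1`` where ectopic streak initiation (cBRA expression)
is expected, ``-1`` elsewhere.  Targets are the modal experimental
outcomes, not outcome frequencies.  Only anterior-half cells enter the
likelihood, because grafts were placed anteriorly; the endogenous
posterior streak is therefore outside the scored region.

Bead concentrations are expressed in model units with the standard
ACTIVIN dose (12.5 ng/ul) defined as 1.0; doses map linearly, so
"sub-threshold" ACTIVIN (2.5 ng/ul) is 0.2 and BMP4 at 6.25/12.5/25/50
ng/ul is 0.5/1/2/4.  During inference a free concentration scale ``c``
multiplies these relative doses and a free ``s`` replaces the spread, so
the absolute mapping is absorbed by the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import yaml

from nwatch.models import ModelParams, component_cells, decide, streak_components
from nwatch.ring import (
    MICROBEAD_WIDTH,
    PELLET_WIDTH,
    BaselineProfileParams,
    BeadSpec,
    RingField,
    apply_design,
    bead_from_dict,
    bead_to_dict,
    baseline_from_dict,
    baseline_to_dict,
    make_baseline,
    ring_distance,
)

#: Fixed width in cells of an expected streak-initiating domain.
EXPECTED_SITE_WIDTH = 11

DEFAULT_N_CELLS = 600


@dataclass
class TargetPattern:
    """Binary per-cell target: +1 streak expected, -1 not."""

    D: np.ndarray
    evaluation_cells: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=int)
        self.evaluation_cells = np.asarray(self.evaluation_cells, dtype=int)
        if not np.all(np.isin(self.D, (-1, 1))):
            raise ValueError("target labels must be +1 or -1")
        if len(self.evaluation_cells) == 0:
            raise ValueError("evaluation_cells must be non-empty")


@dataclass
class DesignSpec:
    """A named bead layout with its encoded target outcome."""

    name: str
    beads: list[BeadSpec]
    target: TargetPattern
    expected_sites: list[tuple[int, int]]
    n_cells: int = DEFAULT_N_CELLS
    baseline: BaselineProfileParams = dc_field(default_factory=BaselineProfileParams)
    group: str = ""
    generating_params: Optional[ModelParams] = None

    @property
    def expected_streak_count(self) -> int:
        return len(self.expected_sites)

    def baseline_field(self) -> RingField:
        return make_baseline(self.baseline, self.n_cells)

    def scaled_beads(self, c_scale: float, spread: float) -> list[BeadSpec]:
        """Beads with concentrations rescaled by ``c_scale`` and spread replaced.

        Catalog concentrations are relative doses; the inference treats
        the overall scale and the spatial decay length as free.
        """
        return [
            BeadSpec(
                compound=b.compound,
                center=b.center,
                width=b.width,
                concentration=b.concentration * c_scale,
                spread=spread,
            )
            for b in self.beads
        ]

    def perturbed_field(
        self, c_scale: float = 1.0, spread: Optional[float] = None
    ) -> RingField:
        beads = (
            self.beads
            if spread is None and c_scale == 1.0
            else self.scaled_beads(c_scale, spread if spread is not None else 5.0)
        )
        return apply_design(self.baseline_field(), beads)


def anterior_evaluation_cells(n_cells: int) -> np.ndarray:
    """Cells within n_cells/4 of the anterior pole (the graft region)."""
    idx = np.arange(n_cells)
    d = ring_distance(idx, n_cells // 2, n_cells)
    return idx[d < n_cells // 4]


def make_target(
    n_cells: int,
    sites: Sequence[tuple[int, int]],
    evaluation_cells: Optional[np.ndarray] = None,
) -> TargetPattern:
    """Build a target with +1 on the given periodic intervals, -1 elsewhere."""
    D = -np.ones(n_cells, dtype=int)
    for site in sites:
        D[component_cells(site, n_cells)] = 1
    if evaluation_cells is None:
        evaluation_cells = anterior_evaluation_cells(n_cells)
    return TargetPattern(D=D, evaluation_cells=evaluation_cells)


def site_at(center: int, n_cells: int, width: int = EXPECTED_SITE_WIDTH) -> tuple[int, int]:
    h = width // 2
    return ((center - h) % n_cells, (center + h) % n_cells)


def _row_centers(anchor: int, m: int, width: int, n_cells: int) -> list[int]:
    """Centers of m side-by-side sources spaced by one footprint width."""
    offsets = (np.arange(m) - (m - 1) / 2) * width
    return [int((anchor + round(o)) % n_cells) for o in offsets]


def _bead_row(
    compounds_doses: Sequence[tuple[str, float]],
    anchor: int,
    width: int,
    spread: float,
    n_cells: int,
) -> list[BeadSpec]:
    centers = _row_centers(anchor, len(compounds_doses), width, n_cells)
    return [
        BeadSpec(compound=comp, center=ctr, width=width, concentration=dose, spread=spread)
        for (comp, dose), ctr in zip(compounds_doses, centers)
    ]


def catalog(
    n_cells: int = DEFAULT_N_CELLS,
    baseline: BaselineProfileParams = BaselineProfileParams(),
    spread: float = 5.0,
) -> list[DesignSpec]:
    """All encoded bead- and pellet-graft experiments.

    Groups: ``microbead`` — the five microbead layouts used for the main
    model comparison; ``pellet`` — cell-pellet (wide footprint) variants;
    ``inhibitor_mod`` — inhibitor-modulation designs (BMP antagonist bead and
    anterior BMP bead); ``subthreshold`` — sub-threshold inducer flanked by
    inhibitor.  Relative doses: ACTIVIN 1.0 (sub-threshold 0.2), BMP4
    0.5/1/2/4 for 6.25/12.5/25/50 ng/ul, dorsomorphin encoded as an
    inhibitor antagonist of unit dose.
    """
    A = n_cells // 2  # anterior pole, graft anchor
    W = MICROBEAD_WIDTH
    P = PELLET_WIDTH
    ant = anterior_evaluation_cells(n_cells)

    def design(name, beads, site_centers, group, site_width=EXPECTED_SITE_WIDTH):
        sites = [site_at(c, n_cells, site_width) for c in site_centers]
        return DesignSpec(
            name=name,
            beads=beads,
            target=make_target(n_cells, sites, ant),
            expected_sites=sites,
            n_cells=n_cells,
            baseline=baseline,
            group=group,
        )

    I, B, C, X = "inducer_source", "inhibitor_source", "neutral", "inhibitor_antagonist"
    designs = []

    # --- microbead model-comparison set (three beads side by side) -------
    trip = lambda seq: _bead_row(seq, A, W, spread, n_cells)
    c3 = _row_centers(A, 3, W, n_cells)
    designs += [
        design("C-C-C", trip([(C, 1), (C, 1), (C, 1)]), [], "microbead_controls"),
        design("C-A-C", trip([(C, 1), (I, 1), (C, 1)]), [A], "microbead"),
        design("A-A-A", trip([(I, 1), (I, 1), (I, 1)]), [], "microbead"),
        design("A-C-A", trip([(I, 1), (C, 1), (I, 1)]), [c3[0], c3[2]], "microbead"),
        design("A-B-A-low", trip([(I, 1), (B, 1), (I, 1)]), [c3[0], c3[2]], "microbead"),
        design("A-B-A-high", trip([(I, 1), (B, 2), (I, 1)]), [], "microbead"),
    ]

    # --- inhibitor modulation (single microbead) -------------------------
    one = lambda comp, dose: [
        BeadSpec(compound=comp, center=A, width=W, concentration=dose, spread=spread)
    ]
    designs += [
        design("dorsomorphin", one(X, 1.0), [A], "inhibitor_mod"),
        design("anterior-BMP", one(B, 4.0), [], "inhibitor_mod"),
    ]

    # --- sub-threshold inducer flanked by inhibitor ----------------------
    designs += [
        design("B-C-B", trip([(B, 0.5), (C, 1), (B, 0.5)]), [], "subthreshold"),
        design("C-Asub-C", trip([(C, 1), (I, 0.2), (C, 1)]), [], "subthreshold"),
        design("B-Asub-B-low", trip([(B, 0.5), (I, 0.2), (B, 0.5)]), [A], "subthreshold"),
        design("B-Asub-B-high", trip([(B, 1.0), (I, 0.2), (B, 1.0)]), [], "subthreshold"),
    ]

    # --- cell-pellet variants (wide footprint) ---------------------------
    row = lambda seq: _bead_row(seq, A, P, spread, n_cells)
    c5 = _row_centers(A, 5, P, n_cells)
    designs += [
        design("pellet-VV", row([(I, 1), (I, 1)]), [A], "pellet"),
        design("pellet-CC", row([(C, 1), (C, 1)]), [], "pellet"),
        design("pellet-VVVV", row([(I, 1)] * 4, ), [], "pellet"),
        design(
            "pellet-VV-C-VV",
            row([(I, 1), (I, 1), (C, 1), (I, 1), (I, 1)]),
            [(c5[0] + c5[1]) // 2, (c5[3] + c5[4]) // 2],
            "pellet",
        ),
        design(
            "pellet-VV-B-VV",
            row([(I, 1), (I, 1), (B, 1), (I, 1), (I, 1)]),
            [(c5[0] + c5[1]) // 2, (c5[3] + c5[4]) // 2],
            "pellet",
        ),
    ]
    return designs


def design_groups(
    n_cells: int = DEFAULT_N_CELLS,
    baseline: BaselineProfileParams = BaselineProfileParams(),
    spread: float = 5.0,
) -> dict[str, list[DesignSpec]]:
    """Catalog designs keyed by experiment group."""
    groups: dict[str, list[DesignSpec]] = {}
    for d in catalog(n_cells, baseline, spread):
        groups.setdefault(d.group, []).append(d)
    return groups


def _dilate_component(
    comp: tuple[int, int], n_cells: int, width: int
) -> tuple[int, int]:
    """Expand a periodic run symmetrically to at least ``width`` cells."""
    cells = component_cells(comp, n_cells)
    if len(cells) >= width:
        return comp
    extra = width - len(cells)
    lo = extra // 2
    hi = extra - lo
    return ((comp[0] - lo) % n_cells, (comp[1] + hi) % n_cells)


def generate_from_model(
    params: ModelParams,
    beads: Sequence[BeadSpec],
    field_params: BaselineProfileParams = BaselineProfileParams(),
    n_cells: int = DEFAULT_N_CELLS,
    name: str = "synthetic",
    evaluation: str = "anterior",
    form: str = "difference",
) -> DesignSpec:
    """Target pattern generated by running a model with known parameters.

    Streak components predicted by the model are dilated to the fixed
    expected site width and become the +1 intervals; a model predicting
    zero streaks yields a valid all-negative target.
    """
    field = apply_design(make_baseline(field_params, n_cells), list(beads))
    profile = decide(field, params, form=form)
    comps = streak_components(profile.streak_mask)
    sites = [_dilate_component(cmp, n_cells, EXPECTED_SITE_WIDTH) for cmp in comps]
    eval_cells = (
        anterior_evaluation_cells(n_cells)
        if evaluation == "anterior"
        else np.arange(n_cells)
    )
    # sites wholly outside the evaluated region are unobservable
    observable = np.zeros(n_cells, dtype=bool)
    observable[eval_cells] = True
    sites = [s for s in sites if observable[component_cells(s, n_cells)].any()]
    return DesignSpec(
        name=name,
        beads=list(beads),
        target=make_target(n_cells, sites, eval_cells),
        expected_sites=sites,
        n_cells=n_cells,
        baseline=field_params,
        group="synthetic",
        generating_params=params,
    )


def randomized_designs(
    n_designs: int,
    seed: int,
    params: Optional[ModelParams] = None,
    n_cells: int = DEFAULT_N_CELLS,
    field_params: BaselineProfileParams = BaselineProfileParams(),
) -> list[DesignSpec]:
    """Random anterior bead layouts with model-generated targets.

    Bead counts are 1-4; compounds are drawn from inducer, inhibitor and
    neutral; relative doses from U(0.2, 4), spreads from U(1, 20); rows
    are anchored within a quarter-ring of the anterior pole.  Targets
    come from running ``params`` (default: a reference neighbourhood
    model with beta=1.3, n=50, a_V=10, a_B=3).
    """
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    if params is None:
        params = ModelParams(model_id="B", a_V=10.0, a_B=3.0, beta=1.3, n=50)
    rng = np.random.default_rng(seed)
    A = n_cells // 2
    out = []
    for k in range(n_designs):
        m = int(rng.integers(1, 5))
        anchor = int((A + rng.integers(-n_cells // 8, n_cells // 8 + 1)) % n_cells)
        seq = [
            (
                str(rng.choice(["inducer_source", "inhibitor_source", "neutral"])),
                float(rng.uniform(0.2, 4.0)),
            )
            for _ in range(m)
        ]
        spread = float(rng.uniform(1.0, 20.0))
        beads = _bead_row(seq, anchor, MICROBEAD_WIDTH, spread, n_cells)
        out.append(
            generate_from_model(
                params,
                beads,
                field_params,
                n_cells=n_cells,
                name=f"random-{k}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Serialisation


def design_to_dict(d: DesignSpec) -> dict:
    """Compact serialisation: the target is canonical given the sites.

    D is +1 exactly on the expected sites; the evaluation region is
    either the anterior half or the full ring, stored as a token (an
    explicit cell list is kept only for non-standard regions).
    """
    anterior = anterior_evaluation_cells(d.n_cells)
    if np.array_equal(d.target.evaluation_cells, anterior):
        evaluation = "anterior"
    elif np.array_equal(d.target.evaluation_cells, np.arange(d.n_cells)):
        evaluation = "all"
    else:
        evaluation = d.target.evaluation_cells.tolist()
    return {
        "name": d.name,
        "group": d.group,
        "n_cells": int(d.n_cells),
        "baseline": baseline_to_dict(d.baseline),
        "beads": [bead_to_dict(b) for b in d.beads],
        "expected_sites": [[int(s), int(e)] for s, e in d.expected_sites],
        "evaluation": evaluation,
    }


def design_from_dict(doc: dict) -> DesignSpec:
    n_cells = int(doc["n_cells"])
    evaluation = doc.get("evaluation", "anterior")
    if evaluation == "anterior":
        eval_cells = anterior_evaluation_cells(n_cells)
    elif evaluation == "all":
        eval_cells = np.arange(n_cells)
    else:
        eval_cells = np.asarray(evaluation, dtype=int)
    sites = [(int(s), int(e)) for s, e in doc["expected_sites"]]
    return DesignSpec(
        name=doc["name"],
        beads=[bead_from_dict(b) for b in doc["beads"]],
        target=make_target(n_cells, sites, eval_cells),
        expected_sites=sites,
        n_cells=n_cells,
        baseline=baseline_from_dict(doc["baseline"]),
        group=doc.get("group", ""),
    )


def dump_designs(designs: Sequence[DesignSpec], stream=None):
    return yaml.safe_dump([design_to_dict(d) for d in designs], stream, sort_keys=False)


def load_designs(stream) -> list[DesignSpec]:
    return [design_from_dict(doc) for doc in yaml.safe_load(stream)]
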