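"""The six selection-model specifications.

Each model fixes a boundary grid on the z-scale and declares which interval
of which study category is governed by which shared log-weight parameter.
Models:

``unbiased``         weight identically 1; no selection.
``high_resolution``  16 intervals cut at 15 symmetric boundaries; the 14
                     inner intervals each carry an independent free
                     log-weight; weight 1 for |z| > 2.58.
``model1``           one category, boundaries (-1.64, 1.64); one parameter
                     w_S for the mid interval.
``model2``           initial vs. subsequent studies; parameters w_I, w_S.
``model3``           initial / early / late; early weight split at z = 0
                     into w_E1 (z in (-1.64, 0]) and w_E2 (z in (0, 1.64]);
                     four parameters.
``proteus``          as model3 but the early weight is selected by sign
                     agreement with the initial finding: w_E1 when the early
                     study opposes the initial result, w_E2 when it agrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .weights import CategoryRule, WeightFunction

__all__ = ["ModelSpec", "build_model", "count_parameters", "MODEL_NAMES",
           "HIGH_RESOLUTION_BOUNDARIES", "REDUCED_BOUNDARIES", "EARLY_BOUNDARIES"]

MODEL_NAMES = ("unbiased", "high_resolution", "model1", "model2", "model3", "proteus")

HIGH_RESOLUTION_BOUNDARIES = (
    -2.58, -1.96, -1.64, -1.28, -1.04, -0.67, -0.25, 0.0,
    0.25, 0.67, 1.04, 1.28, 1.64, 1.96, 2.58,
)
REDUCED_BOUNDARIES = (-1.64, 1.64)
EARLY_BOUNDARIES = (-1.64, 0.0, 1.64)  # union grid used by model3 / proteus

FREE = 0  # sentinel only for readability below; slots use -1 for "pinned at 1"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one selection model.

    ``slots`` maps a template key (see :meth:`CategoryRule.template_key`) to
    an integer row of length k: entry j is the index into the shared
    log-weight parameter vector governing interval j, or -1 where the weight
    is pinned at 1.  All templates of a model share one boundary grid; where
    a category's conceptual weight function has fewer steps, adjacent
    intervals simply share a parameter.
    """

    name: str
    effects_mode: str  # "fixed" | "random"
    category_rule: CategoryRule
    boundaries: np.ndarray
    param_names: tuple
    slots: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.effects_mode not in ("fixed", "random"):
            raise ValueError("effects_mode must be 'fixed' or 'random'")
        object.__setattr__(self, "boundaries", np.asarray(self.boundaries, float))
        k = self.boundaries.size + 1
        for key, row in self.slots.items():
            row = np.asarray(row, int)
            if row.size != k:
                raise ValueError(f"slot row {key!r} has length {row.size}, need {k}")
            if row.size and (row[0] != -1 or row[-1] != -1):
                raise ValueError("outer intervals must be pinned (slot -1)")

    @property
    def n_free_weight_params(self) -> int:
        return len(self.param_names)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size + 1

    def slot_row(self, category: str, sign_agrees: Optional[bool] = None) -> np.ndarray:
        key = self.category_rule.template_key(category, sign_agrees)
        return np.asarray(self.slots[key], int)

    def weight_function(
        self,
        category: str,
        theta: np.ndarray,
        sign_agrees: Optional[bool] = None,
    ) -> WeightFunction:
        """Materialize the weight function for a study category at theta."""
        theta = np.asarray(theta, float)
        if theta.size != self.n_free_weight_params:
            raise ValueError(
                f"expected {self.n_free_weight_params} log-weights, got {theta.size}"
            )
        row = self.slot_row(category, sign_agrees)
        lw = np.where(row >= 0, theta[np.clip(row, 0, None)] if theta.size else 0.0, 0.0)
        return WeightFunction(self.boundaries, lw, free_mask=row >= 0)

    @property
    def weight_templates(self) -> dict:
        """Per-category templates at the neutral point (all log-weights 0)."""
        theta0 = np.zeros(self.n_free_weight_params)
        out = {}
        for key, row in self.slots.items():
            row = np.asarray(row, int)
            out[key] = WeightFunction(
                self.boundaries, np.zeros(row.size), free_mask=row >= 0
            )
        del theta0
        return out


def _spec(name, effects_mode, rule, boundaries, param_names, slots) -> ModelSpec:
    return ModelSpec(
        name=name,
        effects_mode=effects_mode,
        category_rule=rule,
        boundaries=np.asarray(boundaries, float),
        param_names=tuple(param_names),
        slots={k: np.asarray(v, int) for k, v in slots.items()},
    )


def build_model(name: str, effects_mode: str = "random") -> ModelSpec:
    """Construct one of the six model specifications by name."""
    if name == "unbiased":
        return _spec(name, effects_mode, CategoryRule("single"),
                     (), (), {"all": [-1]})
    if name == "high_resolution":
        row = [-1] + list(range(14)) + [-1]
        return _spec(name, effects_mode, CategoryRule("single"),
                     HIGH_RESOLUTION_BOUNDARIES,
                     tuple(f"log_w_{j + 1}" for j in range(14)),
                     {"all": row})
    if name == "model1":
        return _spec(name, effects_mode, CategoryRule("single"),
                     REDUCED_BOUNDARIES, ("log_w_S",), {"all": [-1, 0, -1]})
    if name == "model2":
        return _spec(name, effects_mode, CategoryRule("two_category"),
                     REDUCED_BOUNDARIES, ("log_w_I", "log_w_S"),
                     {"initial": [-1, 0, -1], "subsequent": [-1, 1, -1]})
    if name == "model3":
        return _spec(name, effects_mode, CategoryRule("three_category"),
                     EARLY_BOUNDARIES,
                     ("log_w_I", "log_w_E1", "log_w_E2", "log_w_S"),
                     {"initial": [-1, 0, 0, -1],
                      "early": [-1, 1, 2, -1],
                      "late": [-1, 3, 3, -1]})
    if name == "proteus":
        return _spec(name, effects_mode, CategoryRule("proteus"),
                     EARLY_BOUNDARIES,
                     ("log_w_I", "log_w_E1", "log_w_E2", "log_w_S"),
                     {"initial": [-1, 0, 0, -1],
                      "early_oppose": [-1, 1, 1, -1],
                      "early_agree": [-1, 2, 2, -1],
                      "late": [-1, 3, 3, -1]})
    raise ValueError(f"unknown model {name!r}; valid names: {MODEL_NAMES}")


def count_parameters(spec: ModelSpec, corpus) -> int:
    """Total free-parameter count k entering AIC = 2k - 2L.

    k = shared weight parameters + one mean effect per marker + one
    between-study variance per marker under random effects.  In model
    comparisons on one corpus the per-marker terms cancel, so AIC
    differences depend only on the weight-parameter counts and the
    log-likelihood difference.
    """
    markers = {s.marker_id for s in corpus}
    if not markers:
        raise ValueError("corpus is empty")
    per_marker = 2 if spec.effects_mode == "random" else 1
    return spec.n_free_weight_params + per_marker * len(markers)
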