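"""Stepwise-constant weight functions and category selection rules.

A weight function gives the relative probability that a study result is
published, as a function of its standardized effect z = x / sigma.  It is
piecewise constant on intervals cut at fixed z-boundaries; the outer
intervals are pinned at weight 1, so all estimated weights are relative
publication probabilities with respect to "extreme" (formally significant)
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Mapping

import numpy as np

__all__ = [
    "WeightFunction",
    "CategoryRule",
    "evaluate_weight",
    "interval_index",
    "select_weight_function",
    "CATEGORIES",
]

CATEGORIES = ("initial", "early", "late")


@dataclass(frozen=True)
class WeightFunction:
    """A stepwise-constant weight function of the standardized effect.

    Parameters
    ----------
    boundaries
        Strictly increasing z-values (z_1 .. z_{k-1}) cutting the real line
        into k intervals.  Intervals are left-open/right-closed: z exactly on
        a boundary belongs to the lower interval.
    log_weights
        k log-weights (log w_1 .. log w_k), one per interval.
    free_mask
        Boolean vector marking which log-weights are estimated.  Entries with
        ``free_mask == False`` are pinned at log-weight 0 (weight 1).
    """

    boundaries: np.ndarray
    log_weights: np.ndarray
    free_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        lw = np.asarray(self.log_weights, dtype=float)
        if self.free_mask is None:
            fm = np.ones(lw.shape, dtype=bool)
        else:
            fm = np.asarray(self.free_mask, dtype=bool)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "log_weights", lw)
        object.__setattr__(self, "free_mask", fm)
        if b.ndim != 1 or lw.ndim != 1:
            raise ValueError("boundaries and log_weights must be 1-d")
        if b.size and not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if lw.size != b.size + 1:
            raise ValueError(
                f"need len(boundaries)+1 log-weights, got {lw.size} for "
                f"{b.size} boundaries"
            )
        if fm.shape != lw.shape:
            raise ValueError("free_mask must match log_weights in shape")
        if not np.all(np.isfinite(lw)):
            raise ValueError("log_weights must be finite")
        if np.any(lw[~fm] != 0.0):
            raise ValueError("fixed (non-free) log-weights must be exactly 0")

    @property
    def n_intervals(self) -> int:
        return self.log_weights.size

    def interval_index(self, z):
        """Index of the interval containing z (vectorized).

        Intervals are (z_{j-1}, z_j]; a z exactly on a boundary falls in the
        lower interval.
        """
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite")
        return np.searchsorted(self.boundaries, z, side="left")

    def __call__(self, z):
        """Evaluate the weight exp(log w_j) at standardized effect z."""
        return np.exp(self.log_weights[self.interval_index(z)])


def interval_index(wf: WeightFunction, z):
    return wf.interval_index(z)


def evaluate_weight(wf: WeightFunction, z):
    """Weight of the interval containing z; always positive."""
    return wf(z)


@dataclass(frozen=True)
class CategoryRule:
    """How temporal categories map onto weight functions.

    scheme
        ``single``            one weight function for every study;
        ``two_category``      initial studies vs. all subsequent studies;
        ``three_category``    initial / early-replication / late studies,
                              with the early weight depending only on z;
        ``proteus``           as ``three_category``, but the early-replication
                              weight is selected by whether the study's sign
                              agrees with the initial finding.
    """

    scheme: str
    sign_dependent: bool = False

    _SCHEMES = ("single", "two_category", "three_category", "proteus")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; one of {self._SCHEMES}")
        if self.sign_dependent and self.scheme != "proteus":
            raise ValueError("sign_dependent is only valid for the proteus scheme")
        if self.scheme == "proteus" and not self.sign_dependent:
            object.__setattr__(self, "sign_dependent", True)

    def template_key(self, category: str, sign_agrees: Optional[bool] = None) -> str:
        """Key into a model's per-category weight-function templates."""
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if self.scheme == "single":
            return "all"
        if self.scheme == "two_category":
            return "initial" if category == "initial" else "subsequent"
        # three categories
        if category != "early":
            if self.scheme == "proteus" and sign_agrees is not None:
                raise ValueError("sign_agrees is only meaningful for early studies")
            return category
        if self.scheme == "proteus":
            if sign_agrees is None:
                raise ValueError(
                    "proteus rule requires sign_agrees for early-replication studies"
                )
            return "early_agree" if sign_agrees else "early_oppose"
        return "early"


def select_weight_function(
    rule: CategoryRule,
    category: str,
    sign_agrees: Optional[bool],
    model_wfs: Mapping[str, WeightFunction],
) -> WeightFunction:
    """Pick the weight function governing one study's publication chance.

    ``model_wfs`` maps template keys (as produced by
    :meth:`CategoryRule.template_key`) to weight functions.  Under the
    proteus rule the early-replication function is selected by whether the
    study's sign agrees with the initial result.
    """
    key = rule.template_key(category, sign_agrees)
    try:
        return model_wfs[key]
    except KeyError:
        raise KeyError(f"model has no weight function for template {key!r}") from None
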