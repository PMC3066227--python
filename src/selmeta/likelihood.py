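"""Weighted likelihood for selectively reported study collections.

Under the random-effects model a study result on marker m is
X_i ~ N(Delta_m, sigma_i^2 + tau2_m) with known within-study variance
sigma_i^2.  Selective reporting multiplies the density by the stepwise
weight omega(x_i / sigma_i) of the study's category and renormalizes; the
normalization constant is sum_j w_j B_ij where

    B_ij = Phi((z_j sigma_i - Delta) / s) - Phi((z_{j-1} sigma_i - Delta) / s),
    s = sqrt(sigma_i^2 + tau2),  z_0 = -inf,  z_k = +inf,

i.e. the unselected probability of landing in weight interval j.  The
combined log likelihood over markers shares one weight-parameter vector
across all markers while each marker keeps its own (Delta_m, tau2_m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .models import ModelSpec
from .weights import WeightFunction

__all__ = [
    "StudyResult",
    "MarkerParams",
    "interval_probs",
    "weighted_logdensity",
    "marker_loglik",
    "combined_loglik",
    "CompiledCorpus",
    "compile_corpus",
    "per_marker_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_DENOM_FLOOR = 1e-300


@dataclass
class StudyResult:
    """One published case-control result on one genetic marker."""

    x: float                     # log odds ratio
    sigma: float                 # within-study standard error, > 0
    marker_id: str
    pub_id: str
    year: int
    category: Optional[str] = None        # initial | early | late
    sign_agrees: Optional[bool] = None    # defined for early studies

    def __post_init__(self) -> None:
        if not np.isfinite(self.x):
            raise ValueError(f"non-finite effect for {self.marker_id}/{self.pub_id}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(
                f"standard error must be positive and finite for "
                f"{self.marker_id}/{self.pub_id}"
            )

    @property
    def z(self) -> float:
        return self.x / self.sigma


@dataclass(frozen=True)
class MarkerParams:
    """Mean effect and between-study variance of one marker.

    tau2 may be negative during unrestricted optimization; the likelihood
    raises as soon as any study's total variance sigma_i^2 + tau2 becomes
    nonpositive.
    """

    delta: float
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta) and np.isfinite(self.tau2)):
            raise ValueError("marker parameters must be finite")


def interval_probs(delta, tau2, sigma_i, boundaries) -> np.ndarray:
    """Unselected probabilities B_ij of the k weight intervals.

    Tail intervals are computed via the complementary CDF so that nearly
    degenerate boundary pairs do not cancel catastrophically; each entry is
    floored at 0 after differencing.  The returned vector sums to 1.
    """
    boundaries = np.asarray(boundaries, float)
    sigma_i = float(sigma_i)
    if not sigma_i > 0:
        raise ValueError("sigma_i must be positive")
    total_var = sigma_i**2 + tau2
    if not total_var > 0:
        raise ValueError(f"nonpositive total variance {total_var} (tau2={tau2})")
    if boundaries.size == 0:
        return np.ones(1)
    args = (boundaries * sigma_i - delta) / np.sqrt(total_var)
    cdf = ndtr(args)
    sf = ndtr(-args)  # survival function, accurate in the upper tail
    upper = np.concatenate([cdf, [1.0]])
    lower = np.concatenate([[0.0], cdf])
    probs = upper - lower
    # recompute the top interval from the survival function
    probs[-1] = sf[-1]
    np.clip(probs, 0.0, None, out=probs)
    return probs


def _normalizer(wf: WeightFunction, delta, tau2, sigma_i) -> float:
    b = interval_probs(delta, tau2, sigma_i, wf.boundaries)
    total = float(np.dot(np.exp(wf.log_weights), b))
    if not np.isfinite(total) or total <= _DENOM_FLOOR:
        raise FloatingPointError(
            f"weighted normalization constant underflowed (value {total})"
        )
    return total


def weighted_logdensity(s: StudyResult, p: MarkerParams, wf: WeightFunction) -> float:
    """Log of the selection-weighted density of one study result.

    log omega(x, sigma) + log phi(x; Delta, sigma^2 + tau2) - log sum_j w_j B_ij.
    With all weights equal to 1 this is exactly the unweighted normal log
    density.
    """
    total_var = s.sigma**2 + p.tau2
    if not total_var > 0:
        raise ValueError(
            f"nonpositive total variance for marker {s.marker_id} "
            f"(sigma_i^2={s.sigma**2:.3g}, tau2={p.tau2:.3g})"
        )
    log_w = float(wf.log_weights[wf.interval_index(s.z)])
    log_phi = -0.5 * (_LOG_2PI + np.log(total_var)) - (s.x - p.delta) ** 2 / (
        2.0 * total_var
    )
    return log_w + log_phi - np.log(_normalizer(wf, p.delta, p.tau2, s.sigma))


def marker_loglik(
    studies: Sequence[StudyResult],
    p: MarkerParams,
    spec: ModelSpec,
    log_weights,
) -> float:
    """Log likelihood of one marker's studies at shared log-weights."""
    studies = list(studies)
    if not studies:
        raise ValueError("marker has no studies")
    ids = {s.marker_id for s in studies}
    if len(ids) > 1:
        raise ValueError(f"studies span several markers: {sorted(ids)}")
    theta = np.asarray(log_weights, float)
    total = 0.0
    for s in studies:
        wf = spec.weight_function(_category_of(s, spec), theta,
                                  sign_agrees=_sign_ctx(s, spec))
        total += weighted_logdensity(s, p, wf)
    return total


def combined_loglik(corpus, params, log_weights, spec: ModelSpec) -> float:
    """Multi-dataset log likelihood: sum of marker log likelihoods with one
    shared weight-parameter vector.

    ``params`` maps marker_id -> MarkerParams; every marker in the corpus
    must be covered.
    """
    by_marker: dict = {}
    for s in corpus:
        by_marker.setdefault(s.marker_id, []).append(s)
    missing = sorted(set(by_marker) - set(params))
    if missing:
        raise KeyError(f"no parameters for markers: {missing}")
    return sum(
        marker_loglik(studies, params[mid], spec, log_weights)
        for mid, studies in by_marker.items()
    )


def _category_of(s: StudyResult, spec: ModelSpec) -> str:
    if spec.category_rule.scheme == "single":
        # a single-category model ignores categories; treat anything as late
        return s.category or "late"
    if s.category is None:
        raise ValueError(
            f"study {s.marker_id}/{s.pub_id} has no category; run categorize() first"
        )
    return s.category

def _sign_ctx(s: StudyResult, spec: ModelSpec):
    if spec.category_rule.sign_dependent and (s.category == "early"):
        if s.sign_agrees is None:
            raise ValueError(
                f"early study {s.marker_id}/{s.pub_id} lacks sign context "
                "required by the proteus model"
            )
        return s.sign_agrees
    return None


# ---------------------------------------------------------------------------
# Compiled fast path: the whole corpus as flat arrays, one vectorized pass
# per likelihood evaluation.  Used by the fitting machinery.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompiledCorpus:
    """Corpus flattened to arrays for vectorized likelihood evaluation."""

    spec: ModelSpec
    marker_ids: tuple              # ordered unique marker ids
    x: np.ndarray                  # (N,)
    sigma: np.ndarray              # (N,)
    marker_idx: np.ndarray         # (N,) int, index into marker_ids
    slot_idx: np.ndarray           # (N, k) int, shared-param index or -1
    own_slot: np.ndarray           # (N,) int, param index of own interval
    zb: np.ndarray                 # (N, k-1) boundary * sigma_i
    n_per_marker: np.ndarray       # (m,)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_studies(self) -> int:
        return self.x.size


def compile_corpus(corpus: Sequence[StudyResult], spec: ModelSpec) -> CompiledCorpus:
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus is empty")
    marker_ids = tuple(dict.fromkeys(s.marker_id for s in corpus))
    mpos = {mid: i for i, mid in enumerate(marker_ids)}
    n = len(corpus)
    k = spec.n_intervals
    x = np.empty(n)
    sigma = np.empty(n)
    midx = np.empty(n, int)
    slot_idx = np.empty((n, k), int)
    own = np.empty(n, int)
    b = spec.boundaries
    for i, s in enumerate(corpus):
        x[i] = s.x
        sigma[i] = s.sigma
        midx[i] = mpos[s.marker_id]
        row = spec.slot_row(_category_of(s, spec), _sign_ctx(s, spec))
        slot_idx[i] = row
        j = int(np.searchsorted(b, s.z, side="left"))
        own[i] = row[j]
    return CompiledCorpus(
        spec=spec,
        marker_ids=marker_ids,
        x=x,
        sigma=sigma,
        marker_idx=midx,
        slot_idx=slot_idx,
        own_slot=own,
        zb=sigma[:, None] * b[None, :] if b.size else np.empty((n, 0)),
        n_per_marker=np.bincount(midx, minlength=len(marker_ids)),
    )


def per_marker_loglik(
    c: CompiledCorpus,
    theta_w: np.ndarray,
    delta: np.ndarray,
    tau2: np.ndarray,
    idx: np.ndarray = None,
) -> np.ndarray:
    """Vector of marker log likelihoods; NaN where a marker is infeasible.

    A marker is infeasible when some study's total variance sigma_i^2 + tau2
    is nonpositive, or its weighted normalizer underflows.  With ``idx``
    (study indices) only those studies enter the sums: markers not covered
    by the subset report 0 and callers must ignore their entries.
    """
    if idx is None:
        x, sigma, midx = c.x, c.sigma, c.marker_idx
        slot, own, zb = c.slot_idx, c.own_slot, c.zb
    else:
        x, sigma, midx = c.x[idx], c.sigma[idx], c.marker_idx[idx]
        slot, own, zb = c.slot_idx[idx], c.own_slot[idx], c.zb[idx]
    n = x.size
    d = delta[midx]
    v = sigma**2 + tau2[midx]
    ok = v > 0
    v_safe = np.where(ok, v, 1.0)
    sd = np.sqrt(v_safe)

    theta_ext = np.concatenate([np.asarray(theta_w, float), [0.0]])
    if zb.shape[1]:
        args = (zb - d[:, None]) / sd[:, None]
        cdf = ndtr(args)
        probs = np.empty((n, zb.shape[1] + 1))
        probs[:, 0] = cdf[:, 0]
        probs[:, 1:-1] = np.diff(cdf, axis=1)
        probs[:, -1] = ndtr(-args[:, -1])
        np.clip(probs, 0.0, None, out=probs)
        w = np.exp(theta_ext)[slot]  # slot -1 picks the trailing 1.0
        denom = np.einsum("ij,ij->i", w, probs)
    else:
        denom = np.ones(n)
    ok &= denom > _DENOM_FLOOR
    denom_safe = np.where(denom > _DENOM_FLOOR, denom, 1.0)

    own_lw = np.where(own >= 0, theta_ext[own], 0.0)
    ll = (
        own_lw
        - 0.5 * (_LOG_2PI + np.log(v_safe))
        - (x - d) ** 2 / (2.0 * v_safe)
        - np.log(denom_safe)
    )
    out = np.bincount(midx, weights=ll, minlength=c.n_markers)
    bad = np.bincount(midx, weights=(~ok).astype(float),
                      minlength=c.n_markers) > 0
    out[bad] = np.nan
    return out
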