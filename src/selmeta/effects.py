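"""Per-allele effect estimation and temporal study categorization.

The per-allele log odds ratio is the coefficient of allele dose (0/1/2
copies of the variant allele) in a logistic regression of case status, fit
on the six genotype-count cells of a 2x3 table.  The variant column of the
input defines the risk-allele orientation; no re-orientation by frequency
is performed, because the sign convention feeds directly into the
sign-dependent (Proteus) selection models.

Categories: studies published in the same calendar year as a marker's first
publication are "initial"; the next two calendar years are "early"
replications; everything later is "late".  The initial sign of a marker is
the sign of the most extreme initial result (largest |z|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .likelihood import StudyResult

__all__ = [
    "GenotypeTable",
    "per_allele_log_or",
    "woolf_log_or",
    "categorize",
    "categorize_corpus",
    "inclusion_filter",
]


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 genotype counts (cases, controls) x (hom variant, het, wildtype)."""

    cases: tuple        # (hom, het, wt)
    controls: tuple     # (hom, het, wt)
    marker_id: str
    pub_id: str
    year: int

    def __post_init__(self) -> None:
        for grp, counts in (("cases", self.cases), ("controls", self.controls)):
            if len(counts) != 3:
                raise ValueError(f"{grp} needs 3 genotype counts")
            if any(c < 0 or int(c) != c for c in counts):
                raise ValueError(f"{grp} counts must be nonnegative integers")
            if sum(counts) == 0:
                raise ValueError(f"{grp} group is empty for {self.marker_id}/{self.pub_id}")

    def allele_counts(self) -> np.ndarray:
        """Collapsed 2x2 allele table [[case_var, case_ref], [ctrl_var, ctrl_ref]]."""
        out = np.empty((2, 2))
        for r, (hom, het, wt) in enumerate((self.cases, self.controls)):
            n = hom + het + wt
            out[r, 0] = 2 * hom + het
            out[r, 1] = 2 * n - out[r, 0]
        return out


def woolf_log_or(table_2x2: np.ndarray, haldane: bool = True):
    """Woolf estimator on a 2x2 allele table, with the Haldane 0.5
    continuity correction applied to all cells when any cell is zero."""
    t = np.asarray(table_2x2, float)
    if haldane and np.any(t == 0):
        t = t + 0.5
    (a, b), (c, d) = t
    x = np.log(a * d) - np.log(b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return x, se


def per_allele_log_or(t: GenotypeTable) -> tuple:
    """Per-allele log odds ratio and its standard error.

    Fits case/control status on allele dose (0, 1, 2 per subject, with
    genotype counts as frequency weights) by logistic regression; the dose
    coefficient is the per-allele log OR.  On perfect separation (some
    marginal allele count zero) the regression is degenerate and the
    Haldane-corrected Woolf estimate on the collapsed allele table is
    returned instead.
    """
    alleles = t.allele_counts()
    if np.any(alleles == 0):
        return woolf_log_or(alleles)

    dose = np.array([2.0, 1.0, 0.0, 2.0, 1.0, 0.0])
    status = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    freq = np.array(list(t.cases) + list(t.controls), float)
    keep = freq > 0
    X = sm.add_constant(dose[keep])
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.GLM(
                status[keep], X, family=sm.families.Binomial(), freq_weights=freq[keep]
            ).fit()
        except (PerfectSeparationWarning, np.linalg.LinAlgError, ValueError):
            return woolf_log_or(alleles)
    x, se = float(fit.params[1]), float(fit.bse[1])
    if not (np.isfinite(x) and np.isfinite(se)) or se > 1e3:
        return woolf_log_or(alleles)
    return x, se


def categorize(studies: Sequence[StudyResult]) -> tuple:
    """Assign temporal categories and sign context to one marker's studies.

    Returns ``(categorized_studies, initial_sign)`` where the studies are
    new StudyResult objects (input order preserved) with ``category`` set,
    and early studies carry ``sign_agrees``.  ``initial_sign`` is +1 or -1,
    from the most extreme initial result; z = 0 counts as negative, matching
    the left-open/right-closed interval convention of the weight functions.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("no studies to categorize")
    ids = {s.marker_id for s in studies}
    if len(ids) > 1:
        raise ValueError(f"categorize() works per marker; got {sorted(ids)}")
    y0 = min(s.year for s in studies)
    initial = [s for s in studies if s.year == y0]
    most_extreme = max(initial, key=lambda s: abs(s.z))
    initial_sign = 1 if most_extreme.z > 0 else -1
    out = []
    for s in studies:
        if s.year == y0:
            cat, agrees = "initial", None
        elif s.year <= y0 + 2:
            cat = "early"
            agrees = (1 if s.z > 0 else -1) == initial_sign
        else:
            cat, agrees = "late", None
        out.append(
            StudyResult(
                x=s.x, sigma=s.sigma, marker_id=s.marker_id, pub_id=s.pub_id,
                year=s.year, category=cat, sign_agrees=agrees,
            )
        )
    return out, initial_sign


def categorize_corpus(corpus: Sequence[StudyResult]) -> list:
    """Categorize every marker of a corpus; returns a flat study list."""
    df: dict = {}
    for s in corpus:
        df.setdefault(s.marker_id, []).append(s)
    out = []
    for mid in df:
        cat, _ = categorize(df[mid])
        out.extend(cat)
    return out


def inclusion_filter(corpus: Sequence[StudyResult], min_publications: int = 4) -> list:
    """Keep markers reported by at least ``min_publications`` distinct
    publications.  No Hardy-Weinberg or allele-frequency filtering."""
    pubs: dict = {}
    for s in corpus:
        pubs.setdefault(s.marker_id, set()).add(s.pub_id)
    keep = {mid for mid, p in pubs.items() if len(p) >= min_publications}
    return [s for s in corpus if s.marker_id in keep]
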