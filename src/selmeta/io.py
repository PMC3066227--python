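"""Corpus CSV input/output.

Two dialects, both UTF-8 with a header row:

* dialect A (precomputed effects):
  ``marker_id, pub_id, year, log_or, se``
* dialect B (raw 2x3 genotype tables):
  ``marker_id, pub_id, year, case_hom, case_het, case_wt, ctrl_hom,
  ctrl_het, ctrl_wt``

Dialect B rows are converted to per-allele log odds ratios on read.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .effects import GenotypeTable, per_allele_log_or
from .likelihood import StudyResult

__all__ = ["read_corpus", "write_corpus", "corpus_to_frame", "frame_to_corpus"]

_A_COLS = ["marker_id", "pub_id", "year", "log_or", "se"]
_B_COLS = ["marker_id", "pub_id", "year", "case_hom", "case_het", "case_wt",
           "ctrl_hom", "ctrl_het", "ctrl_wt"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [col for col in cols if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def frame_to_corpus(df: pd.DataFrame, dialect: str = "A", source: str = "<frame>"):
    if dialect.upper() == "A":
        _require_columns(df, _A_COLS, source)
        out = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                out.append(StudyResult(
                    x=float(row.log_or), sigma=float(row.se),
                    marker_id=str(row.marker_id), pub_id=str(row.pub_id),
                    year=int(row.year),
                ))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{source}, line {i}: {exc}") from None
        return out
    if dialect.upper() == "B":
        _require_columns(df, _B_COLS, source)
        out = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                table = GenotypeTable(
                    cases=(int(row.case_hom), int(row.case_het), int(row.case_wt)),
                    controls=(int(row.ctrl_hom), int(row.ctrl_het), int(row.ctrl_wt)),
                    marker_id=str(row.marker_id), pub_id=str(row.pub_id),
                    year=int(row.year),
                )
                x, se = per_allele_log_or(table)
                out.append(StudyResult(
                    x=x, sigma=se, marker_id=table.marker_id,
                    pub_id=table.pub_id, year=table.year,
                ))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{source}, line {i}: {exc}") from None
        return out
    raise ValueError(f"unknown dialect {dialect!r}; use 'A' or 'B'")


def read_corpus(path, dialect: str = "A"):
    """Read a study corpus from CSV in dialect A or B."""
    df = pd.read_csv(path)
    return frame_to_corpus(df, dialect, source=str(path))


def corpus_to_frame(corpus: Sequence[StudyResult]) -> pd.DataFrame:
    rows = [{
        "marker_id": s.marker_id, "pub_id": s.pub_id, "year": s.year,
        "log_or": s.x, "se": s.sigma,
    } for s in corpus]
    return pd.DataFrame(rows, columns=_A_COLS)


def write_corpus(corpus: Sequence[StudyResult], path) -> None:
    """Write a corpus as dialect-A CSV."""
    corpus_to_frame(corpus).to_csv(path, index=False)
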