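"""End-to-end analysis and simulation-recovery pipelines.

``run_analysis`` is the full published-corpus workflow: read, derive
effects (dialect B), categorize, apply the inclusion filter, run the
convergence-exclusion protocol across the requested models, fit each model
on the common surviving corpus, and write a comparison table, derived
reporting probabilities, per-marker corrected/uncorrected estimates and an
exclusion log.  ``run_recovery`` simulates corpora under a chosen model and
reports truth-vs-estimate coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as corpus_io
from .effects import categorize_corpus, inclusion_filter
from .inference import (
    FitOptions,
    FitResult,
    corrected_estimates,
    derive_reporting_probability,
    exclusion_protocol,
    fit,
    model_table,
)
from .models import build_model
from .simulate import SimConfig, simulate_corpus

log = logging.getLogger("selmeta")

__all__ = ["RunConfig", "run_analysis", "run_recovery"]

_DERIVABLE = {
    "model1": ["log_w_S"],
    "model2": ["log_w_I", "log_w_S"],
    "model3": ["log_w_I", "log_w_E1", "log_w_E2", "log_w_S"],
    "proteus": ["log_w_I", "log_w_E1", "log_w_E2", "log_w_S",
                ("log_w_E1", "log_w_E2")],
    "high_resolution": [f"log_w_{j + 1}" for j in range(14)],
    "unbiased": [],
}


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    dialect: str = "A"
    models: Sequence[str] = ("unbiased", "model1", "model2", "model3", "proteus")
    effects_mode: str = "random"
    apply_exclusion: bool = True
    min_publications: int = 4
    output_dir: str = "selmeta_out"
    seed: int = 0
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model is required")


def _prepare_corpus(cfg: RunConfig, corpus=None):
    if corpus is None:
        if cfg.input_path is None:
            raise ValueError("either a corpus or an input path is required")
        corpus = corpus_io.read_corpus(cfg.input_path, cfg.dialect)
    corpus = inclusion_filter(corpus, cfg.min_publications)
    if not corpus:
        raise ValueError("no marker passes the inclusion filter")
    return categorize_corpus(corpus)


def run_analysis(cfg: RunConfig, corpus=None) -> dict:
    """Fit the requested models on one corpus and write the report bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = _prepare_corpus(cfg, corpus)
    specs = [build_model(name, cfg.effects_mode) for name in cfg.models]
    opts = cfg.fit_options
    opts.seed = cfg.seed

    errors: dict = {}
    if cfg.apply_exclusion:
        # a model that errors outright is dropped (and reported) so the
        # shared-exclusion protocol can still run for the others
        excluded, per_model, fits = exclusion_protocol(
            corpus, specs, opts, on_error="skip")
        for spec in specs:
            if spec.name not in fits:
                errors[spec.name] = "fit failed during the exclusion protocol"
                log.error("model %s failed during the exclusion protocol",
                          spec.name)
        if not fits:
            raise RuntimeError("every requested model failed to fit")
        for name, ids in per_model.items():
            for mid in ids:
                log.info("exclusion: marker %s failed convergence under %s",
                         mid, name)
        kept = [s for s in corpus if s.marker_id not in excluded]
        log.info("fitted %d models on %d studies / %d markers (%d excluded)",
                 len(fits), len(kept), len({s.marker_id for s in kept}),
                 len(excluded))
    else:
        excluded, per_model = set(), {}
        kept = corpus
        fits = {}
        for spec in specs:
            try:
                fits[spec.name] = fit(kept, spec, opts)
            except Exception as exc:  # keep other models running
                errors[spec.name] = str(exc)
                log.error("model %s failed: %s", spec.name, exc)
    for name, res in fits.items():
        log.info("model %-16s logL=%.3f aic=%.3f converged=%s",
                 name, res.loglik, res.aic, res.converged)

    bundle = {"fits": fits, "errors": errors, "excluded": sorted(excluded),
              "per_model_exclusions": per_model}

    for name, res in fits.items():
        res.to_json(out / f"fit_{name}.json")
    if "unbiased" in fits and len(fits) > 1:
        table = model_table([fits[n] for n in fits], fits["unbiased"])
        table.to_csv(out / "model_table.csv")
        bundle["model_table"] = table
        best = table["delta_aic"].idxmin()
        bundle["best_model"] = best
        if best != "unbiased":
            per_marker, summary = corrected_estimates(fits[best], fits["unbiased"])
            per_marker.to_csv(out / "corrected_estimates.csv")
            bundle["corrected_estimates"] = per_marker
            bundle["correction_summary"] = summary

    derived = []
    for name, res in fits.items():
        for param in _DERIVABLE.get(name, []):
            try:
                eff = derive_reporting_probability(res, param)
            except (KeyError, ValueError):
                continue
            derived.append({"model": name, "parameter": eff.name,
                            "estimate": eff.estimate, "se": eff.se,
                            "point": eff.point, "ci_low": eff.ci_low,
                            "ci_high": eff.ci_high})
    derived_df = pd.DataFrame(derived)
    derived_df.to_csv(out / "reporting_probabilities.csv", index=False)
    bundle["reporting_probabilities"] = derived_df

    with open(out / "exclusions.json", "w") as fh:
        json.dump({"excluded": sorted(excluded),
                   "per_model": {k: list(v) for k, v in per_model.items()}}, fh,
                  indent=1)
    _write_summary(out / "summary.txt", bundle)
    return bundle


def _write_summary(path, bundle) -> None:
    lines = ["selmeta analysis summary", "=" * 24, ""]
    lines.append(f"excluded markers: {len(bundle['excluded'])}")
    if "model_table" in bundle:
        lines.append("")
        lines.append(bundle["model_table"].to_string())
        lines.append("")
        lines.append(f"best model by AIC: {bundle.get('best_model')}")
    if bundle.get("errors"):
        lines.append(f"failed models: {bundle['errors']}")
    Path(path).write_text("\n".join(lines) + "\n")


def run_recovery(simcfg: SimConfig, runcfg: RunConfig,
                 n_replicates: int = 1) -> pd.DataFrame:
    """Simulate ``n_replicates`` corpora and re-estimate the generating
    model; one row per replicate with truth, estimate, SE and a flag for
    the truth lying within 2 reported SEs."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    spec = build_model(simcfg.model, runcfg.effects_mode)
    truth = np.asarray(simcfg.log_weights, float)
    seeds = np.random.SeedSequence(simcfg.seed).generate_state(n_replicates) % (2**31)
    rows = []
    for r in range(n_replicates):
        cfg_r = SimConfig(**{**simcfg.to_dict(), "seed": int(seeds[r])})
        corpus = categorize_corpus(simulate_corpus(cfg_r))
        res = fit(corpus, spec, runcfg.fit_options)
        row = {"replicate": r, "seed": int(seeds[r]), "loglik": res.loglik,
               "converged": res.converged,
               "n_excluded": len(res.excluded_markers)}
        for i, name in enumerate(spec.param_names):
            est, se = res.theta_w[i], res.se_w[i]
            row[f"true_{name}"] = truth[i]
            row[f"est_{name}"] = est
            row[f"se_{name}"] = se
            row[f"covered_{name}"] = bool(abs(est - truth[i]) <= 2.0 * se)
        rows.append(row)
    return pd.DataFrame(rows)
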