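import numpy as np
import pytest

from selmeta import (
    SimConfig,
    StudyResult,
    build_model,
    categorize_corpus,
    exclusion_protocol,
    fit,
    simulate_corpus,
)


def make_corpus(model="model2", log_weights=(-0.8, -0.2), n_markers=40, seed=1,
                **kwargs):
    cfg = SimConfig(seed=seed, n_markers=n_markers, model=model,
                    log_weights=log_weights, **kwargs)
    return categorize_corpus(simulate_corpus(cfg))


@pytest.fixture(scope="session")
def small_corpus():
    """40-marker corpus generated with initial-study selection (model2)."""
    return make_corpus()


@pytest.fixture(scope="session")
def nested_fits(small_corpus):
    """All five comparison models fitted through the shared exclusion
    protocol, so every fit covers the identical corpus (session-cached)."""
    specs = [build_model(name)
             for name in ("unbiased", "model1", "model2", "model3", "proteus")]
    _, _, fits = exclusion_protocol(small_corpus, specs)
    return fits


def toy_marker(xs, sigmas, marker_id="M1", years=None, categories=None):
    """Hand-built single-marker study list."""
    n = len(xs)
    years = years or [2000] * n
    out = []
    for i in range(n):
        out.append(StudyResult(
            x=float(xs[i]), sigma=float(sigmas[i]), marker_id=marker_id,
            pub_id=f"{marker_id}-P{i}", year=int(years[i]),
            category=categories[i] if categories else "late",
        ))
    return out
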