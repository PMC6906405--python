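"""Shared fixtures: tiny graphs and a small simulated case-control panel."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netseed.simulate import CohortSimSpec, VariantSimSpec, simulate_cohort


@pytest.fixture
def square_with_chord() -> nx.Graph:
    """4-cycle A-B-C-D-A plus the chord A-C."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C")])
    return g


@pytest.fixture(scope="session")
def small_null_panel():
    """400 samples, 30 null variants, no stratification."""
    rng = np.random.default_rng(11)
    variants = tuple(
        VariantSimSpec(maf=float(m), odds_ratio=1.0, position=i + 1)
        for i, m in enumerate(rng.uniform(0.1, 0.5, 30))
    )
    spec = CohortSimSpec(n_cases=200, n_controls=200, variants=variants, rng_seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def risk_panel():
    """A panel with two positive-effect variants, paper-like odds ratios."""
    variants = (
        VariantSimSpec(maf=0.08, odds_ratio=2.2, position=100),
        VariantSimSpec(maf=0.12, odds_ratio=1.64, position=200),
    )
    spec = CohortSimSpec(n_cases=300, n_controls=1200, variants=variants, rng_seed=5)
    return simulate_cohort(spec)
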