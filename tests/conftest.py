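"""Shared fixtures: small simulated cohorts and handcrafted matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dmrkit import MethCountMatrix, SampleSheet, SimConfig, simulate_cohort

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """16 samples, 1,500 CpGs, 6 strong planted regions + 2 steroid regions."""
    config = SimConfig(
        n_cases=8,
        n_controls=8,
        n_cpgs=1_500,
        n_dmrs=6,
        n_steroid_regions=2,
        delta_beta=0.30,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture()
def tiny_matrix():
    """4 sites x 3 samples with hand-set counts for exact-value tests."""
    sites = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 150, 400, 100],
            "strand": ["+", "+", "+", "+"],
        }
    )
    total = np.array(
        [
            [20, 30, 40],
            [10, 10, 10],
            [500, 500, 501],
            [9, 100, 100],
        ]
    )
    methylated = np.array(
        [
            [10, 15, 20],
            [1, 2, 3],
            [250, 400, 100],
            [0, 50, 100],
        ]
    )
    return MethCountMatrix(
        sites=sites, samples=["a", "b", "c"], methylated=methylated, total=total
    )


def make_sheet(n_case: int, n_control: int, seed: int = 0) -> SampleSheet:
    """Minimal valid sample sheet with mildly varied covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_case + n_control):
        group = "case" if i < n_case else "control"
        rows.append(
            {
                "sample_id": f"s{i:02d}",
                "group": group,
                "age_years": float(rng.integers(2, 14)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "neutered": int(rng.random() < 0.5),
                "breed": rng.choice(["beagle", "poodle", "shiba"]),
                "steroid": int(rng.random() < 0.3),
                "setting": rng.choice(["site_A", "site_B"]),
                "split": "unassigned",
            }
        )
    return SampleSheet(pd.DataFrame(rows))
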