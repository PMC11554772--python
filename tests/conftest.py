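import numpy as np
import pytest

from nrf2screen.cohort import Cohort, Histology, MutationStatus, Sample
from nrf2screen.simulate import default_params, simulate_cohort


def make_sample(i, histology="LUAD", status="WT", **kwargs):
    return Sample(
        sample_id=f"S{i}",
        histology=Histology(histology),
        mutation_status=MutationStatus(status),
        **kwargs,
    )


@pytest.fixture
def tiny_cohort():
    """Three samples (two LUAD, one LUSC) with one-gene expression."""
    samples = (
        make_sample(1, "LUAD", "KEAP1mut", expression={"NQO1": 8.0}, h_score=250),
        make_sample(2, "LUAD", "WT", expression={"NQO1": 5.0}, h_score=40),
        make_sample(3, "LUSC", "NFE2L2mut", expression={"NQO1": 7.5}),
    )
    return Cohort(samples=samples, panel=("NQO1",))


def random_cohort(seed, n=30, with_missing=True):
    """Small random cohort with realistic missingness for IO round trips."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        samples.append(
            Sample(
                sample_id=f"R{i:03d}",
                histology=rng.choice(["LUAD", "LUSC"]),
                mutation_status=rng.choice(["KEAP1mut", "NFE2L2mut", "WT"]),
                expression={
                    g: float(rng.normal())
                    for g in ("NQO1", "TXNRD1")
                    if not (with_missing and rng.random() < 0.15)
                },
                h_score=(
                    None if with_missing and rng.random() < 0.3
                    else int(rng.integers(0, 301))
                ),
                k1n2_score=(
                    None if with_missing and rng.random() < 0.2
                    else float(rng.normal())
                ),
                k1n2_call=(None if with_missing and rng.random() < 0.2
                           else bool(rng.random() < 0.5)),
                pathway_active_truth=bool(rng.random() < 0.5),
            )
        )
    return Cohort(samples=tuple(samples), panel=("NQO1", "TXNRD1"))


@pytest.fixture(scope="session")
def paper_like_cohort():
    """One mutation-enriched synthetic cohort at the default study size."""
    return simulate_cohort(default_params("paper_like", n_samples=348, seed=11))
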