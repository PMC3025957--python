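"""Shared fixtures: simulated datasets and one fully analyzed scenario run."""

from __future__ import annotations

import numpy as np
import pytest

import mtconcert as m
from mtconcert.cli import RunConfig, analyze_copies


@pytest.fixture(scope="session")
def default_sim() -> m.SimResult:
    return m.simulate_dataset(m.default_scenario(seed=1))


@pytest.fixture(scope="session")
def scenario_copies(default_sim) -> list[m.LabeledSeq]:
    copies = []
    for g in default_sim.genomes:
        pair = m.detect_duplication(g)
        assert pair is not None
        copies.extend(m.extract_copies(g, pair))
    return copies


@pytest.fixture(scope="session")
def scenario_result(scenario_copies):
    return analyze_copies(scenario_copies, RunConfig(seed=1))


@pytest.fixture(scope="session")
def scenario_alignment(scenario_result) -> m.JointAlignment:
    return scenario_result.aln


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_alignment(rows: dict[str, str]) -> m.JointAlignment:
    """Build a JointAlignment directly from label -> gapped row (tests only)."""
    labels = []
    matrix = []
    for lab, row in rows.items():
        ind, cp = lab.rsplit("-", 1)
        labels.append((ind, cp))
        matrix.append(row)
    n = len(matrix[0])
    ref = matrix[0]
    ref_map, k = [], 0
    for ch in ref:
        if ch == "-":
            ref_map.append(-1)
        else:
            ref_map.append(k)
            k += 1
    return m.JointAlignment(
        row_labels=labels,
        matrix=matrix,
        reference_label=f"{labels[0][0]}-{labels[0][1]}",
        ref_map=np.array(ref_map),
    )
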