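"""Shared fixtures: toy genomes and simulated cells.

Expensive cohorts are session-scoped so the acceptance tests that look at
different aspects of the same study conditions (architecture recovery,
cohort contrasts) reuse one simulation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from dip3d import (
    NAIVE_LIKE, PRIMED_LIKE, CellArchetype, make_toy_genome, sample_contacts,
    simulate_cohort, simulate_structure,
)
from dip3d.impute import impute_pipeline

#: archetype used where a single nondescript "default" cell is needed
DEFAULT_CELL = CellArchetype(name="custom", seed=11)


@pytest.fixture(scope="session")
def toy():
    """Default toy genome: 3 chromosomes x 2 Mb at 20-kb bins."""
    return make_toy_genome(seed=7)


@pytest.fixture(scope="session")
def small():
    """Tiny genome for unit tests: 2 chromosomes x 400 kb (40 bins diploid)."""
    return make_toy_genome(n_chrom=2, chrom_length=400_000, seed=3)


@pytest.fixture(scope="session")
def small_cell(small):
    genome, cpg = small
    arch = replace(DEFAULT_CELL, n_contacts=2_000, capture_radius=2.5, seed=4)
    structure = simulate_structure(genome, cpg, arch, n_sweeps=200)
    contacts, truth = sample_contacts(structure, arch)
    return structure, contacts, truth, arch


@pytest.fixture(scope="session")
def default_cell(toy):
    """One default toy cell: 600 diploid particles, 20,000 contacts,
    phase rate 0.3."""
    genome, cpg = toy
    structure = simulate_structure(genome, cpg, DEFAULT_CELL)
    contacts, truth = sample_contacts(structure, DEFAULT_CELL)
    return structure, contacts, truth


@pytest.fixture(scope="session")
def imputed_default_cell(default_cell):
    structure, contacts, truth = default_cell
    return structure, contacts, truth, impute_pipeline(contacts)


@pytest.fixture(scope="session")
def cohort(toy):
    """10 naive-like + 10 primed-like cells under the default conditions."""
    genome, cpg = toy
    return simulate_cohort(10, [NAIVE_LIKE, PRIMED_LIKE], genome, cpg, base_seed=2024)
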