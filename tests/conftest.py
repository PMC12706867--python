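import math

import numpy as np
import pytest

import editbench as eb

# reduced-scale simulation settings shared across tests: small libraries keep
# the exact test's conditional enumeration cheap while leaving per-gene counts
# in the hundreds, comfortably informative for all engines
SMALL_LIB = math.log(2e5)


def null_params(n_genes=1000, phi=0.05, seed=0, **kw):
    """Pure-null generator: one line, no line/batch structure, no edits."""
    return eb.SimulationParams(
        n_genes=n_genes,
        libsize_logmean=SMALL_LIB,
        sigma_line=0.0,
        sigma_batch=0.0,
        edit_effects={},
        dispersion_shape=1e6,
        dispersion_scale=phi / 1e6,  # essentially constant dispersion = phi
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def null_counts_3v3():
    design = eb.make_design(1, 3, 3)
    counts, _ = eb.simulate_counts(design, null_params(seed=101))
    return design, counts


@pytest.fixture(scope="session")
def four_line_counts():
    """Four-line design with default-style structure at reduced gene count."""
    design = eb.make_design(4, 3, 3)
    params = eb.SimulationParams(
        n_genes=1200,
        libsize_logmean=SMALL_LIB,
        n_edit_genes=60,
        seed=202,
    )
    counts, truth = eb.simulate_counts(design, params)
    return design, counts, truth
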