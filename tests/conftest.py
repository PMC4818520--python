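import numpy as np
import pytest

import multitrans as mt


@pytest.fixture(scope="session")
def small_panel():
    """Structured 60x120 raw panel with local LD (fast, shared read-only)."""
    cfg = mt.SynthConfig(
        n_individuals=60, n_markers=120, n_populations=2, fst=0.2,
        ld_rho=0.7, seed=12345,
    )
    return mt.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_study():
    """Filtered/standardized study bundle with kinship and an h2=0.5 phenotype."""
    cfg = mt.SynthConfig(
        n_individuals=80, n_markers=200, n_populations=2, fst=0.2,
        ld_rho=0.7, seed=54321,
    )
    return mt.make_study(cfg, h2=0.5)


@pytest.fixture()
def toy_matrix_file(tmp_path):
    """Three marker rows, two individuals, one NA, positions out of order."""
    path = tmp_path / "toy.geno.txt"
    path.write_text(
        "1 snp1 100 A 0 1\n"
        "1 snp2 300 A 2 1\n"
        "1 snp3 200 A 1 NA\n"
    )
    return path
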