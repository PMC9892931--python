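import numpy as np
import pandas as pd
import pytest

from phagoscreen.differential import estimate_dispersions, size_factors, wald_test
from phagoscreen.library import CONTROL_GENE, LibraryEntry, LibraryIndex
from phagoscreen.simulate import SimConfig, simulate_screen


def make_library(n_genes=3, guides_per_gene=2, n_controls=1, spacer_len=20, seed=0):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    entries = []
    seen = set()

    def spacer():
        while True:
            s = "".join(alphabet[rng.integers(0, 4, spacer_len)])
            if s not in seen:
                seen.add(s)
                return s

    for g in range(n_genes):
        for j in range(guides_per_gene):
            entries.append(
                LibraryEntry(f"g{g + 1}_{j + 1}", f"GENE{g + 1}", spacer(), False)
            )
    for c in range(n_controls):
        entries.append(LibraryEntry(f"c{c + 1}", CONTROL_GENE, spacer(), True))
    return LibraryIndex(entries)


@pytest.fixture
def tiny_library():
    return make_library()


@pytest.fixture(scope="session")
def planted_screen():
    """Small screen with planted depletion, shared across read-only tests."""
    cfg = SimConfig(seed=11, n_genes=300, planted_fraction=0.05)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def planted_sgrna_stats(planted_screen):
    _, matrix, _ = planted_screen
    norm = size_factors(matrix)
    disp = estimate_dispersions(matrix, norm)
    return wald_test(matrix, norm, disp, ("PhagoLate", "PhagoNeg"))


def sample_meta(conditions):
    """Metadata frame from {condition: n_replicates}."""
    rows = [
        {"sample_id": f"{c}_r{r}", "condition": c, "replicate": r}
        for c, n in conditions.items()
        for r in range(1, n + 1)
    ]
    return pd.DataFrame(rows)
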