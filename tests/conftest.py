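import numpy as np
import pandas as pd
import pytest

from deepgwas.popgen import GenotypePanel


@pytest.fixture
def panel_factory():
    """Build a small panel from an individuals × variants dosage matrix."""

    def make(G, chrom="1", spacing=1_000, pos=None, chroms=None):
        G = np.asarray(G, dtype=float)
        n_var = G.shape[1]
        positions = pos if pos is not None else 1_000 + spacing * np.arange(n_var)
        chrom_col = chroms if chroms is not None else [chrom] * n_var
        variants = pd.DataFrame(
            {
                "chrom": [str(c) for c in chrom_col],
                "pos": np.asarray(positions, dtype=int),
                "variant_id": [f"v{i}" for i in range(n_var)],
                "ref": ["A"] * n_var,
                "alt": ["G"] * n_var,
            }
        )
        variants["key"] = (
            variants["chrom"] + ":" + variants["pos"].astype(str) + ":A:G"
        )
        return GenotypePanel(variants=variants, genotypes=G)

    return make


@pytest.fixture
def random_panel(panel_factory):
    """A 100-individual, 50-variant polymorphic panel with LD structure."""
    rng = np.random.default_rng(7)
    shared = rng.standard_normal((100, 1))
    latent = 0.6 * shared + 0.8 * rng.standard_normal((100, 50))
    G = (latent < -0.3).astype(float) + (latent < 0.5).astype(float)
    return panel_factory(G, spacing=50_000)
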