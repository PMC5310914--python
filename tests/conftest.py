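import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mutspect.io import Reference, VariantPanel

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_panel(sequence: str, records, n_samples: int, chrom: str = "chr1") -> tuple[VariantPanel, Reference]:
    """Build a tiny panel by hand.

    ``records``: list of (pos_1based, ref, alt, aa, {sample_index: alt_count}).
    """
    rows = []
    genos = []
    for pos, ref, alt, aa, gts in records:
        rows.append((chrom, pos, ref, alt, aa))
        g = np.zeros(n_samples, dtype=np.int8)
        for j, c in gts.items():
            g[j] = c
        genos.append(g)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "aa"])
    genotypes = np.vstack(genos) if genos else np.zeros((0, n_samples), dtype=np.int8)
    samples = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n_samples)],
            "population": ["pop0"] * n_samples,
            "region": ["region0"] * n_samples,
            "source": ["tissue"] * n_samples,
        }
    )
    return VariantPanel(variants, genotypes, samples), Reference({chrom: sequence})


@pytest.fixture(scope="session")
def small_reference():
    from mutspect.synthetic_data import SyntheticGenomeSpec, generate_reference

    ref, freqs = generate_reference(SyntheticGenomeSpec(length=120_000, seed=11))
    return ref, freqs
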