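import numpy as np
import pandas as pd
import pytest

from eqtlscan import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one planted cis effect and one trans hotspot."""
    cfg = SimulationConfig(
        n_individuals=400,
        n_snps=60,
        n_probes=12,
        cis_effects=[(15, 0, 0.8)],
        trans_hotspots=[(35, [5, 6, 7], [0.6, 0.6, -0.6])],
        n_confounders=2,
        trait_models=[("trait_a", "probe", 5, 1.0, 1.0), ("trait_b", "snp", 35, 0.5, 1.0)],
        seed=20201,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_genotypes(dosages, chrom="1", spacing=10_000):
    """Build a GenotypeMatrix from a raw dosage array."""
    from eqtlscan import GenotypeMatrix

    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j:05d}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(m) * spacing,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(dosages=dosages, samples=[f"i{r}" for r in range(n)], snps=snps)
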