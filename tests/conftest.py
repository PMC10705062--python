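import numpy as np
import pandas as pd
import pytest

from sweepscan import ChromLengths, GenotypeMatrix, SimConfig, SweepSpec, simulate


def make_gm(dosage, positions=None, chrom="1", pops=None, samples=None):
    """Build a small GenotypeMatrix from a dosage array (samples x variants)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n)]
    if pops is None:
        pops = {s: "POP" for s in samples}
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "id": [f"v{j}" for j in range(m)],
        }
    )
    return GenotypeMatrix(
        samples=samples, pops=pops, variants=variants, dosage=dosage
    )


@pytest.fixture(scope="session")
def k2_sim():
    """Two clearly differentiated populations (F=0.3), ~2,000 SNPs, 25+25."""
    cfg = SimConfig(
        pop_sizes={"A": 25, "B": 25},
        group_of={"A": "indigenous", "B": "commercial"},
        chrom_lengths=ChromLengths.from_mapping({"1": 800_000}),
        snp_density=1.0 / 400.0,
        baseline_F=0.3,
        seed=11,
    )
    return cfg, *simulate(cfg)


@pytest.fixture(scope="session")
def sweep_sim():
    """5 Mb toy genome, 2 populations of 15 per group, one implanted sweep
    (8x diversity reduction) in the indigenous group."""
    cfg = SimConfig(
        pop_sizes={"I1": 15, "I2": 15, "C1": 15, "C2": 15},
        group_of={
            "I1": "indigenous", "I2": "indigenous",
            "C1": "commercial", "C2": "commercial",
        },
        chrom_lengths=ChromLengths.from_mapping({"1": 5_000_000}),
        baseline_F=0.05,
        sweep_specs=[SweepSpec("1", 2_000_001, 2_200_000, "indigenous", 8.0)],
        seed=7,
    )
    return cfg, *simulate(cfg)
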