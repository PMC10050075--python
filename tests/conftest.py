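import numpy as np
import pytest

from crdomics.containers import QuantificationMatrix


@pytest.fixture
def make_matrix():
    """Factory for small phenotype matrices with evenly spaced peaks."""

    def _make(values, chrom=None, start=None, end=None, ids=None,
              phenotype_class="peak", spacing=10_000, width=500):
        values = np.asarray(values, dtype=float)
        p, n = values.shape
        chrom = chrom if chrom is not None else ["1"] * p
        start = start if start is not None else [i * spacing for i in range(p)]
        end = end if end is not None else [s + width for s in start]
        ids = ids if ids is not None else [f"pk{i:03d}" for i in range(p)]
        return QuantificationMatrix(
            np.array(ids, dtype=object), np.array(chrom, dtype=object),
            np.array(start), np.array(end), values,
            [f"S{j}" for j in range(n)], phenotype_class,
        )

    return _make


@pytest.fixture(scope="session")
def planted_population():
    """Six 10-peak blocks (r=0.7) on three chromosomes, with QTLs,
    cis genes and two trans couplings; n=300."""
    from crdomics.simulate import SimulationConfig, simulate_population

    cfg = SimulationConfig(
        n_samples=300,
        blocks=[(10, 0.7)] * 6,
        blocks_per_chrom=2,
        background_peaks_per_chrom=40,
        qtls=[(b, 0.25) for b in range(4)],
        genes=[(b, 0.3) for b in range(6)] + [(None, 0.0)] * 4,
        trans=[(0, 2, 0.6), (1, 3, 0.6)],
        seed=11,
    )
    return cfg, simulate_population(cfg)
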