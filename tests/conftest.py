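"""Shared fixtures: small seeded genomes, probe sets, and simulated bundles.

Everything is generated programmatically at collection time; the scales
are small (a few hundred kb) so the whole suite stays fast. Acceptance
tests build their own demo-scale fixture in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from meklchip import synthetic_data as sd
from meklchip.types import ArraySample, ProbeSet


@pytest.fixture(scope="session")
def genome():
    """~200 kb genome with CpG islands (seeded)."""
    return sd.generate_genome(200_000, 0.06, seed=11)


@pytest.fixture(scope="session")
def probes(genome):
    return sd.tile_probes(genome, n_control=300, n_antigenomic=300)


@pytest.fixture(scope="session")
def truth(genome):
    return sd.plant_dmrs(genome, 5, seed=12)


@pytest.fixture(scope="session")
def clean_truth(genome):
    """Truth with zero noise and no dropout at 250 ng."""
    return sd.plant_dmrs(
        genome,
        5,
        seed=12,
        noise_sd_by_input_ng={250: 0.0},
        dropout_by_input_ng={250: 0.0},
    )


@pytest.fixture(scope="session")
def clean_bundle(genome, probes, clean_truth):
    """Noise-free, bias-free 3v3 bundle: intensities equal expectations."""
    return sd.simulate_bundle(
        genome, probes, clean_truth, 3, 250, seed=13, dye_bias_strength=0.0
    )


@pytest.fixture(scope="session")
def noisy_bundle(genome, probes, truth):
    """Default-noise 3v3 bundle at 250 ng with dye bias on."""
    return sd.simulate_bundle(genome, probes, truth, 3, 250, seed=14)


def make_probe_set(
    starts,
    chrom="chr1",
    length=50,
    n_control=0,
    n_antigenomic=0,
    cpg_count=1,
):
    """Hand-built ProbeSet for unit tests."""
    n = len(starts)
    rows = {
        "probe_id": [f"P{i:04d}" for i in range(n)],
        "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
        "start": list(starts),
        "length": length,
        "is_control": False,
        "is_antigenomic": False,
        "cpg_count": cpg_count,
    }
    df = pd.DataFrame(rows)
    extra = []
    for j in range(n_control):
        extra.append((f"C{j:04d}", "*", -1, length, True, False, 0))
    for j in range(n_antigenomic):
        extra.append((f"A{j:04d}", "*", -1, length, False, True, 0))
    if extra:
        df = pd.concat(
            [df, pd.DataFrame(extra, columns=df.columns)], ignore_index=True
        )
    return ProbeSet(df)


def make_sample(probes, input_intensity, enriched_intensity, **kw):
    defaults = dict(sample_id="s1", tissue="t1", input_ng=250, replicate=1)
    defaults.update(kw)
    return ArraySample(
        input_intensity=np.asarray(input_intensity, float),
        enriched_intensity=np.asarray(enriched_intensity, float),
        **defaults,
    )
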