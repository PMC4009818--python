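"""Shared fixtures: a small but complete simulated screen and record builders."""

from __future__ import annotations

import pytest

from emscreen.simulator import SimulationConfig, generate_screen, simulate_screen
from emscreen.variant_model import GenotypeCall, VariantRecord, VariantSite, Zygosity

#: compact study conditions for fast tests: same densities and rates as the
#: defaults, one tenth of the sequence
TINY = dict(
    arms=(("3L", 200_000), ("2R", 100_000)),
    gene_count=24,
    background_density=3000,
    n_unrelated=4,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    """A complete in-memory screen: background, 3 mutants, 4 unrelated."""
    return simulate_screen(tiny_config)


@pytest.fixture(scope="session")
def tiny_screen_dir(tiny_config, tmp_path_factory):
    """The same screen written to disk (FASTA/GFF3/WIG/VCFs/manifest/truth)."""
    outdir = tmp_path_factory.mktemp("screen") / "fixture"
    return generate_screen(tiny_config, outdir)


def make_record(
    chrom: str = "3L",
    pos: int = 100,
    ref: str = "G",
    alt: str = "A",
    zygosity: Zygosity = Zygosity.HET,
    gq: int | None = 90,
    qual: float = 200.0,
    sample: str = "s1",
    depth: int | None = 30,
) -> VariantRecord:
    if zygosity is Zygosity.MISSING:
        call = GenotypeCall(sample, zygosity)
    else:
        call = GenotypeCall(sample, zygosity, gq=gq, depth=depth)
    return VariantRecord(VariantSite(chrom, pos, ref, alt), qual, {sample: call})


@pytest.fixture
def record_factory():
    return make_record
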