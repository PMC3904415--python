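"""Shared helpers: run the caller on generated fixtures, build random
fixture configurations, and convert call records for oracle comparison."""

from __future__ import annotations

from random import Random

import pysam
import pytest

from paircall import (
    DEL,
    INS,
    SNV,
    FixtureConfig,
    PlantedSpec,
    QualityProfile,
    Thresholds,
    call_variants_file,
    generate_fixture,
)

# min_overlap matched to the default fixture geometry: a mate spans the
# full amplicon region (insert + 2 primers), so its on-insert fraction is
# insert / region, e.g. 100/140 ~ 0.714 for the default design.
FIXTURE_OVERLAP = 0.7


def call_fixture(fx, thresholds: Thresholds, sample: str = "sample"):
    """Open the fixture's BAM and run the caller over its amplicons."""
    with pysam.AlignmentFile(str(fx.bam_path)) as bam:
        return call_variants_file(bam, fx.amplicons, thresholds, sample)


def call_identity(record) -> tuple:
    """Reduce a CallRecord to the oracle's comparison tuple."""
    v = record.variant
    return ((v.chrom, v.pos, v.kind, v.ref, v.alt), record.amplicon_name,
            record.pair_count, record.total_pairs)


def random_planted(rng: Random, config_kwargs: dict) -> list[PlantedSpec]:
    """A random non-overlapping mix of planted variants."""
    n_amp = config_kwargs["n_amplicons"]
    insert = config_kwargs["insert_length"]
    planted = []
    for amp in range(n_amp):
        offset = 2
        for _ in range(rng.randint(0, 3)):
            offset += rng.randint(0, insert // 4)
            kind = rng.choice([SNV, SNV, INS, DEL])
            length = rng.randint(1, 3)
            if kind == INS and offset >= insert - 1:
                break
            if kind == DEL and offset + length > insert:
                break
            if offset >= insert:
                break
            planted.append(PlantedSpec(
                amplicon_index=amp, kind=kind, offset=offset,
                allele_fraction=rng.choice([0.1, 0.5, 1.0]),
                alt="".join(rng.choice("ACGT") for _ in range(length))
                if kind == INS else None,
                length=length,
            ))
            offset += length + 2
    return planted


def random_fixture_config(seed: int) -> FixtureConfig:
    """A varied, small fixture: <= 5 amplicons, <= 200 pairs in total."""
    rng = Random(seed)
    kwargs = dict(
        n_amplicons=rng.randint(1, 5),
        insert_length=rng.choice([60, 80, 100]),
        primer_length=rng.choice([15, 20]),
        read_length=150,
        pairs_per_amplicon=rng.randint(10, 40),
        per_base_error_rate=rng.choice([0.0, 0.002, 0.01]),
        quality=rng.choice([
            QualityProfile(),
            QualityProfile(high=38, low=12, low_fraction=0.1),
        ]),
    )
    planted = random_planted(rng, kwargs)
    return FixtureConfig(seed=seed, planted=planted, **kwargs)


@pytest.fixture
def het_fixture(tmp_path):
    """One amplicon, error-free, a heterozygous SNV and a homozygous DEL."""
    config = FixtureConfig(
        seed=11,
        n_amplicons=1,
        pairs_per_amplicon=20,
        planted=[
            PlantedSpec(0, SNV, 30, 0.5),
            PlantedSpec(0, DEL, 60, 1.0, length=2),
        ],
    )
    return generate_fixture(config, tmp_path / "het_fixture")
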