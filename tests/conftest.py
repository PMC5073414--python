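import pytest

from reglink import (
    PostalCityTable,
    RegistryRecord,
    SourceRecord,
    StandardizedRecord,
    SyntheticConfig,
    derive_source,
    generate_registry,
)
from reglink.standardize import standardize_registry, standardize_source


@pytest.fixture(scope="session")
def toy_table():
    return PostalCityTable(
        [("M", "TORONTO"), ("K1", "OTTAWA"), ("K", "EASTERN"),
         ("L", "CENTRAL"), ("N", "SOUTHWEST"), ("P", "NORTHERN")]
    )


@pytest.fixture(scope="session")
def noise_free_config():
    return SyntheticConfig(
        n_registry=400, n_source=150, kind="immigration", seed=11,
        unlinkable_frac=0.0, dup_frac=0.0, typo_rate=0.0,
        phonetic_swap_rate=0.0, date_transpose_rate=0.0, missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def noisy_small():
    """A small noisy study: (registry, source, truth) with defaults."""
    cfg = SyntheticConfig(n_registry=800, n_source=300, kind="immigration", seed=3)
    reg = generate_registry(cfg)
    src, truth = derive_source(cfg, reg)
    return reg, src, truth


@pytest.fixture(scope="session")
def std_pair(noisy_small, toy_table):
    """Standardized (source, registry) record lists for the noisy study."""
    reg, src, _ = noisy_small
    return standardize_source(src, toy_table), standardize_registry(reg, toy_table)


def make_std(rid="X1", **kw) -> StandardizedRecord:
    """Shorthand standardized record for unit tests."""
    defaults = dict(
        surname_clean="SMITH", given_clean=("ANNA",), surname_nysiis="SNAT",
        given_initial="A", birth_year=1970, birth_month=4, birth_day=9,
        sex="F", city_code="TORONTO",
    )
    defaults.update(kw)
    return StandardizedRecord(rid=rid, **defaults)
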