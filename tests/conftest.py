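import numpy as np
import pytest

from plastidkit import build_usage_table
from plastidkit.codon_stats import CdsRecord, synonym_families, STOP_SYMBOL
from plastidkit.synth import UsageProfileSpec, gen_cds_set


def random_cds(rng: np.random.Generator, n_codons: int | None = None) -> CdsRecord:
    """A random in-frame CDS: ATG start, random sense interior, one stop."""
    fams = synonym_families(11)
    sense = sorted(c for aa, cs in fams.items() if aa != STOP_SYMBOL for c in cs)
    stops = sorted(fams[STOP_SYMBOL])
    if n_codons is None:
        n_codons = int(rng.integers(5, 60))
    interior = [sense[i] for i in rng.integers(len(sense), size=n_codons - 2)]
    seq = "ATG" + "".join(interior) + stops[rng.integers(len(stops))]
    return CdsRecord(id=f"rand_{rng.integers(1 << 30)}", sequence=seq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151203)


@pytest.fixture(scope="session")
def at_rich_profile():
    """A synonymous-frequency profile targeting plastome-like GC3 ~ 0.121."""
    return UsageProfileSpec.from_gc3(0.121)


@pytest.fixture(scope="session")
def at_rich_table(at_rich_profile):
    return at_rich_profile.to_usage_table()


@pytest.fixture(scope="session")
def reference_cds_set(at_rich_profile):
    records, _ = gen_cds_set(40, 120, at_rich_profile, rng_seed=11)
    return records


@pytest.fixture(scope="session")
def reference_table(reference_cds_set):
    return build_usage_table(reference_cds_set)
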