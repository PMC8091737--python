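import io

import pytest

from yeastchar import rdna, synth


@pytest.fixture(scope="session")
def primers():
    return rdna.DEFAULT_PRIMERS


@pytest.fixture()
def planted_rdna():
    """A 3-contig genome with 9 planted copies carrying 12 variants."""
    lengths = {f"c{i}": 12_000 for i in range(3)}
    plan = synth.random_copy_plan(lengths, n_copies=9, n_variants=12, seed=11)
    genome, truth = synth.gen_rdna_genome(lengths, plan, seed=11)
    return genome, truth, lengths


@pytest.fixture()
def plate_csv_text():
    series, truth = synth.gen_pm_plate(seed=3)
    return synth.plates_to_csv([series]), truth


def make_gff(text: str) -> io.StringIO:
    return io.StringIO(text)
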