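import pytest

import dietshift as ds


@pytest.fixture(scope="session")
def catalog():
    return ds.default_catalog()


@pytest.fixture()
def toy_table():
    """Three mass-based samples from one year with hand-checkable indices.

    s1: polar cod 10 g + T. inermis 2 g; s2: capelin 5 g + polar cod 5 g;
    s3: T. inermis 3 g.
    """
    def sample(sid, items):
        return ds.DietSample(sample_id=sid, year=2000,
                             items=tuple(ds.PreyItem(t, m) for t, m in items))

    return ds.SampleTable([
        sample("s1", [("polar cod", 10.0), ("Thysanoessa inermis", 2.0)]),
        sample("s2", [("capelin", 5.0), ("polar cod", 5.0)]),
        sample("s3", [("Thysanoessa inermis", 3.0)]),
    ])


@pytest.fixture(scope="session")
def generated_table():
    return ds.generate_samples(seed=101)


@pytest.fixture(scope="session")
def generated_fo(generated_table, catalog):
    return ds.occurrence_frequencies(generated_table, level="taxon",
                                     catalog=catalog)
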