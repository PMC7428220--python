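import textwrap

import pytest

from raretrends import core_io


@pytest.fixture
def tiny_csv(tmp_path):
    """Two assemblages, BioTIME-style columns: 4 records for A, 2 for B."""
    p = tmp_path / "tiny.csv"
    p.write_text(textwrap.dedent("""\
        STUDY_ID,YEAR,SAMPLE_DESC,GENUS_SPECIES,sum.allrawdata.ABUNDANCE
        A,2000,s1,sp1,3
        A,2000,s1,sp2,1
        A,2001,s1,sp1,2
        A,2001,s1,sp3,5
        B,2000,s1,sp1,7
        B,2001,s1,sp2,1
    """))
    return p


def make_series(rows, assemblage_id="A", is_aggregable=True):
    """Series from (year, sample_id, species_id, abundance) tuples."""
    import pandas as pd

    df = pd.DataFrame(rows, columns=["year", "sample_id", "species_id", "abundance"])
    return core_io.AssemblageTimeSeries(assemblage_id, df, is_aggregable)


@pytest.fixture
def series_factory():
    return make_series
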