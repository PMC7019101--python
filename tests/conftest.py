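import pytest

from nupvar.synthetic_data import nup155_variants


@pytest.fixture(scope="session")
def nup155():
    """The packaged 24-variant NUP155 table (published annotation scores)."""
    return nup155_variants()


@pytest.fixture()
def by_change(nup155):
    return {str(v.protein_change): v for v in nup155}
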