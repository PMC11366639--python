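import warnings

import pytest

from pvdevol.templates import load_reference_table, load_template_library

# the segmenter warns about missing TE domains etc. on purpose-built fixtures
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def library():
    return load_template_library()


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def substrate_names(reference_table):
    return [e.substrate for e in reference_table]
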