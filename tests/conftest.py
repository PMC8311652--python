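import io
import textwrap

import pytest

from epipharm import load_reference_registry
from epipharm.ora import parse_ontology


@pytest.fixture(scope="session")
def reference_registry():
    return load_reference_registry()


@pytest.fixture()
def chain_dag():
    """Three-term chain: child -> mid -> root."""
    obo = textwrap.dedent(
        """\
        format-version: 1.2
        ontology: test

        [Term]
        id: T:0000001
        name: root
        namespace: molecular_function

        [Term]
        id: T:0000002
        name: mid
        namespace: molecular_function
        is_a: T:0000001

        [Term]
        id: T:0000003
        name: child
        namespace: molecular_function
        is_a: T:0000002
        """
    )
    return parse_ontology(io.StringIO(obo))
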