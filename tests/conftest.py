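import io
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from gosets.fixtures import FixtureSpec, make_ontology
from gosets.ontology import parse_obo

MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child process
namespace: biological_process
alt_id: GO:0000008
is_a: GO:0000001

[Term]
id: GO:0000003
name: obsolete process
namespace: biological_process
is_obsolete: true
replaced_by: GO:0000002
"""

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: mid
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
is_a: GO:0000002
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: left
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: right
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: bottom
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003
"""


@pytest.fixture
def minimal_dag():
    return parse_obo(io.StringIO(MINIMAL_OBO))


@pytest.fixture
def chain_dag():
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_dag():
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def fixture_dag_and_truth():
    spec = FixtureSpec(n_terms=80, n_genes=60, n_assocs=300, seed=11)
    obo_text, truth = make_ontology(spec)
    return parse_obo(io.StringIO(obo_text)), truth, spec
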