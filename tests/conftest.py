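"""Shared fixtures: tiny hand-written ontology/annotation/network files and
small similarity views used across the suite. All fixtures are generated at
test time; nothing binary is stored."""

from __future__ import annotations

import numpy as np
import pytest

from cmvmc.datamodel import Partition, SimilarityView

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child process
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: grandchild process
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: root function
namespace: molecular_function

[Term]
id: GO:0000005
name: gone process
namespace: biological_process
is_obsolete: true
"""

# GAF 2.1: DB, object id, symbol, qualifier, GO id, ref, evidence, with,
# aspect, ... (only the first nine columns matter to the reader)
TOY_GAF = """\
!gaf-version: 2.1
DB\tA1\tgeneA\t\tGO:0000002\tREF:1\tIEA\t\tP\tdesc\t\tprotein\ttaxon:9606\t20200101\tDB
DB\tB1\tgeneB\t\tGO:0000003\tREF:1\tIEA\t\tP\tdesc\t\tprotein\ttaxon:9606\t20200101\tDB
DB\tB1\tgeneB\t\tGO:0000004\tREF:1\tIEA\t\tF\tdesc\t\tprotein\ttaxon:9606\t20200101\tDB
DB\tC1\tgeneC\t\tGO:0000005\tREF:1\tIEA\t\tP\tdesc\t\tprotein\ttaxon:9606\t20200101\tDB
DB\tD1\tgeneD\t\tGO:0000004\tREF:1\tIEA\t\tF\tdesc\t\tprotein\ttaxon:9606\t20200101\tDB
"""

# 4 edge lines: one duplicate pair (kept at max confidence), one self-loop
TOY_PPIN = """\
geneA\tgeneB\t0.9
geneB\tgeneC
geneA\tgeneB\t0.5
geneD\tgeneD\t1.0
"""


@pytest.fixture
def obo_file(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def gaf_file(tmp_path):
    path = tmp_path / "toy.gaf"
    path.write_text(TOY_GAF)
    return path


@pytest.fixture
def ppin_file(tmp_path):
    path = tmp_path / "toy_ppin.tsv"
    path.write_text(TOY_PPIN)
    return path


def make_view(matrix, ids=None) -> SimilarityView:
    m = np.asarray(matrix, dtype=float)
    ids = ids if ids is not None else [f"g{i}" for i in range(m.shape[0])]
    return SimilarityView(list(ids), m)


def random_partition(n: int, k: int, rng: np.random.Generator) -> Partition:
    """Random total assignment guaranteed to use all k labels."""
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)
    return Partition(labels=labels)


def random_view(n: int, rng: np.random.Generator) -> SimilarityView:
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return make_view(m)
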