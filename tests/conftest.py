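import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitomk as mk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code5():
    return mk.get_code(5)


@pytest.fixture(scope="session")
def code1():
    return mk.get_code(1)


@pytest.fixture(scope="session")
def code2():
    return mk.get_code(2)


@pytest.fixture(scope="session")
def mt_tables():
    """Packaged 13-gene mitochondrial MK count fixture."""
    return mk.load_dmel_mt_mk_counts()


@pytest.fixture(scope="session")
def mt_by_gene(mt_tables):
    return {t.gene_name: t for t in mt_tables}


def make_alignment(seqs: dict[str, str], outgroups: list[str]) -> mk.PopulationAlignment:
    """Build a PopulationAlignment from label -> sequence strings."""
    from mitomk.alignment import encode_sequence

    ids = list(seqs)
    matrix = np.vstack([encode_sequence(seqs[i]) for i in ids])
    return mk.PopulationAlignment(ids, matrix, outgroups)


@pytest.fixture
def simple_gene_factory():
    """Build a one-gene CodonGeneAlignment from ingroup/outgroup sequences."""

    def build(ingroup: list[str], outgroup: str, code_id: int = 5):
        seqs = {f"s{i}": s for i, s in enumerate(ingroup)}
        seqs["out"] = outgroup
        aln = make_alignment(seqs, ["out"])
        ann = mk.GeneAnnotation("g", 1, aln.length, "+", 0, code_id)
        return mk.extract_gene(aln, ann)

    return build
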