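import numpy as np
import pytest

from ppibias.correction import RoleAnnotatedStudy
from ppibias.studies import StudyCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def asymmetric_study():
    """The worked example: baits {A, B} (2) < preys {A, C, D} (3)."""
    return RoleAnnotatedStudy(
        study_id="s1",
        interactions=[("A", "C"), ("A", "D"), ("B", "C"), ("B", "A")],
    )


@pytest.fixture
def mitab_file(tmp_path):
    """A small PSI-MITAB fixture: three role-annotated lines, one without
    roles, and one self-interaction."""

    def line(a, b, pub, role_a, role_b):
        cols = ["-"] * 18
        cols[0] = f"uniprotkb:{a}"
        cols[1] = f"uniprotkb:{b}"
        cols[6] = 'psi-mi:"MI:0004"(affinity chromatography technology)'
        cols[8] = pub
        cols[16] = role_a
        cols[17] = role_b
        return "\t".join(cols)

    bait = 'psi-mi:"MI:0496"(bait)'
    prey = 'psi-mi:"MI:0498"(prey)'
    content = "\n".join(
        [
            line("P1", "P2", "pubmed:111", bait, prey),
            line("P3", "P1", "pubmed:111", prey, bait),
            line("P2", "P4", "pubmed:222", bait, prey),
            line("P5", "P6", "pubmed:222", "-", "-"),
            line("P7", "P7", "pubmed:222", bait, prey),
        ]
    )
    path = tmp_path / "fixture.mitab"
    path.write_text(content + "\n")
    return path


@pytest.fixture
def tiny_catalog():
    s1 = RoleAnnotatedStudy("s1", [("A", "B"), ("A", "C")])
    s2 = RoleAnnotatedStudy("s2", [("B", "A"), ("C", "D")])
    return StudyCatalog(studies=[s1, s2])
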