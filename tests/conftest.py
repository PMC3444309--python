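from __future__ import annotations

import pytest

from ctxquery import (
    apply_rules,
    build_canonical_fixture,
    build_figure1_scenario,
    load_ctx_ontology,
    load_ctx_ruleset,
)


@pytest.fixture(scope="session")
def ctx_ontology():
    return load_ctx_ontology()


@pytest.fixture(scope="session")
def ctx_ruleset():
    return load_ctx_ruleset()


@pytest.fixture(scope="session")
def canonical():
    """(raw cohort, ontology, ruleset) for the reference CTX cohort."""
    return build_canonical_fixture()


@pytest.fixture(scope="session")
def enriched(canonical):
    cohort, ontology, ruleset = canonical
    out, records = apply_rules(cohort, ruleset, ontology)
    return out, ontology, ruleset, records


@pytest.fixture(scope="session")
def figure1(ctx_ontology, ctx_ruleset):
    cohort = build_figure1_scenario()
    out, _ = apply_rules(cohort, ctx_ruleset, ctx_ontology)
    return out


TOY_OBO = """\
format-version: 1.2

[Term]
id: root
name: Root

[Term]
id: A
name: A node
is_a: root

[Term]
id: B
name: B node
is_a: A

[Term]
id: C
name: C node
is_a: root
"""


@pytest.fixture()
def toy_obo():
    return TOY_OBO
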