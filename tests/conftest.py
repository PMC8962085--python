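import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from retriage.io import fixture_path
from retriage.knowledge_base import (
    GeneDiseaseEntry,
    Inheritance,
    Registration,
    Snapshot,
)
from retriage.phenotype import load_ontology

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_ontology():
    """5-term / 4-disease hand-checkable ontology (packaged fixture)."""
    return load_ontology(fixture_path("toy.obo"), fixture_path("toy_corpus.tsv"))


def make_entry(
    gene="GENE1",
    disease_id="600001",
    inheritance=Inheritance.AD,
    registration=Registration.OMIM_REGISTERED,
    profile=("HP:0000118",),
    entry_date=dt.date(2020, 1, 1),
    name="test disorder",
    lof=True,
):
    return GeneDiseaseEntry(
        gene_symbol=gene,
        disease_id=disease_id,
        disease_name=name,
        inheritance=inheritance,
        registration=registration,
        hpo_profile=frozenset(profile),
        entry_date=entry_date,
        lof_mechanism=lof,
    )


@pytest.fixture
def entry_factory():
    return make_entry


@pytest.fixture
def snapshot_factory():
    def build(date=dt.date(2020, 1, 1), entries=(), assertions=(), frequencies=None):
        return Snapshot.build(date, entries, assertions, frequencies)

    return build
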