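import pytest

from meshmine import (Corpus, PubMedRecord, builtin_digital_health_vocabulary,
                      builtin_disease_sample_vocabulary)


def record(pmid, descriptors=(), year=2015, has_abstract=True,
           affiliations=("University of Surrey, Guildford, UK",), title=None):
    return PubMedRecord(pmid=pmid, year=year, has_abstract=has_abstract,
                        affiliations=tuple(affiliations),
                        descriptors=tuple(descriptors), title=title)


@pytest.fixture
def dh_vocab():
    return builtin_digital_health_vocabulary()


@pytest.fixture
def disease_vocab():
    return builtin_disease_sample_vocabulary()


@pytest.fixture
def toy_corpus():
    """Three hand-built records used across hand-enumeration tests.

    r1 matches {telemedicine, obesity}; r2 {telemedicine, obesity, asthma};
    r3 {telemedicine} — so occ(telemedicine)=3, occ(obesity)=2, occ(asthma)=1,
    cooc(telemedicine,obesity)=2, cooc(telemedicine,asthma)=1,
    cooc(asthma,obesity)=1.
    """
    r1 = record("1", ["Telemedicine", "Obesity"], year=2015)
    r2 = record("2", ["Telemedicine/methods", "Obesity", "Asthma"], year=2015)
    r3 = record("3", ["Telemedicine"], year=2016)
    return Corpus(records=(r1, r2, r3), provenance="toy")
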