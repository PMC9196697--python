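import pytest

from cohortcraft.edits import CatalogRow, ConceptCatalog
from cohortcraft.entities import Lexicon, LexiconEntry, annotate_representation
from cohortcraft.model import Category, ConceptRef, read_criteria_text


def concept(cid, name, domain, standard=True):
    return ConceptRef(
        concept_id=cid, concept_name=name, domain=domain,
        vocabulary="SNOMED", standard=standard,
    )


#: Sentence used throughout for negation-scope behavior.
COVID_SENTENCE = (
    "If symptomatic, presence of mild to moderate symptoms without signs of "
    "respiratory distress, with positive for SARS-CoV-2 diagnostic assay "
    "within 72 hours prior to informed consent."
)


@pytest.fixture
def covid_lexicon():
    return Lexicon(
        [
            LexiconEntry("symptomatic", Category.Condition,
                         concept(1001, "Symptomatic", "Condition")),
            LexiconEntry("symptoms", Category.Condition,
                         concept(1002, "Symptom", "Condition")),
            LexiconEntry("respiratory distress", Category.Condition,
                         concept(1003, "Respiratory distress", "Condition")),
            LexiconEntry("sars-cov-2 diagnostic assay", Category.Measurement,
                         concept(1004, "SARS-CoV-2 assay", "Measurement")),
        ]
    )


@pytest.fixture
def covid_rep(covid_lexicon):
    rep = read_criteria_text(
        "Inclusion Criteria:\n- " + COVID_SENTENCE, "NCT04300000"
    )
    return annotate_representation(rep, covid_lexicon)


@pytest.fixture
def catalog():
    return ConceptCatalog(
        [
            CatalogRow(concept(4182210, "Dementia", "Condition"), ("dementia",)),
            CatalogRow(concept(4043241, "Mixed dementia", "Condition"),
                       ("dementia of mixed type",)),
            CatalogRow(concept(80502, "Osteoporosis", "Condition")),
            CatalogRow(concept(4124693, "Liver finding", "Condition")),
            CatalogRow(concept(198124, "Kidney disease", "Condition")),
            CatalogRow(concept(35604394, "Mood Stabilizer", "Drug"),
                       ("mood stabilizers",)),
            CatalogRow(concept(999001, "Dementia (non-standard)", "Condition",
                               standard=False), ("dementia",)),
        ]
    )
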