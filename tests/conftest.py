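import pytest

from ineads import GeneratorConfig, generate_corpus, seed_default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return seed_default_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """A 200-admission noiseless corpus shared across tests."""
    return generate_corpus(GeneratorConfig(n_admissions=200, seed=101))


def write_notes_csv(path, rows):
    """rows: (note_id, patient, admission, category, charttime, text)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, quoting=csv.QUOTE_ALL)
        writer.writerow(["ROW_ID", "SUBJECT_ID", "HADM_ID", "CATEGORY", "CHARTTIME", "TEXT"])
        writer.writerows(rows)


def write_admissions_csv(path, rows):
    """rows: (admission, patient, age, gender, ethnicity, type, insurance, hosp, follow)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["HADM_ID", "SUBJECT_ID", "AGE", "GENDER", "ETHNICITY",
             "ADMISSION_TYPE", "INSURANCE", "HOSPITAL_EXPIRE_FLAG",
             "FOLLOWUP_EXPIRE_FLAG"]
        )
        writer.writerows(rows)
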