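import csv

import pytest

from contratopics import resources
from contratopics.ingest import RawReview
from contratopics.textprep import PrepConfig

UCI_COLUMNS = ["uniqueID", "drugName", "condition", "review", "rating",
               "date", "usefulCount"]


@pytest.fixture(scope="session")
def catalog():
    return resources.default_method_catalog()


@pytest.fixture(scope="session")
def prep_config():
    return PrepConfig.default()


@pytest.fixture
def write_tsv(tmp_path):
    """Factory writing rows (dicts with UCI column keys) to a TSV file."""

    def _write(rows, name="reviews.tsv"):
        path = tmp_path / name
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=UCI_COLUMNS,
                                    delimiter="\t", quotechar='"',
                                    doublequote=True,
                                    quoting=csv.QUOTE_MINIMAL,
                                    lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
        return path

    return _write


def make_row(record_id="1", drug="Mirena", condition="Birth Control",
             review="It was fine.", rating=8, date="May 5, 2012", useful=3):
    return {"uniqueID": record_id, "drugName": drug, "condition": condition,
            "review": review, "rating": rating, "date": date,
            "usefulCount": useful}


def make_raw(record_id="1", drug="Mirena", condition="Birth Control",
             text="It was fine.", rating=8, date="May 5, 2012", useful=3):
    return RawReview(record_id=record_id, drug_name=drug, condition=condition,
                     text=text, rating=rating, date=date, useful_count=useful)
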