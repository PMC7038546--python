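import numpy as np
import pandas as pd
import pytest

from diabtype.tables import EventTables, empty_table


def _frame(rows, table):
    return pd.DataFrame(rows) if rows else empty_table(table)


class TableBuilder:
    """Hand-build tiny event-table fixtures person by person."""

    def __init__(self):
        self.persons, self.encounters, self.prescriptions = [], [], []
        self.labs, self.deliveries, self.labels = [], [], []

    def person(self, pid, sex="female", birth="1980-01-01", true_type="T2D"):
        self.persons.append({"person_id": pid, "sex": sex,
                             "birth_date": pd.Timestamp(birth)})
        self.labels.append({"person_id": pid, "true_type": true_type})
        return self

    def encounter(self, pid, date, icd9, source="mixed", setting="outpatient"):
        self.encounters.append({"person_id": pid, "date": pd.Timestamp(date),
                                "icd9": icd9, "source": source, "setting": setting})
        return self

    def rx(self, pid, drug_class, start, duration=90):
        self.prescriptions.append({"person_id": pid, "drug_class": drug_class,
                                   "start_date": pd.Timestamp(start),
                                   "duration_days": duration})
        return self

    def lab(self, pid, date, test, value, setting="outpatient"):
        self.labs.append({"person_id": pid, "date": pd.Timestamp(date),
                          "test": test, "value": value, "setting": setting})
        return self

    def delivery(self, pid, date, kind="delivery"):
        self.deliveries.append({"person_id": pid, "date": pd.Timestamp(date),
                                "kind": kind})
        return self

    def build(self):
        tables = EventTables(
            persons=_frame(self.persons, "persons"),
            encounters=_frame(self.encounters, "encounters"),
            prescriptions=_frame(self.prescriptions, "prescriptions"),
            labs=_frame(self.labs, "labs"),
            deliveries=_frame(self.deliveries, "deliveries"),
        )
        return tables, _frame(self.labels, "labels")


@pytest.fixture
def builder():
    return TableBuilder()


@pytest.fixture(scope="session")
def small_synthetic():
    """A modest synthetic registry shared across tests (seeded)."""
    from diabtype.simulate import SyntheticConfig, generate

    cfg = SyntheticConfig(n_persons=4000, seed=11, t1d_fraction=0.05)
    tables, labels, params = generate(cfg)
    return tables, labels, params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160101)
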