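import numpy as np
import pytest

import pvonset as pv
from pvonset.dates import PartialDate


@pytest.fixture(scope="session")
def terms() -> pv.TermQuery:
    return pv.bundled_demo_terms()


def make_case(
    case_id="C1",
    sex=pv.Sex.MALE,
    age="20s",
    drugs=(),
    reactions=(),
    history=(),
):
    """Hand-build a CaseRecord from terse tuples."""
    demo = pv.DemoEntry(case_id=case_id, sex=sex, age_raw=age)
    drug_entries = [
        pv.DrugEntry(
            case_id=case_id,
            drug_name=name,
            involvement=pv.Involvement(inv),
            dose_mg_per_day=dose,
            start_date=PartialDate(*start) if start else None,
        )
        for (name, inv, dose, start) in drugs
    ]
    reac_entries = [
        pv.ReacEntry(
            case_id=case_id,
            pt=pt,
            onset_date=PartialDate(*onset) if onset else None,
        )
        for (pt, onset) in reactions
    ]
    hist_entries = [pv.HistEntry(case_id=case_id, disease_pt=pt) for pt in history]
    return pv.CaseRecord(
        case_id=case_id,
        demo=demo,
        drugs=drug_entries,
        reactions=reac_entries,
        history=hist_entries,
    )


@pytest.fixture()
def seizure_case():
    """Clozapine case with a dated seizure and co-medication."""
    return make_case(
        case_id="SZ1",
        sex=pv.Sex.FEMALE,
        age="30s",
        drugs=[
            ("clozapine", "suspected", 300.0, (2020, 1, 1)),
            ("risperidone", "concomitant", None, (2020, 1, 1)),
            ("lithium", "concomitant", 400.0, (2020, 1, 1)),
        ],
        reactions=[("Seizure", (2020, 3, 1))],
        history=["Schizophrenia"],
    )


@pytest.fixture(scope="session")
def small_dump():
    """A mixed synthetic dump (study-drug and other reports, missingness on)."""
    return pv.simulate(pv.SimConfig(n_cases=500, seed=11))


@pytest.fixture(scope="session")
def small_dump_dir(small_dump, tmp_path_factory):
    d = tmp_path_factory.mktemp("dump")
    pv.write_tables(small_dump, d)
    return d


@pytest.fixture(scope="session")
def clean_dump():
    """Zero-missingness dump: every study-drug case is retainable."""
    cfg = pv.SimConfig(
        n_cases=600,
        seed=23,
        m_sex=0.0,
        m_age=0.0,
        p_age_nonnumeric=0.0,
        m_dose=0.0,
        m_lithium_dose=0.0,
        m_date=0.0,
        p_partial_date=0.0,
    )
    return pv.simulate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
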