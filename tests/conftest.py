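import numpy as np
import pandas as pd
import pytest

import minvent as mv


@pytest.fixture(scope="session")
def reference_table():
    return mv.ReferenceCoefficientTable.synthetic_default()


@pytest.fixture(scope="session")
def toy_table():
    """Minimal table: a0=-10, a1=2, a2=0.1, spline identically zero."""
    rows = []
    for sex in (1, 2):
        for group in ("Caucasian", "Other"):
            for outcome in ("FVC", "FEV1"):
                rows.append({"sex_code": sex, "group": group, "outcome": outcome,
                             "a0": -10.0, "a1": 2.0, "a2": 0.1})
    coef = pd.DataFrame(rows)
    spline = pd.DataFrame(
        [{"sex_code": s, "group": g, "outcome": o, "age": a, "spline_value": 0.0}
         for s in (1, 2) for g in ("Caucasian", "Other") for o in ("FVC", "FEV1")
         for a in (4, 80)]
    )
    return mv.ReferenceCoefficientTable(coef, spline, {"source": "toy"})


@pytest.fixture(scope="session")
def small_sim(reference_table):
    """60-subject simulated cohort under default (realistic-noise) conditions."""
    return mv.simulate_dataset(mv.SimulationConfig(n_subjects=60), seed=11)


@pytest.fixture(scope="session")
def small_fit(small_sim, reference_table):
    return mv.fit_loglog_lmm(small_sim.dataset, mv.ModelFormula.d2(),
                             reference_table=reference_table)


def make_profile(**kwargs):
    defaults = dict(subject_id="s1", age=30.0, sex_code=1, height=178.0,
                    ethnicity_label="Caucasian", country="US")
    defaults.update(kwargs)
    return mv.SubjectProfile(**defaults)
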