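"""Shared fixtures: small synthetic studies and hand-built toy tables."""

import io

import numpy as np
import pandas as pd
import pytest

from foxsel.core_data import StudyDesign
from foxsel.synthetic import SyntheticParams, generate_study


@pytest.fixture(scope="session")
def small_study():
    """One default-parameter synthetic study at reduced size."""
    return generate_study(SyntheticParams(n_per_subplot=60), seed=42)


@pytest.fixture(scope="session")
def lognormal_study():
    """Oracle-surface study: gradients are exactly the generating betas."""
    params = SyntheticParams(
        n_per_subplot=200,
        surface="lognormal",
        selection_gradients={
            "ambient": (0.9, 0.4, -0.2, 0.25),
            "addition": (0.9, 0.4, -0.2, 0.25),
        },
    )
    return generate_study(params, seed=7)


@pytest.fixture()
def toy_design():
    return StudyDesign(
        {
            "P1": {"ambient": "P1-amb", "addition": "P1-add"},
            "P2": {"ambient": "P2-amb", "addition": "P2-add"},
        }
    )


def make_individuals(rows):
    """Minimal individual table from (plot, subplot, trt, height, fruit) rows."""
    df = pd.DataFrame(
        rows, columns=["plot_id", "subplot_id", "treatment", "height", "fruit_count"]
    )
    for col, val in (
        ("leaf_count", 5.0),
        ("sla", 25.0),
        ("flowering_day", 210.0),
        ("main_panicle_length", np.nan),
        ("seedling_class", None),
    ):
        df[col] = val
    df["herbivory"] = False
    df["fitness_excluded"] = False
    return df


@pytest.fixture()
def individuals_csv():
    return io.StringIO(
        "plot_id,subplot_id,treatment,height,leaf_count,sla,flowering_day,"
        "fruit_count,herbivory,fitness_excluded\n"
        "P1,P1-amb,ambient,120,4,22.5,208,15,false,false\n"
        "P1,P1-add,addition,340,7,31.0,,80,true,false\n"
        "P2,P2-amb,ambient,95,3,NA,214,0,false,false\n"
    )
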