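import numpy as np
import pandas as pd
import pytest

from coldtrial.spatial import PHENOTYPE_FLAGS, CellMap


def make_cell_map(
    coords,
    flags,
    sample_id="S1",
    patient_id="P1",
    timepoint="baseline",
    area_mm2=1.0,
):
    """Build a CellMap from explicit coordinates and per-cell flag sets.

    ``flags`` is a list of iterables of phenotype labels; the CD3 flag is
    filled in automatically for CD4/CD8 cells.
    """
    rows = []
    for (x, y), fl in zip(coords, flags):
        fl = set(fl)
        if fl & {"CD4", "CD8"}:
            fl.add("CD3")
        rows.append(
            {
                "x_um": float(x),
                "y_um": float(y),
                **{f: (f in fl) for f in PHENOTYPE_FLAGS},
            }
        )
    cols = ["x_um", "y_um", *PHENOTYPE_FLAGS]
    cells = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(
        {c: pd.Series(dtype=(bool if c in PHENOTYPE_FLAGS else float)) for c in cols}
    )
    return CellMap(
        sample_id=sample_id,
        patient_id=patient_id,
        timepoint=timepoint,
        area_mm2=area_mm2,
        cells=cells,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
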