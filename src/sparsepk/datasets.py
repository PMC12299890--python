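"""The bundled rat serum scyllo-inositol dataset.

A complete single-dose oral study in six male Wistar rats: 10 mg/kg
scyllo-inositol by gavage, serum sampled on a two-subgroup staggered grid
(rats 1-3 at 0-24 h, rats 4-6 at 2-48 h), concentrations below the assay's
limit of quantification recorded as BLQ (0 mg/L). Small enough to ship as
two CSVs; used throughout the examples and as the reference input for the
reproduction scripts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import SubjectProfile, attach_doses, read_concentration_table

#: Terminal elimination rate constants (1/h) reported for each rat in the
#: source study. The point selection behind them is undocumented and cannot
#: be reproduced from the concentrations alone (rat 1's terminal
#: quantifiable segment even rises), so they are offered as fixed-K inputs
#: for reproducing the published parameter tables, not as fit targets.
REPORTED_K_PER_H = {
    "rat1": 2.521,
    "rat2": 0.01387,
    "rat3": 0.0276,
    "rat4": 0.9102,
    "rat5": 0.161,
    "rat6": 0.2861,
}

#: Reported terminal rate constant of the pooled mean profile (1/h).
REPORTED_K_POOLED_PER_H = 0.0689

#: Subgroup membership of the staggered design.
STUDY_GROUPS = {
    "rats 1-3": ("rat1", "rat2", "rat3"),
    "rats 4-6": ("rat4", "rat5", "rat6"),
}


def _data_path(name: str):
    return resources.files("sparsepk.data").joinpath(name)


def study_concentration_table() -> pd.DataFrame:
    """Raw long-format serum concentration table (BLQ as sentinel rows)."""
    with resources.as_file(_data_path("serum_concentrations.csv")) as path:
        return pd.read_csv(path, dtype={"subject_id": str})


def study_dose_table() -> pd.DataFrame:
    """Body weights (g) and administered doses (mg) of the six rats."""
    with resources.as_file(_data_path("doses.csv")) as path:
        return pd.read_csv(path, dtype={"subject_id": str})


def load_study() -> list[SubjectProfile]:
    """The six study profiles with doses and body weights attached."""
    with resources.as_file(_data_path("serum_concentrations.csv")) as path:
        profiles = read_concentration_table(path)
    return attach_doses(profiles, study_dose_table(), expected_dose_mg_per_kg=10.0)
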