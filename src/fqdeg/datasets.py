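"""Packaged study tables and their loaders.

The package ships the published input tables as plain CSV fixtures:

* docking scores of 49 fluoroquinolones against the degrading-enzyme
  receptors 1GKQ, 1OB0 and 5M0K (``table2_scores.csv``);
* the published composite biodegradability values for the same compounds
  (``table3_composite.csv``) — a *diagnostic* reference only, see
  :func:`composite_deviation_report`;
* predicted biodegradability and environmental properties of moxifloxacin
  (MOX) and its ten designed derivatives (``table4_derivatives.csv``,
  ``table5_environment.csv``), including the published percent-change
  columns for regression checks;
* the agricultural-soil nutrient survey (``table6_survey.csv``);
* the composting amendment design (``table1_design.csv``), the published
  per-scenario binding energies (``scenario_energies.csv``), and the 2^3
  field-measure design with binding energies (``table7_field_measures.csv``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .factorial import DesignTable
from .io import read_csv
from .scoring import CompositeScoreModel, ScoreMatrix
from .screening import DerivativeRecord

__all__ = [
    "fixture_path",
    "load_score_matrix",
    "load_reference_composites",
    "load_table4",
    "load_table5",
    "load_derivative_records",
    "load_survey",
    "load_amendment_design",
    "load_scenario_energies",
    "load_field_design",
    "composite_deviation_report",
    "GROUP_ADDITIVES",
    "NUTRIENT_ADDITION_LEVELS",
]

#: Amendment represented by each experimental group (blank group G0 empty).
GROUP_ADDITIVES = {
    "G1": "OM", "G2": "POS", "G3": "WV", "G4": "CA",
    "G5": "AP", "G6": "UR", "G7": "NTA", "G8": "MS",
}

#: Nutrient amounts (g/kg of C, N, P) added in the soil simulation recipe;
#: configuration, not derived from the survey means.
NUTRIENT_ADDITION_LEVELS = {"c": 2, "n": 1, "p": 2}


def fixture_path(name: str):
    """Filesystem path of a packaged CSV fixture."""
    return resources.files("fqdeg.data").joinpath(name)


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(fixture_path(name)) as p:
        return read_csv(p)


def load_score_matrix() -> ScoreMatrix:
    """49 x 3 docking-score matrix (1GKQ, 1OB0, 5M0K)."""
    return ScoreMatrix.from_dataframe(_load("table2_scores.csv"))


def load_reference_composites() -> pd.DataFrame:
    """Published composite values; diagnostic reference, not a gate."""
    return _load("table3_composite.csv")


def load_table4() -> pd.DataFrame:
    """Derivative biodegradability predictions with published change columns."""
    return _load("table4_derivatives.csv")


def load_table5() -> pd.DataFrame:
    """Derivative environmental/functional predictions with change columns."""
    return _load("table5_environment.csv")


def load_derivative_records() -> list[DerivativeRecord]:
    """Merged derivative records (biodegradability + environmental properties)."""
    t4 = load_table4()
    t5 = load_table5().drop(columns=["is_parent"])
    merged = t4.merge(t5, on="name", validate="one_to_one")
    records = []
    for _, row in merged.iterrows():
        records.append(DerivativeRecord(
            name=row["name"],
            site=None if pd.isna(row["site"]) else int(row["site"]),
            group=None if pd.isna(row["site"]) else str(row["group"]),
            cv=row["cv"], g1gkq=row["g1gkq"], g1ob0=row["g1ob0"],
            g5m0k=row["g5m0k"], ploec=row["ploec"], logkow=row["logkow"],
            logt12=row["logt12"], is_parent=bool(row["is_parent"]),
        ))
    return records


def load_survey() -> pd.DataFrame:
    """12-site C/N/P nutrient survey of north-eastern agricultural soils."""
    return _load("table6_survey.csv")


def load_amendment_design() -> pd.DataFrame:
    """Blank + 8 single-amendment groups (OM, POS, WV, CA, AP, UR, NTA, MS)."""
    return _load("table1_design.csv")


def load_scenario_energies() -> pd.DataFrame:
    """Published per-scenario binding energies of Derivative-10 with the
    receptor complex (only the groups whose energies were reported)."""
    return _load("scenario_energies.csv")


def load_field_design() -> tuple[DesignTable, float, float]:
    """Field-measure 2^3 design for Derivative-10 plus the two baselines.

    Returns ``(design, mox_energy, derivative10_energy)`` where the design
    covers organic fertilizer application, straw returning and plowing, the
    MOX energy is the parent baseline and the Derivative-10 energy is the
    no-measure run (also the design's blank cell).
    """
    df = _load("table7_field_measures.csv")
    mox = float(df.loc[df["compound"] == "MOX", "binding_energy"].iloc[0])
    d10 = df[df["compound"] == "Derivative-10"].reset_index(drop=True)
    factors = ["organic_fertilizer", "straw_returning", "plowing"]
    gids = ["-".join(map(str, r)) for r in d10[factors].to_numpy(int)]
    design = DesignTable(gids, factors, d10[factors].to_numpy(int),
                         d10["binding_energy"].to_numpy(float),
                         blank_id="0-0-0")
    blank = float(d10.loc[(d10[factors] == 0).all(axis=1), "binding_energy"].iloc[0])
    return design, mox, blank


def composite_deviation_report() -> dict:
    """Deviation between recomputed composites and the published table.

    The published composite table is not exactly reproducible from the
    published score matrix (cross-checking individual compounds implies
    mutually inconsistent weights), so this comparison is shipped as a
    diagnostic, never as a correctness gate.
    """
    scores = load_score_matrix()
    result = CompositeScoreModel(scores).fit()
    ref = load_reference_composites().set_index("compound")["cv"]
    recomputed = pd.Series(result.composite, index=list(scores.compound_ids))
    common = ref.index.intersection(recomputed.index)
    dev = (recomputed.loc[common] - ref.loc[common]).abs()
    return {
        "n_compared": int(len(common)),
        "max_abs_deviation": float(dev.max()),
        "mean_abs_deviation": float(dev.mean()),
        "weights": dict(zip(scores.receptor_ids, result.weights)),
        "per_compound": pd.DataFrame({
            "recomputed": recomputed.loc[common],
            "published": ref.loc[common],
            "abs_deviation": dev,
        }),
    }
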