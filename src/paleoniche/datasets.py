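"""Bundled reference tables for the ivesioid clade analysis.

Three published summary tables for the ivesioid clade of *Potentilla*
(Rosaceae) and its sister species *P. biennis* are shipped as package
data, for use as fixtures and worked examples:

* the sixteen candidate climate variables with their single-variable
  mean AUC and the pairwise Pearson correlations among them;
* the fitted climate-envelope bounds (min/max of four selected
  variables) of the 38 ivesioid species plus *P. biennis*, with the
  number of occurrence localities behind each;
* the reconstructed ancestral envelope bounds for internal nodes 40-77
  of the clade's dated phylogeny.

Caveat: in the ancestral table the "coolest month precipitation"
minimum column is row-for-row identical to the "warmest month
precipitation" minimum column — a printing defect of the source table;
those values fall below every tip's value for that character and cannot
be reproduced by any branch-length-weighted averaging of the tip data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .bioclim import EnvelopeModel
from .varselect import CorrelationMatrix

__all__ = [
    "climate_variable_table",
    "climate_correlations",
    "tip_envelope_table",
    "tip_envelopes",
    "ancestral_envelope_table",
    "SELECTED_VARIABLES",
]

# the four variables marked as retained in the reference variable table
SELECTED_VARIABLES = (
    "Mean_temperature_in_coolest_month",
    "Standard_deviation_of_mean_temperature",
    "Mean_daily_precipitation_in_warmest_month",
    "Mean_daily_precipitation_in_coolest_month",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("paleoniche").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def climate_variable_table() -> pd.DataFrame:
    """Sixteen candidate variables: ``variable, mean_auc, selected``."""
    return _read("ivesioid_variables.csv")


def climate_correlations() -> CorrelationMatrix:
    """Pairwise Pearson correlations among the sixteen variables."""
    order = list(climate_variable_table()["variable"])
    pairs = _read("ivesioid_correlations.csv")
    n = len(order)
    r = np.eye(n)
    idx = {v: i for i, v in enumerate(order)}
    for rec in pairs.itertuples():
        i, j = idx[rec.var_a], idx[rec.var_b]
        r[i, j] = r[j, i] = rec.r
    return CorrelationMatrix(order, r)


def tip_envelope_table() -> pd.DataFrame:
    """Tip envelope bounds: ``taxon, variable, min, max, n_points``."""
    return _read("ivesioid_tip_envelopes.csv")


def tip_envelopes() -> dict[str, EnvelopeModel]:
    """Tip envelope bounds as :class:`EnvelopeModel` objects."""
    df = tip_envelope_table()
    out: dict[str, EnvelopeModel] = {}
    for taxon, sub in df.groupby("taxon", sort=False):
        bounds = {
            str(row.variable): (float(row.min), float(row.max))
            for row in sub.itertuples()
        }
        out[str(taxon)] = EnvelopeModel(
            str(taxon), bounds, n_points=int(sub["n_points"].iloc[0])
        )
    return out


def ancestral_envelope_table() -> pd.DataFrame:
    """Reconstructed ancestral bounds: ``node, variable, min, max``.

    Node numbers follow the source figure's numbering (40-77).  See the
    module docstring for the known defect in the coolest-month
    precipitation minimum column.
    """
    return _read("ivesioid_ancestral_envelopes.csv")
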