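"""Packaged example data: a 20-genotype x 12-environment rice yield trial.

``load_rice_yield_means`` returns the published cell-means matrix of paddy
yield (kg/ha) for 20 Green Super Rice lines -- including the two local
checks G19 and G20 -- evaluated in RCBD trials with three replicates at 12
locations across Pakistan.  Only replicate means are available, so ANOVA
stages that need the error stratum operate instead on the published mean
squares, available through ``load_rice_mean_squares`` for six traits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CellMeans

#: replicates behind each cell of the rice trial
RICE_REPLICATES = 3

#: check cultivars (local check I and II)
RICE_CHECKS = ("G19", "G20")

RICE_TRAITS = {
    "plant_height": "plant height (cm)",
    "tiller_number": "productive tillers per plant",
    "panicle_length": "panicle length (cm)",
    "grains_per_panicle": "grains per panicle",
    "thousand_grain_weight": "1000-grain weight (g)",
    "paddy_yield": "paddy yield (kg/ha)",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("metstab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_rice_yield_means() -> CellMeans:
    """Cell-means matrix (kg/ha) of the packaged rice trial.

    The matrix holds replicate means, so ``r`` is recorded as 1: analyses
    needing the within-trial error stratum must use the published mean
    squares instead.
    """
    df = _read("rice_yield_means.csv").set_index("genotype")
    df.index.name = None
    return CellMeans(df.astype(float), r=1, trait_name="paddy_yield")


def load_rice_mean_squares() -> pd.DataFrame:
    """Published combined-ANOVA mean squares for the six measured traits.

    Indexed by source (GEN, REP, ENV, GEN:ENV, ERROR) with a ``df`` column
    and one column per trait (see :data:`RICE_TRAITS`).
    """
    return _read("rice_anova_ms.csv").set_index("source")
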