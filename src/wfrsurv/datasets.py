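"""Packaged example datasets.

Two small fixtures ship with the package:

* ``gastric_cancer``: survival times in years of 46 gastric-cancer patients
  treated with combined chemotherapy and radiation (Stablein et al.'s
  classical series), widely used to benchmark parametric lifetime models.
* ``simulated_censored``: a progressive type-II censored sample of m = 15
  observations generated from WFr(0.5, 2.5, 0.96, 0.6) with n = 30 and
  removal scheme R = (7, 1, 2, 4, 1, 0, ..., 0).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .censoring import CensoredSample, ProgressiveScheme

__all__ = ["load_gastric_data", "load_simulated_example"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("wfrsurv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_gastric_data() -> np.ndarray:
    """46 gastric-cancer survival times in years, sorted ascending."""
    t = _read("gastric_cancer.csv")["time"].to_numpy(dtype=float)
    return np.sort(t)


def load_simulated_example() -> CensoredSample:
    """The 15-point progressive type-II censored WFr sample (n = 30)."""
    df = _read("simulated_censored.csv")
    removals = tuple(int(r) for r in df["removed"])
    m = len(removals)
    scheme = ProgressiveScheme(n=m + sum(removals), m=m, removals=removals)
    return CensoredSample(tuple(df["time"].astype(float)), scheme)
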