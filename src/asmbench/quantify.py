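"""Sequencing-library quantification.

Molarity of a double-stranded DNA library from its fluorometric
concentration and average insert size (AIS)::

    nM = conc / ((AIS + adapter_bp) * mass_per_bp) * 1e6

with ``adapter_bp = 120`` (the two ligated adapters) and
``mass_per_bp = 650`` g/mol per base pair of dsDNA. Electrophoretic
(Bioanalyzer) insert-size estimates systematically overestimate the
remap-derived truth; a linear correction ``AIS = 0.564 * AIS_Bio + 258``
is shipped as the default model, and :func:`fit_insert_regression`
refits it from (AIS_Bio, AIS_actual) calibration pairs.

Triplicate averaging of concentration and AIS_Bio measurements is the
caller's responsibility; all operations take scalars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ADAPTER_BP",
    "MASS_PER_BP",
    "LOADING_FACTOR",
    "RegressionModel",
    "LibraryQuantification",
    "BIOANALYZER_CORRECTION",
    "molarity",
    "apply_loading_factor",
    "correct_bioanalyzer",
    "fit_insert_regression",
    "overestimation_pct",
    "quantify_library",
]

#: Length in bp added by the two ligated sequencing adapters.
ADAPTER_BP = 120.0
#: Average molar mass of one double-stranded base pair, g/(mol*bp).
MASS_PER_BP = 650.0
#: Rough loading adjustment applied to molarity before pooling.
LOADING_FACTOR = 1.3


@dataclass(frozen=True)
class RegressionModel:
    """Ordinary least-squares line AIS = slope * AIS_Bio + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


#: Default Bioanalyzer-to-actual insert size correction (recommended model,
#: fit on 14 remapped libraries with R^2 ~ 0.98).
BIOANALYZER_CORRECTION = RegressionModel(slope=0.564, intercept=258.0, r_squared=0.98, n_points=14)


@dataclass(frozen=True)
class LibraryQuantification:
    """Quantification record for one final library."""

    conc: float  # ng/ul, triplicate mean
    ais_bio: float  # bp, triplicate Bioanalyzer mean
    ais: float  # bp, corrected/actual
    nM: float

    def __post_init__(self) -> None:
        if self.conc <= 0 or self.ais <= 0 or self.nM <= 0:
            raise ValueError("conc, AIS and nM must all be positive")


def molarity(
    conc: float, ais: float, adapter_bp: float = ADAPTER_BP, mass_per_bp: float = MASS_PER_BP
) -> float:
    """Library molarity in nM from concentration (ng/ul) and insert size (bp)."""
    if conc <= 0:
        raise ValueError(f"conc must be positive, got {conc}")
    if ais <= 0:
        raise ValueError(f"AIS must be positive, got {ais}")
    return conc / ((ais + adapter_bp) * mass_per_bp) * 1e6


def apply_loading_factor(nm: float, factor: float = LOADING_FACTOR) -> float:
    """Adjust molarity by the empirical loading factor before pooling."""
    if nm <= 0:
        raise ValueError(f"molarity must be positive, got {nm}")
    return nm * factor


def correct_bioanalyzer(ais_bio: float, model: RegressionModel = BIOANALYZER_CORRECTION) -> float:
    """Estimate actual average insert size from a Bioanalyzer reading."""
    if ais_bio < 0:
        raise ValueError(f"AIS_Bio must be non-negative, got {ais_bio}")
    return model.predict(ais_bio)


def fit_insert_regression(pairs: Sequence[tuple[float, float]]) -> RegressionModel:
    """OLS fit of actual AIS against Bioanalyzer AIS over calibration pairs."""
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 calibration points, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all AIS_Bio values are equal")
    res = stats.linregress(x, y)
    return RegressionModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pairs),
    )


def overestimation_pct(ais_bio: float, ais_actual: float) -> float:
    """Percent by which the Bioanalyzer reading exceeds the actual AIS."""
    if ais_actual <= 0:
        raise ValueError(f"actual AIS must be positive, got {ais_actual}")
    return 100.0 * (ais_bio - ais_actual) / ais_actual


def quantify_library(
    conc: float,
    ais_bio: float,
    model: RegressionModel = BIOANALYZER_CORRECTION,
) -> LibraryQuantification:
    """Full quantification of one library: correct AIS_Bio, then molarity."""
    ais = correct_bioanalyzer(ais_bio, model)
    return LibraryQuantification(conc=conc, ais_bio=ais_bio, ais=ais, nM=molarity(conc, ais))
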