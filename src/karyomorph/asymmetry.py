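"""Karyotype asymmetry statistics: CV_CL, M_CA, TCL and population summaries.

Per metaphase plate (all 2n chromosomes):

* ``cv_cl``  — interchromosomal asymmetry: 100 * sd(CL) / mean(CL), the
  coefficient of variation of chromosome lengths (sample sd, n-1);
* ``m_ca``   — intrachromosomal asymmetry: mean centromeric asymmetry,
  the average of CA_i = 100 (L_i - S_i)/(L_i + S_i);
* ``tcl``    — total length of the diploid complement, sum of CL_i (um).

Per population, the plate values are averaged (mean +/- sample SD across
plates), which is how a small set of spreads per population is normally
reported.  ``scatter_table`` assembles the (M_CA, CV_CL, TCL) coordinates
used to separate taxa in an asymmetry scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .karyotype import KaryotypeModel
from .measurements import MetaphasePlate
from .morphometrics import centromeric_asymmetry, chromosome_length


def cv_cl(plate: MetaphasePlate, include_satellite: bool = True) -> float:
    """Coefficient of variation (%) of chromosome lengths on one plate."""
    lengths = np.array([chromosome_length(c, include_satellite) for c in plate.chromosomes])
    if lengths.size < 2:
        raise ValidationError("cv_cl needs at least 2 chromosomes")
    return 100.0 * lengths.std(ddof=1) / lengths.mean()


def m_ca(plate: MetaphasePlate) -> float:
    """Mean centromeric asymmetry (%) over all chromosomes of one plate."""
    return float(np.mean([centromeric_asymmetry(c) for c in plate.chromosomes]))


def tcl(plate: MetaphasePlate, include_satellite: bool = True) -> float:
    """Total length (um) of the diploid chromosome complement."""
    return float(sum(chromosome_length(c, include_satellite) for c in plate.chromosomes))


def karyotype_indices(model: KaryotypeModel) -> dict[str, float]:
    """CV_CL / M_CA / TCL evaluated on a consensus haploid karyotype.

    Alternative to the per-plate route: indices of the idealized complement
    built by duplicating each consensus pair.  TCL is reported on the
    diploid scale.
    """
    lengths = np.repeat([p.mean_length for p in model.pairs], 2)
    cas = np.repeat(
        [100.0 * (p.mean_long - p.mean_short) / (p.mean_long + p.mean_short)
         for p in model.pairs], 2)
    return {
        "cv_cl": 100.0 * lengths.std(ddof=1) / lengths.mean(),
        "m_ca": float(cas.mean()),
        "tcl": float(lengths.sum()),
    }


@dataclass(frozen=True)
class AsymmetrySummary:
    """Mean +/- sample SD of CV_CL, M_CA and TCL across one population's plates.

    SD fields are ``None`` when only one plate was summarized.
    """

    population_id: str
    n_plates: int
    cv_cl_mean: float
    cv_cl_sd: float | None
    m_ca_mean: float
    m_ca_sd: float | None
    tcl_mean: float
    tcl_sd: float | None


def summarize_population(
    plates: Sequence[MetaphasePlate], include_satellite: bool = True
) -> AsymmetrySummary:
    """Across-plate mean +/- sample SD of the three indices for one population."""
    if not plates:
        raise ValidationError("summarize_population needs at least one plate")
    pops = {p.population_id for p in plates}
    if len(pops) != 1:
        raise ValidationError(f"plates from mixed populations: {sorted(pops)}")
    cv = np.array([cv_cl(p, include_satellite) for p in plates])
    ca = np.array([m_ca(p) for p in plates])
    tl = np.array([tcl(p, include_satellite) for p in plates])
    n = len(plates)

    def sd(x: np.ndarray) -> float | None:
        return float(x.std(ddof=1)) if n > 1 else None

    return AsymmetrySummary(
        population_id=pops.pop(),
        n_plates=n,
        cv_cl_mean=float(cv.mean()), cv_cl_sd=sd(cv),
        m_ca_mean=float(ca.mean()), m_ca_sd=sd(ca),
        tcl_mean=float(tl.mean()), tcl_sd=sd(tl),
    )


def scatter_table(summaries: Sequence[AsymmetrySummary]) -> pd.DataFrame:
    """Scatter-plot coordinates (one row per population, sorted by id)."""
    if not summaries:
        raise ValidationError("scatter_table needs at least one summary")
    rows = [
        {
            "population": s.population_id,
            "m_ca_mean": s.m_ca_mean,
            "cv_cl_mean": s.cv_cl_mean,
            "tcl_mean": s.tcl_mean,
        }
        for s in summaries
    ]
    return (
        pd.DataFrame(rows, columns=["population", "m_ca_mean", "cv_cl_mean", "tcl_mean"])
        .sort_values("population", kind="stable")
        .reset_index(drop=True)
    )
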