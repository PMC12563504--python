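"""Time-series summarisation: six statistics per species, 30 features per individual.

Each simulated species' concentration series is reduced to mean, median,
maximum, standard deviation, skewness and kurtosis.  Central tendency and
dispersion are in μM; skewness and kurtosis are unitless shape measures —
for an accumulating metabolite like 5-HIAA, a more negative skew of the
sampled series means later accumulation (the concentration spends most of
the window near its late peak).

Moment convention
-----------------
Population (biased) moments are the default: sd = sqrt(m2),
skew = m3 / m2^1.5 and Pearson (non-excess) kurtosis = m4 / m2^2, where
m_k is the k-th central moment with divisor n.  Sample-corrected
(``"sample"``) and excess-kurtosis (``"excess"``) conventions are available
via ``convention``.  A degenerate series (zero variance) reports skewness
and kurtosis of 0 together with a degenerate flag, keeping downstream rank
tests total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import SPECIES, Trajectory

__all__ = [
    "STATISTICS",
    "FEATURE_COLUMNS",
    "SeriesSummary",
    "summarize_series",
    "feature_table",
]

STATISTICS = ("mean", "median", "max", "sd", "skew", "kurt")

#: The 30 feature columns in fixed output order (species-major).
FEATURE_COLUMNS = tuple(f"{sp}_{st}" for sp in SPECIES for st in STATISTICS)


@dataclass(frozen=True)
class SeriesSummary:
    mean: float
    median: float
    max: float
    sd: float
    skew: float
    kurt: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {st: getattr(self, st) for st in STATISTICS}


def summarize_series(
    x: Sequence[float] | np.ndarray,
    convention: str = "population",
) -> SeriesSummary:
    """Six summary statistics of one concentration series.

    Parameters
    ----------
    x : array-like, non-empty, finite
    convention : {"population", "sample", "excess"}
        "population": biased moments, Pearson kurtosis (default).
        "sample": ddof=1 sd with the usual bias-adjusted skew/kurtosis
        (kurtosis still non-excess).
        "excess": population moments with kurtosis − 3.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in series")
    if convention not in ("population", "sample", "excess"):
        raise ValueError(f"unknown moment convention {convention!r}")

    n = arr.size
    mean = float(arr.mean())
    centered = arr - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return SeriesSummary(
            mean=mean,
            median=float(np.median(arr)),
            max=float(arr.max()),
            sd=0.0,
            skew=0.0,
            kurt=0.0,
            degenerate=True,
        )
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    sd = float(np.sqrt(m2))
    if convention == "sample":
        sd = float(np.sqrt(m2 * n / (n - 1))) if n > 1 else 0.0
        if n > 2:
            skew = skew * np.sqrt(n * (n - 1)) / (n - 2)
        if n > 3:
            kurt = (
                (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * (kurt - 3.0) + 6.0)
            ) + 3.0
    elif convention == "excess":
        kurt = kurt - 3.0
    return SeriesSummary(
        mean=mean,
        median=float(np.median(arr)),
        max=float(arr.max()),
        sd=sd,
        skew=float(skew),
        kurt=float(kurt),
    )


def feature_table(
    trajectories: Mapping[str, Trajectory] | Iterable[tuple[str, Trajectory]],
    convention: str = "population",
) -> pd.DataFrame:
    """Build the per-individual feature matrix (one row, 30 columns each).

    All trajectories must share an identical time grid; input order is
    preserved in the output rows.
    """
    items = (
        list(trajectories.items())
        if isinstance(trajectories, Mapping)
        else list(trajectories)
    )
    if not items:
        raise ValueError("no trajectories given")
    ref_times = items[0][1].times
    rows = []
    for sample_id, traj in items:
        if len(traj.times) != len(ref_times) or not np.array_equal(
            traj.times, ref_times
        ):
            raise ValueError(f"time grid mismatch for sample {sample_id!r}")
        row: dict[str, object] = {"sample_id": sample_id}
        for sp in SPECIES:
            summary = summarize_series(traj.series[sp], convention=convention)
            for st, value in summary.as_dict().items():
                row[f"{sp}_{st}"] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *FEATURE_COLUMNS])
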