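"""Cohort-level model object and its fitted results.

`PresynapseCohortModel` bundles a genotype cohort with variant definitions
and kinetic parameters; `fit()` runs the full per-individual simulation and
feature extraction and then the group-comparison battery, returning a
`CohortAnalysisResults` carrying the per-sample activity coefficients, the
30-column feature matrix, the three-group Kruskal--Wallis table, the
two-way ART ANOVA table (diagnosis x suicide-attempt status within
patients), Tukey post hoc contrasts for significant diagnosis effects, and
a printable `summary()`.

Because the activity-coefficient triple takes finitely many values under
the five-variant model, trajectories are computed once per distinct triple
and shared across individuals — an exact memoisation, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as gstats
from .features import FEATURE_COLUMNS, feature_table
from .kinetics import KineticParameters, Trajectory, simulate
from .variants import (
    ActivityCoefficients,
    GenotypeRecord,
    VariantSpec,
    compute_activity,
    default_variant_specs,
    parse_genotype_table,
)

__all__ = ["PresynapseCohortModel", "CohortAnalysisResults"]

_CoeffKey = tuple[float, float, float]


def _coeff_key(c: ActivityCoefficients) -> _CoeffKey:
    return (round(c.c_tph2, 12), round(c.c_sert, 12), round(c.c_maoa, 12))


class PresynapseCohortModel:
    """Genotype-informed serotonin-presynapse model for a labelled cohort.

    Parameters
    ----------
    records : sequence of GenotypeRecord
    variant_specs : optional list of VariantSpec (defaults to the five
        literature variants)
    kinetic_params : optional KineticParameters
    moment_convention : moment convention for the feature statistics
    """

    def __init__(
        self,
        records: Sequence[GenotypeRecord],
        variant_specs: Sequence[VariantSpec] | None = None,
        kinetic_params: KineticParameters | None = None,
        moment_convention: str = "population",
    ) -> None:
        if not records:
            raise ValueError("cohort is empty")
        self.records = list(records)
        self.variant_specs = (
            list(variant_specs) if variant_specs is not None else default_variant_specs()
        )
        self.kinetic_params = (
            kinetic_params if kinetic_params is not None else KineticParameters()
        )
        self.moment_convention = moment_convention
        for rec in self.records:
            rec.validate(self.variant_specs)

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        variant_specs: Sequence[VariantSpec] | None = None,
        **kwargs,
    ) -> "PresynapseCohortModel":
        specs = variant_specs if variant_specs is not None else default_variant_specs()
        return cls(parse_genotype_table(path, specs), variant_specs=specs, **kwargs)

    @classmethod
    def from_design(cls, design, **kwargs) -> "PresynapseCohortModel":
        from .cohort import generate_genotypes

        specs = kwargs.get("variant_specs") or default_variant_specs()
        kwargs["variant_specs"] = specs
        return cls(generate_genotypes(design, specs), **kwargs)

    # -- fitting ----------------------------------------------------------

    def activity_frame(self) -> pd.DataFrame:
        """Per-sample activity coefficients with group labels."""
        rows = []
        for rec in self.records:
            c = compute_activity(rec, self.variant_specs)
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "sex": rec.sex,
                    "diagnosis": rec.diagnosis,
                    "sa_status": rec.sa_status,
                    "age": rec.age,
                    "c_tph2": c.c_tph2,
                    "c_sert": c.c_sert,
                    "c_maoa": c.c_maoa,
                }
            )
        return pd.DataFrame(rows)

    def fit(
        self,
        posthoc: bool = True,
        bh_adjust: bool = False,
        trajectory_cache: dict[_CoeffKey, Trajectory] | None = None,
    ) -> "CohortAnalysisResults":
        """Simulate every individual, extract features, run the statistics.

        ``trajectory_cache`` may be shared across fits with identical
        kinetic parameters (e.g. replicate cohorts) to reuse simulations.
        """
        cache = trajectory_cache if trajectory_cache is not None else {}
        coeffs = self.activity_frame()
        keys: list[_CoeffKey] = []
        for c_tph2, c_sert, c_maoa in coeffs[["c_tph2", "c_sert", "c_maoa"]].values:
            key = _coeff_key(
                ActivityCoefficients(c_tph2=c_tph2, c_sert=c_sert, c_maoa=c_maoa)
            )
            if key not in cache:
                cache[key] = simulate(
                    ActivityCoefficients(*key), self.kinetic_params
                )
            keys.append(key)
        traj_items = [(rec.sample_id, cache[k]) for rec, k in zip(self.records, keys)]
        feats = feature_table(traj_items, convention=self.moment_convention)
        feats.insert(1, "diagnosis", coeffs["diagnosis"].to_numpy())
        feats.insert(2, "sa_status", coeffs["sa_status"].to_numpy())

        notices: list[str] = []
        kw = self._kruskal_table(feats, notices)
        art, ph = self._art_tables(feats, posthoc, notices)
        if bh_adjust:
            kw = _add_bh(kw, "p")
            art = _add_bh(art, "p", by="effect")
        return CohortAnalysisResults(
            model=self,
            coefficients=coeffs,
            features=feats,
            kruskal=kw,
            art=art,
            posthoc=ph,
            notices=notices,
            trajectory_cache=cache,
            sample_keys=dict(zip(coeffs["sample_id"], keys)),
        )

    def _kruskal_table(
        self, feats: pd.DataFrame, notices: list[str]
    ) -> pd.DataFrame:
        patients = feats[feats["diagnosis"] != "UNAFFECTED"]
        groups = {
            "SA": patients[patients["sa_status"] == "SA"],
            "NONSA": patients[patients["sa_status"] == "NONSA"],
            "UNAFFECTED": feats[feats["diagnosis"] == "UNAFFECTED"],
        }
        if any(len(g) == 0 for g in groups.values()) or len(feats) < 3:
            notices.append(
                "kruskal-wallis skipped: need non-empty SA, non-SA and "
                "unaffected groups"
            )
            return pd.DataFrame()
        rows = []
        for col in FEATURE_COLUMNS:
            res = gstats.kruskal_wallis([g[col].to_numpy() for g in groups.values()])
            rows.append(
                {
                    "feature": col,
                    "mean_UNAFFECTED": groups["UNAFFECTED"][col].mean(),
                    "mean_SA": groups["SA"][col].mean(),
                    "mean_NONSA": groups["NONSA"][col].mean(),
                    "H": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "label": gstats.significance_label(res.p_value),
                }
            )
        return pd.DataFrame(rows)

    def _art_tables(
        self, feats: pd.DataFrame, posthoc: bool, notices: list[str]
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        patients = feats[feats["diagnosis"] != "UNAFFECTED"]
        diag = patients["diagnosis"].to_numpy()
        sa = patients["sa_status"].to_numpy()
        cells = pd.crosstab(diag, sa) if len(patients) else pd.DataFrame()
        n_cells = int(cells.shape[0] * cells.shape[1]) if len(cells) else 0
        enough = (
            len(patients) > n_cells
            and n_cells >= 4
            and (cells.to_numpy() > 0).all()
        )
        if not enough:
            notices.append(
                "art-anova skipped: incomplete diagnosis x SA factorial layout"
            )
            return pd.DataFrame(), pd.DataFrame()
        art_rows, ph_frames = [], []
        for col in FEATURE_COLUMNS:
            y = patients[col].to_numpy()
            res = gstats.art_anova(y, diag, sa, a_name="diagnosis", b_name="sa_status")
            for effect, tr in res.effects.items():
                art_rows.append(
                    {
                        "feature": col,
                        "effect": effect,
                        "F": tr.statistic,
                        "df1": tr.df[0],
                        "df2": tr.df[1],
                        "p": tr.p_value,
                        "label": gstats.significance_label(tr.p_value),
                    }
                )
            diag_p = res.effects["diagnosis"].p_value
            if posthoc and diag_p < gstats.ALPHA:
                frame = gstats.art_posthoc(y, diag, sa, factor="A")
                frame.insert(0, "feature", col)
                ph_frames.append(frame)
        ph = (
            pd.concat(ph_frames, ignore_index=True)
            if ph_frames
            else pd.DataFrame()
        )
        return pd.DataFrame(art_rows), ph


def _add_bh(frame: pd.DataFrame, pcol: str, by: str | None = None) -> pd.DataFrame:
    """Benjamini--Hochberg column across features (optional, non-default)."""
    from statsmodels.stats.multitest import multipletests

    if frame.empty:
        return frame
    frame = frame.copy()
    if by is None:
        frame["p_bh"] = multipletests(frame[pcol], method="fdr_bh")[1]
    else:
        frame["p_bh"] = np.nan
        for _, idx in frame.groupby(by).groups.items():
            frame.loc[idx, "p_bh"] = multipletests(
                frame.loc[idx, pcol], method="fdr_bh"
            )[1]
    return frame


@dataclass
class CohortAnalysisResults:
    """Fitted results: features, test tables, diagnostics and summary."""

    model: PresynapseCohortModel
    coefficients: pd.DataFrame
    features: pd.DataFrame
    kruskal: pd.DataFrame
    art: pd.DataFrame
    posthoc: pd.DataFrame
    notices: list[str]
    trajectory_cache: Mapping[_CoeffKey, Trajectory]
    sample_keys: Mapping[str, _CoeffKey]

    def trajectory_for(self, sample_id: str) -> Trajectory:
        return self.trajectory_cache[self.sample_keys[sample_id]]

    def significant(self, table: str = "art", alpha: float = gstats.ALPHA) -> pd.DataFrame:
        frame = getattr(self, table)
        if frame.empty:
            return frame
        return frame[frame["p"] < alpha]

    def summary(self) -> str:
        lines = []
        lines.append("Serotonin presynapse cohort analysis")
        lines.append("=" * 52)
        counts = (
            self.coefficients.groupby(["diagnosis", "sa_status"])
            .size()
            .rename("n")
            .reset_index()
        )
        lines.append(f"Samples: {len(self.coefficients)}")
        for _, row in counts.iterrows():
            lines.append(f"  {row['diagnosis']:>10} {row['sa_status']:>6}: {row['n']}")
        lines.append(f"Features per sample: {len(FEATURE_COLUMNS)}")
        if not self.kruskal.empty:
            sig = self.kruskal[self.kruskal["p"] < gstats.ALPHA]
            lines.append(
                f"Kruskal-Wallis (SA / non-SA / unaffected): "
                f"{len(sig)}/{len(self.kruskal)} features significant at 0.05"
            )
            for _, row in sig.iterrows():
                lines.append(f"  {row['feature']:<14} H={row['H']:.2f} p={row['p']:.4f}")
        if not self.art.empty:
            sig = self.art[self.art["p"] < gstats.ALPHA]
            lines.append(
                f"ART ANOVA (diagnosis x SA status, patients): "
                f"{len(sig)} significant effects at 0.05"
            )
            for _, row in sig.iterrows():
                lines.append(
                    f"  {row['feature']:<14} {row['effect']:<22} "
                    f"F={row['F']:.2f} p={row['p']:.4f}"
                )
        for note in self.notices:
            lines.append(f"NOTE: {note}")
        return "\n".join(lines)
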