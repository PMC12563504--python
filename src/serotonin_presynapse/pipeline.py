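"""End-to-end orchestration: genotypes -> simulation -> features -> statistics.

`run_full_analysis` reproduces the study's analysis layout on any genotype
table or synthetic cohort design: a demographic summary with its tests
(Mann--Whitney age SA vs non-SA, Kruskal--Wallis age across the three
groups, sex chi-square with Yates correction), the per-feature three-group
Kruskal--Wallis table with group means, per-feature two-way ART ANOVA
within patients with Tukey post hoc contrasts for significant diagnosis
effects, plus feature and (optional) trajectory CSV exports, the resolved
configuration and a run log.  Identical config + seed reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import stats as gstats
from .cohort import generate_genotypes
from .config import (
    design_from_config,
    dump_config,
    load_config,
    params_from_config,
    specs_from_config,
)
from .kinetics import SPECIES, Trajectory
from .model import CohortAnalysisResults, PresynapseCohortModel
from .variants import GenotypeRecord, parse_genotype_table, write_genotype_table

__all__ = [
    "RunConfig",
    "run_full_analysis",
    "summarize_demographics",
    "trajectories_to_frame",
    "trajectories_from_frame",
]

logger = logging.getLogger("serotonin_presynapse")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run (fully serialisable)."""

    genotype_path: str | None = None
    config_path: str | None = None
    outdir: str = "presynapse_run"
    seed: int = 0
    write_trajectories: bool = False
    options: dict[str, Any] = field(default_factory=dict)

    def resolved(self) -> dict[str, Any]:
        return {
            "genotype_path": self.genotype_path,
            "config_path": self.config_path,
            "outdir": self.outdir,
            "seed": self.seed,
            "write_trajectories": self.write_trajectories,
            "options": dict(self.options),
        }


def summarize_demographics(
    records: Sequence[GenotypeRecord], yates: bool = True
) -> dict[str, Any]:
    """Counts, percentages and the demographic tests.

    Returns a dict with a ``counts`` DataFrame (diagnosis x SA cells with
    sex breakdown and shares) and a ``tests`` dict: sex chi-square between
    SA and non-SA patients (Yates by default for the 2x2 table) and, when
    ages are present, Mann--Whitney age SA vs non-SA plus Kruskal--Wallis
    age across SA / non-SA / unaffected.  Tests that the data cannot
    support are skipped with an explicit notice.
    """
    if not records:
        raise ValueError("no records")
    frame = pd.DataFrame(
        {
            "diagnosis": [r.diagnosis for r in records],
            "sa_status": [r.sa_status for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
        }
    )
    patients = frame[frame["diagnosis"] != "UNAFFECTED"]
    n_patients = len(patients)
    rows = []
    for (diag, sa), sub in frame.groupby(["diagnosis", "sa_status"], sort=True):
        rows.append(
            {
                "diagnosis": diag,
                "sa_status": sa,
                "n": len(sub),
                "n_female": int((sub["sex"] == "female").sum()),
                "n_male": int((sub["sex"] == "male").sum()),
                "pct_of_patients": (
                    round(100.0 * len(sub) / n_patients, 2)
                    if diag != "UNAFFECTED" and n_patients
                    else np.nan
                ),
            }
        )
    counts = pd.DataFrame(rows)

    shares: dict[str, float] = {}
    if n_patients:
        for diag in ("BD", "MDD", "SCH"):
            n = int((patients["diagnosis"] == diag).sum())
            if n:
                shares[f"{diag.lower()}_pct"] = round(100.0 * n / n_patients, 2)
        for sa in ("SA", "NONSA"):
            n = int((patients["sa_status"] == sa).sum())
            if n:
                shares[f"{sa.lower()}_pct"] = round(100.0 * n / n_patients, 2)

    tests: dict[str, Any] = {}
    notices: list[str] = []
    sa_pat = patients[patients["sa_status"] == "SA"]
    nonsa_pat = patients[patients["sa_status"] == "NONSA"]
    if len(sa_pat) and len(nonsa_pat):
        table = [
            [int((g["sex"] == "female").sum()), int((g["sex"] == "male").sum())]
            for g in (sa_pat, nonsa_pat)
        ]
        if all(sum(row) for row in table) and all(
            sum(col) for col in zip(*table)
        ):
            tests["sex_sa_vs_nonsa"] = gstats.chi_square_independence(
                table, yates=yates
            )
        else:
            notices.append("sex chi-square skipped: zero margin")
    else:
        notices.append("sex chi-square skipped: need both SA and non-SA patients")

    ages_ok = frame["age"].notna().all() and len(frame) > 0
    if ages_ok and len(sa_pat) and len(nonsa_pat):
        tests["age_sa_vs_nonsa"] = gstats.mann_whitney(
            sa_pat["age"].to_numpy(float), nonsa_pat["age"].to_numpy(float)
        )
        unaff = frame[frame["diagnosis"] == "UNAFFECTED"]
        if len(unaff):
            tests["age_three_group"] = gstats.kruskal_wallis(
                [
                    sa_pat["age"].to_numpy(float),
                    nonsa_pat["age"].to_numpy(float),
                    unaff["age"].to_numpy(float),
                ]
            )
    elif not ages_ok:
        notices.append("age tests skipped: ages absent")
    return {"counts": counts, "shares": shares, "tests": tests, "notices": notices}


def trajectories_to_frame(
    items: Sequence[tuple[str, Trajectory]]
) -> pd.DataFrame:
    """Tidy trajectory table: sample_id, time_min, species, concentration_uM."""
    frames = []
    for sample_id, traj in items:
        for sp in SPECIES:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "time_min": traj.times,
                        "species": sp,
                        "concentration_uM": traj.series[sp],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def trajectories_from_frame(frame: pd.DataFrame) -> list[tuple[str, Trajectory]]:
    """Rebuild trajectories from the tidy CSV format (inverse of the above)."""
    out = []
    for sample_id, sub in frame.groupby("sample_id", sort=False):
        series = {}
        times = None
        for sp, sp_sub in sub.groupby("species", sort=False):
            sp_sub = sp_sub.sort_values("time_min")
            series[sp] = sp_sub["concentration_uM"].to_numpy(float)
            times = sp_sub["time_min"].to_numpy(float)
        out.append((str(sample_id), Trajectory(times=times, series=series)))
    return out


def _test_to_dict(res: gstats.TestResult) -> dict[str, Any]:
    df = res.df
    if isinstance(df, tuple):
        df = list(df)
    return {
        "statistic": res.statistic,
        "df": df,
        "p_value": res.p_value,
        "method": res.method,
        "n_per_group": list(res.n_per_group),
    }


def run_full_analysis(run: RunConfig) -> CohortAnalysisResults | None:
    """Execute the whole pipeline and write all artifacts to ``run.outdir``.

    Returns the fitted results (None when the cohort is too small for any
    statistics — the demographic table is still written).
    """
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config = load_config(run.config_path)
        specs = specs_from_config(config)
        params = params_from_config(config)
        stat_opts = dict(config.get("statistics") or {})
        stat_opts.update(run.options)

        if run.genotype_path:
            logger.info("stage=genotypes loading %s", run.genotype_path)
            records = parse_genotype_table(run.genotype_path, specs)
        else:
            design = design_from_config(config, seed=run.seed)
            logger.info(
                "stage=genotypes synthesising cohort n=%d seed=%d",
                design.total_n,
                design.seed,
            )
            records = generate_genotypes(design, specs)
            write_genotype_table(records, outdir / "genotypes.tsv")

        demo = summarize_demographics(
            records, yates=bool(stat_opts.get("yates", True))
        )
        demo["counts"].to_csv(outdir / "demographics.csv", index=False)
        with open(outdir / "demographic_tests.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "shares": demo["shares"],
                    "tests": {k: _test_to_dict(v) for k, v in demo["tests"].items()},
                    "notices": demo["notices"],
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        dump_config(run.resolved(), outdir / "resolved_config.yaml")

        if len(records) < 2:
            logger.info("stage=stats skipped: cohort of %d", len(records))
            (outdir / "NOTICE.txt").write_text(
                "statistics stage skipped: cohort has fewer than 2 individuals\n",
                encoding="utf-8",
            )
            return None

        model = PresynapseCohortModel(
            records,
            variant_specs=specs,
            kinetic_params=params,
            moment_convention=stat_opts.get("moment_convention", "population"),
        )
        logger.info("stage=simulate n=%d", len(records))
        results = model.fit(
            posthoc=bool(stat_opts.get("posthoc", True)),
            bh_adjust=bool(stat_opts.get("bh_adjust", False)),
        )
        logger.info(
            "stage=simulate distinct coefficient profiles=%d",
            len(results.trajectory_cache),
        )
        results.features.to_csv(outdir / "features.csv", index=False)
        if not results.kruskal.empty:
            results.kruskal.to_csv(outdir / "kruskal_wallis.csv", index=False)
        if not results.art.empty:
            results.art.to_csv(outdir / "art_anova.csv", index=False)
        if not results.posthoc.empty:
            results.posthoc.to_csv(outdir / "posthoc.csv", index=False)
        if run.write_trajectories:
            items = [(r.sample_id, results.trajectory_for(r.sample_id)) for r in records]
            trajectories_to_frame(items).to_csv(
                outdir / "trajectories.csv", index=False
            )
        (outdir / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
        for note in results.notices:
            logger.info("notice: %s", note)
        logger.info("stage=done outputs in %s", outdir)
        return results
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
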