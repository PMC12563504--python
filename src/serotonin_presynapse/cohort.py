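"""Synthetic genotype cohorts under Hardy--Weinberg equilibrium.

The study cohort (392 psychiatric patients split by diagnosis and
suicide-attempt history, plus 140 unaffected individuals) is not publicly
deposited, so analyses are exercised on synthetic cohorts with the same
structure: per-cell sample sizes and sex counts, Hardy--Weinberg genotypes
at configurable allele frequencies, X-linked hemizygosity for the MAOA
uVNTR in males, and optional per-group allele-frequency shifts used to
inject detectable effects for power and recovery studies.

Default allele frequencies are documented placeholders (the study's own
frequency tables are not reproduced here) and are fully configurable; no
numerical comparison in this package depends on them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .variants import (
    GenotypeRecord,
    VariantSpec,
    VARIANT_IDS,
    default_variant_specs,
)

__all__ = [
    "CohortCell",
    "CohortDesign",
    "DEFAULT_ALLELE_FREQS",
    "TABLE1_AGE_MODEL",
    "default_study_design",
    "inject_effect",
    "generate_genotypes",
]

#: Placeholder population allele frequencies (configurable, not canonical).
DEFAULT_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "rs111798998": {"G": 0.35, "T": 0.65},
    "rs4290270": {"A": 0.40, "T": 0.60},
    "rs7305115": {"A": 0.45, "G": 0.55},
    "HTTLPR": {"L": 0.55, "S": 0.45},
    "uVNTR": {"2R": 0.015, "3R": 0.60, "3.5R": 0.02, "4R": 0.35, "5R": 0.015},
}

#: Per-cell age means/SDs (years) for the optional demographic age model.
TABLE1_AGE_MODEL: dict[tuple[str, str], tuple[float, float]] = {
    ("BD", "SA"): (43.74, 11.7),
    ("BD", "NONSA"): (39.05, 10.9),
    ("MDD", "SA"): (47.91, 9.7),
    ("MDD", "NONSA"): (50.99, 8.2),
    ("SCH", "SA"): (31.11, 8.7),
    ("SCH", "NONSA"): (35.47, 9.5),
    ("UNAFFECTED", "NA"): (40.34, 11.19),
}


@dataclass(frozen=True)
class CohortCell:
    """One diagnosis x suicide-attempt-status cell of the design."""

    diagnosis: str
    sa_status: str
    n: int
    n_female: int

    def __post_init__(self) -> None:
        if self.n < 0 or not (0 <= self.n_female <= self.n):
            raise ValueError(
                f"cell ({self.diagnosis}, {self.sa_status}): invalid sizes "
                f"n={self.n}, n_female={self.n_female}"
            )


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout plus sampling frequencies.

    ``allele_freqs`` are the shared (population) frequencies per variant;
    ``group_freqs`` optionally overrides them per diagnosis group — the
    mechanism behind :func:`inject_effect`.
    """

    cells: tuple[CohortCell, ...]
    allele_freqs: Mapping[str, Mapping[str, float]]
    group_freqs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict
    )
    seed: int = 0
    simulate_ages: bool = False

    def __post_init__(self) -> None:
        for vid, freqs in self.allele_freqs.items():
            _validate_freqs(vid, freqs)
        for group, per_variant in self.group_freqs.items():
            for vid, freqs in per_variant.items():
                _validate_freqs(f"{group}/{vid}", freqs)

    def freqs_for(self, diagnosis: str, variant_id: str) -> Mapping[str, float]:
        return self.group_freqs.get(diagnosis, {}).get(
            variant_id, self.allele_freqs[variant_id]
        )

    @property
    def total_n(self) -> int:
        return sum(c.n for c in self.cells)


def _validate_freqs(label: str, freqs: Mapping[str, float]) -> None:
    vals = list(freqs.values())
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError(f"{label}: frequencies must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"{label}: frequencies must sum to 1 (got {sum(vals)})")


def default_study_design(seed: int = 0, simulate_ages: bool = False) -> CohortDesign:
    """The study layout: 392 patients in six diagnosis x SA cells + 140 unaffected.

    Cell sizes and per-cell female counts follow the published demographic
    table (BD 46/55, MDD 76/72, SCH 53/90 split SA/non-SA; 140 unaffected
    with 48 women), so demographic summaries of a generated cohort
    reproduce the printed shares exactly.  Allele frequencies default to
    the shared neutral placeholders.
    """
    cells = (
        CohortCell("BD", "SA", 46, 34),
        CohortCell("BD", "NONSA", 55, 43),
        CohortCell("MDD", "SA", 76, 55),
        CohortCell("MDD", "NONSA", 72, 44),
        CohortCell("SCH", "SA", 53, 29),
        CohortCell("SCH", "NONSA", 90, 53),
        CohortCell("UNAFFECTED", "NA", 140, 48),
    )
    return CohortDesign(
        cells=cells,
        allele_freqs=copy.deepcopy(DEFAULT_ALLELE_FREQS),
        seed=seed,
        simulate_ages=simulate_ages,
    )


def inject_effect(
    design: CohortDesign,
    target_group: str,
    variant_id: str,
    allele: str,
    delta: float,
) -> CohortDesign:
    """Shift one allele's frequency by ``delta`` within one diagnosis group.

    The remaining alleles are scaled down (or up) proportionally so the
    frequencies still sum to one.  Returns a new design; the input design
    is unchanged.
    """
    base = dict(design.freqs_for(target_group, variant_id))
    if allele not in base:
        raise ValueError(f"unknown allele {allele!r} for {variant_id}")
    new_target = base[allele] + delta
    if not (0.0 <= new_target <= 1.0):
        raise ValueError(
            f"shifted frequency {new_target:.4f} for {variant_id} {allele} "
            f"out of [0, 1]"
        )
    rest = 1.0 - base[allele]
    shifted = {}
    for al, f in base.items():
        if al == allele:
            shifted[al] = new_target
        elif rest > 0:
            shifted[al] = f * (1.0 - new_target) / rest
        else:
            shifted[al] = (1.0 - new_target) / (len(base) - 1)
    group_freqs = {g: {v: dict(m) for v, m in pv.items()}
                   for g, pv in design.group_freqs.items()}
    group_freqs.setdefault(target_group, {})[variant_id] = shifted
    return replace(design, group_freqs=group_freqs)


def _draw_alleles(rng: np.random.Generator, freqs: Mapping[str, float], k: int):
    alleles = list(freqs.keys())
    probs = np.array([freqs[a] for a in alleles], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(alleles), size=k, p=probs)
    return tuple(alleles[i] for i in idx)


def generate_genotypes(
    design: CohortDesign,
    specs: Sequence[VariantSpec] | None = None,
) -> list[GenotypeRecord]:
    """Sample a cohort of genotype records from the design.

    Autosomal variants are drawn under Hardy--Weinberg within each group
    (two independent allele draws); the X-linked MAOA uVNTR gets one draw
    for males and two for females.  Sex counts per cell match the design
    exactly; sexes are shuffled within the cell.  Each cell uses its own
    deterministic substream of the master seed, so resizing one cell never
    perturbs another, and the same seed always yields the same cohort.
    """
    if specs is None:
        specs = default_variant_specs()
    by_id = {s.variant_id: s for s in specs}
    records: list[GenotypeRecord] = []
    for cell_index, cell in enumerate(design.cells):
        ss = np.random.SeedSequence(entropy=(design.seed, cell_index))
        rng = np.random.default_rng(ss)
        sexes = np.array(
            ["female"] * cell.n_female + ["male"] * (cell.n - cell.n_female)
        )
        rng.shuffle(sexes)
        ages = None
        if design.simulate_ages:
            mean, sd = TABLE1_AGE_MODEL.get(
                (cell.diagnosis, cell.sa_status), (40.0, 11.0)
            )
            ages = np.clip(rng.normal(mean, sd, size=cell.n), 18.0, 90.0)
        for i in range(cell.n):
            calls = {}
            for vid in VARIANT_IDS:
                spec = by_id[vid]
                freqs = design.freqs_for(cell.diagnosis, vid)
                if spec.inheritance == "x_linked" and sexes[i] == "male":
                    calls[vid] = _draw_alleles(rng, freqs, 1)
                else:
                    calls[vid] = _draw_alleles(rng, freqs, 2)
            records.append(
                GenotypeRecord(
                    sample_id=f"{cell.diagnosis}_{cell.sa_status}_{i:04d}",
                    sex=str(sexes[i]),
                    diagnosis=cell.diagnosis,
                    sa_status=cell.sa_status,
                    calls=calls,
                    age=float(round(ages[i], 2)) if ages is not None else None,
                )
            )
    return records
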