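"""Functional variants of the serotonin pathway and genotype -> activity mapping.

Five regulatory variants modulate expression of the three proteins in the
presynaptic serotonin cycle:

* *TPH2* (synthesis): rs111798998 (G raises mRNA ~3-fold), rs7305115
  (A raises ~1.7-fold), rs4290270 (A lowers ~1.4-fold);
* *SLC6A4* / SERT (reuptake): the 5-HTTLPR promoter length polymorphism
  (L allele raises transporter mRNA ~3-fold over S);
* *MAOA* (degradation): the X-linked promoter uVNTR, whose 3.5R and 4R
  alleles raise expression 5--6-fold relative to the other repeat alleles.

Each individual's genotype is converted into a triple of dimensionless
activity coefficients (``c_tph2``, ``c_sert``, ``c_maoa``) that scale the
corresponding Vmax values in the kinetic model: allele fold-changes combine
additively (arithmetic mean) within a diploid call, and multiplicatively
across the three TPH2 SNPs.  Males are hemizygous at the MAOA uVNTR and
carry a single allele.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantSpec",
    "GenotypeRecord",
    "ActivityCoefficients",
    "default_variant_specs",
    "specs_with_overrides",
    "variant_coefficient",
    "compute_activity",
    "parse_genotype_table",
    "write_genotype_table",
    "GENOTYPE_COLUMNS",
    "VARIANT_IDS",
    "DIAGNOSES",
    "SA_STATUSES",
    "SEXES",
]

DIAGNOSES = ("BD", "MDD", "SCH", "UNAFFECTED")
SA_STATUSES = ("SA", "NONSA", "NA")
SEXES = ("female", "male")

VARIANT_IDS = ("rs111798998", "rs4290270", "rs7305115", "HTTLPR", "uVNTR")

GENOTYPE_COLUMNS = (
    "sample_id",
    "sex",
    "diagnosis",
    "sa_status",
    "rs111798998",
    "rs4290270",
    "rs7305115",
    "HTTLPR",
    "uVNTR",
)


@dataclass(frozen=True)
class VariantSpec:
    """One functional variant: its alleles, expression multipliers, inheritance.

    ``multiplier`` maps each allele to a positive expression fold-change
    relative to the reference allele, whose multiplier is exactly 1.0.
    """

    gene: str
    variant_id: str
    alleles: tuple[str, ...]
    multiplier: Mapping[str, float]
    inheritance: str = "autosomal"  # or "x_linked"

    def __post_init__(self) -> None:
        if self.gene not in ("TPH2", "SLC6A4", "MAOA"):
            raise ValueError(f"unknown gene {self.gene!r}")
        if self.inheritance not in ("autosomal", "x_linked"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.variant_id}: duplicate alleles")
        if set(self.multiplier) != set(self.alleles):
            raise ValueError(f"{self.variant_id}: multiplier keys must match alleles")
        for allele, m in self.multiplier.items():
            if not (m > 0):
                raise ValueError(
                    f"{self.variant_id}: multiplier for allele {allele!r} must be > 0"
                )
        if not any(m == 1.0 for m in self.multiplier.values()):
            raise ValueError(f"{self.variant_id}: no reference allele (multiplier 1.0)")

    @property
    def max_multiplier(self) -> float:
        return max(self.multiplier.values())


@dataclass(frozen=True)
class ActivityCoefficients:
    """Per-individual protein-activity scalars derived from genotype."""

    c_tph2: float
    c_sert: float
    c_maoa: float

    def __post_init__(self) -> None:
        for name in ("c_tph2", "c_sert", "c_maoa"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c_tph2, self.c_sert, self.c_maoa)


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual's labels and five-variant genotype.

    ``calls`` maps variant id to a tuple of alleles: two for diploid calls,
    one for hemizygous calls (male MAOA uVNTR).
    """

    sample_id: str
    sex: str
    diagnosis: str
    sa_status: str
    calls: Mapping[str, tuple[str, ...]]
    age: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"{self.sample_id}: invalid sex {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"{self.sample_id}: invalid diagnosis {self.diagnosis!r}")
        if self.sa_status not in SA_STATUSES:
            raise ValueError(f"{self.sample_id}: invalid sa_status {self.sa_status!r}")
        if (self.sa_status == "NA") != (self.diagnosis == "UNAFFECTED"):
            raise ValueError(
                f"{self.sample_id}: sa_status must be NA exactly for UNAFFECTED "
                f"(got diagnosis={self.diagnosis}, sa_status={self.sa_status})"
            )

    def validate(self, specs: Sequence[VariantSpec]) -> None:
        """Check the calls against a set of variant specs; raise on violation."""
        by_id = {s.variant_id: s for s in specs}
        for vid, spec in by_id.items():
            if vid not in self.calls:
                raise ValueError(f"{self.sample_id}: missing call for {vid}")
            call = self.calls[vid]
            for allele in call:
                if allele not in spec.alleles:
                    raise ValueError(
                        f"{self.sample_id}: unknown allele {allele!r} at {vid}"
                    )
            if spec.inheritance == "x_linked":
                expected = 1 if self.sex == "male" else 2
                if len(call) != expected:
                    raise ValueError(
                        f"{self.sample_id}: {self.sex} must carry {expected} "
                        f"allele(s) at X-linked {vid}, got {len(call)}"
                    )
            elif len(call) != 2:
                raise ValueError(
                    f"{self.sample_id}: autosomal {vid} needs two alleles, "
                    f"got {len(call)}"
                )
        extra = set(self.calls) - set(by_id)
        if extra:
            raise ValueError(f"{self.sample_id}: calls for unknown variants {extra}")


def default_variant_specs(maoa_high: float = 5.5) -> list[VariantSpec]:
    """The five variants with literature expression fold-changes.

    ``maoa_high`` is the shared multiplier for the high-expression uVNTR
    alleles 3.5R and 4R (default 5.5, the midpoint of the reported 5--6-fold
    range); 2R, 3R and 5R are treated as reference.
    """
    return [
        VariantSpec(
            gene="TPH2",
            variant_id="rs111798998",
            alleles=("G", "T"),
            multiplier={"G": 3.0, "T": 1.0},
        ),
        VariantSpec(
            gene="TPH2",
            variant_id="rs4290270",
            alleles=("A", "T"),
            multiplier={"A": 1.0 / 1.4, "T": 1.0},
        ),
        VariantSpec(
            gene="TPH2",
            variant_id="rs7305115",
            alleles=("A", "G"),
            multiplier={"A": 1.7, "G": 1.0},
        ),
        VariantSpec(
            gene="SLC6A4",
            variant_id="HTTLPR",
            alleles=("L", "S"),
            multiplier={"L": 3.0, "S": 1.0},
        ),
        VariantSpec(
            gene="MAOA",
            variant_id="uVNTR",
            alleles=("2R", "3R", "3.5R", "4R", "5R"),
            multiplier={"2R": 1.0, "3R": 1.0, "3.5R": maoa_high, "4R": maoa_high, "5R": 1.0},
            inheritance="x_linked",
        ),
    ]


def specs_with_overrides(
    overrides: Mapping[str, Mapping[str, float]] | None,
    base: Sequence[VariantSpec] | None = None,
) -> list[VariantSpec]:
    """Return variant specs with per-allele multipliers replaced from config.

    ``overrides`` is keyed by variant id, then allele, e.g.
    ``{"uVNTR": {"4R": 6.0, "3.5R": 6.0}}``.
    """
    specs = list(base) if base is not None else default_variant_specs()
    if not overrides:
        return specs
    out = []
    for spec in specs:
        if spec.variant_id in overrides:
            mult = dict(spec.multiplier)
            for allele, value in overrides[spec.variant_id].items():
                if allele not in mult:
                    raise ValueError(
                        f"override for unknown allele {allele!r} at {spec.variant_id}"
                    )
                mult[allele] = float(value)
            spec = VariantSpec(
                gene=spec.gene,
                variant_id=spec.variant_id,
                alleles=spec.alleles,
                multiplier=mult,
                inheritance=spec.inheritance,
            )
        out.append(spec)
    return out


def variant_coefficient(call: Sequence[str], spec: VariantSpec) -> float:
    """Combine a variant call into one activity scalar.

    Diploid calls average the two allele multipliers (additive expression of
    two gene copies); hemizygous calls use the single allele's multiplier.
    This combination rule is deliberately isolated here so it can be swapped.
    """
    if len(call) not in (1, 2):
        raise ValueError(f"{spec.variant_id}: call must have 1 or 2 alleles")
    values = []
    for allele in call:
        if allele not in spec.multiplier:
            raise ValueError(f"unknown allele {allele!r} at {spec.variant_id}")
        values.append(spec.multiplier[allele])
    return float(sum(values) / len(values))


def compute_activity(
    record: GenotypeRecord, specs: Sequence[VariantSpec]
) -> ActivityCoefficients:
    """Convert one genotype record into (c_tph2, c_sert, c_maoa).

    The three TPH2 SNP coefficients multiply (independent effects; haplotype
    phase unknown); SERT and MAOA take their single variant's coefficient.
    An all-reference genotype maps to (1, 1, 1) for either sex.
    """
    record.validate(specs)
    c_tph2 = 1.0
    c_sert = 1.0
    c_maoa = 1.0
    for spec in specs:
        coef = variant_coefficient(record.calls[spec.variant_id], spec)
        if spec.gene == "TPH2":
            c_tph2 *= coef
        elif spec.gene == "SLC6A4":
            c_sert = coef
        else:
            c_maoa = coef
    return ActivityCoefficients(c_tph2=c_tph2, c_sert=c_sert, c_maoa=c_maoa)


def _format_call(call: tuple[str, ...]) -> str:
    return "/".join(call) if len(call) > 1 else call[0]


def _parse_call(text: str) -> tuple[str, ...]:
    parts = text.strip().split("/")
    if not parts or any(p == "" for p in parts):
        raise ValueError(f"malformed call {text!r}")
    return tuple(parts)


def parse_genotype_table(
    path: str | Path | io.TextIOBase,
    specs: Sequence[VariantSpec] | None = None,
) -> list[GenotypeRecord]:
    """Read a delimited genotype table (TSV default, CSV accepted).

    Header columns: ``sample_id sex diagnosis sa_status rs111798998
    rs4290270 rs7305115 HTTLPR uVNTR`` with an optional trailing ``age``.
    Diploid calls are written ``A/B``, hemizygous calls as a bare allele.
    Every record is validated against ``specs``; errors name the offending
    line and variant.
    """
    if specs is None:
        specs = default_variant_specs()
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    first_line = text.splitlines()[0] if text else ""
    delimiter = "\t" if "\t" in first_line else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    missing = [c for c in GENOTYPE_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    has_age = "age" in (reader.fieldnames or [])

    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        try:
            calls = {vid: _parse_call(row[vid]) for vid in VARIANT_IDS}
            age_text = (row.get("age") or "").strip() if has_age else ""
            rec = GenotypeRecord(
                sample_id=row["sample_id"].strip(),
                sex=row["sex"].strip(),
                diagnosis=row["diagnosis"].strip(),
                sa_status=row["sa_status"].strip(),
                calls=calls,
                age=float(age_text) if age_text and age_text != "NA" else None,
            )
            rec.validate(specs)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        if rec.sample_id in seen:
            raise ValueError(f"line {lineno}: duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        records.append(rec)
    return records


def write_genotype_table(
    records: Iterable[GenotypeRecord],
    path: str | Path | io.TextIOBase,
    delimiter: str = "\t",
) -> None:
    """Write records in the table format read by :func:`parse_genotype_table`."""
    records = list(records)
    include_age = any(r.age is not None for r in records)
    columns = GENOTYPE_COLUMNS + (("age",) if include_age else ())

    def _emit(fh) -> None:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            row = [
                rec.sample_id,
                rec.sex,
                rec.diagnosis,
                rec.sa_status,
                *(_format_call(rec.calls[vid]) for vid in VARIANT_IDS),
            ]
            if include_age:
                row.append("NA" if rec.age is None else repr(rec.age))
            writer.writerow(row)

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _emit(fh)
    else:
        _emit(path)
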