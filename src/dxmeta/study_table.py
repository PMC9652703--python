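"""Study-level table handling: parsing, validation, 2x2 reconstruction, covariates.

The atomic analysis unit is one *study row* — one diagnostic evaluation of one
lncRNA in one sample type.  A single publication may contribute several rows
(different genes, or tissue and circulating arms of the same gene), so row
identifiers are row-unique rather than publication-unique.

Each row carries the reported sensitivity/specificity and arm sizes, from which
the 2x2 contingency table (TP/FP/FN/TN) is reconstructed by nearest-integer
rounding; the reconstruction is guarded by a round-trip invariant
``|tp/(tp+fn) - SEN| <= 0.5/n_case`` (and the analogue for specificity).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: sample-type normalisation: raw specimen label (lower-case) -> analysis class
_SAMPLE_CLASS = {
    "tissue": "tissue",
    "serum": "circulating",
    "plasma": "circulating",
    "plasma (early cancer)": "circulating",
    "gastric juices": "gastric_juice",
    "gastric juice": "gastric_juice",
}

_LOCATIONS = {"intergenic", "antisense", "intronic", "bidirectional", "unknown"}

#: default column mapping for the packaged fixture schema
DEFAULT_DIALECT: Mapping[str, str] = {
    "author": "author",
    "year": "year",
    "ethnicity": "ethnicity",
    "gene": "gene",
    "regulation": "regulation",
    "location": "location",
    "sample_type": "sample_type",
    "reported_auc": "reported_auc",
    "cutoff": "cutoff",
    "sen": "sen",
    "spe": "spe",
    "total": "total",
    "n_case": "n_case",
    "n_control": "n_control",
    "nos": "nos",
}


class StudyTableError(ValueError):
    """Raised for malformed or invariant-violating study tables."""


@dataclass(frozen=True)
class StudyRecord:
    """One study x gene x sample-type row of the meta-analysis input table.

    ``sample_type`` is the analysis class (tissue / circulating / gastric_juice);
    the raw specimen label (serum, plasma, ...) is kept in ``specimen``.
    """

    study_id: str
    author: str
    year: int
    ethnicity: str
    gene: str
    regulation: str            # "up" | "down"
    location: str              # intergenic | antisense | intronic | bidirectional | unknown
    sample_type: str           # tissue | circulating | gastric_juice
    specimen: str              # raw label as printed
    sen: float
    spe: float
    n_case: int
    n_control: int
    nos: int
    reported_auc: float | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sen <= 1.0):
            raise StudyTableError(f"{self.study_id}: SEN {self.sen} outside [0,1]")
        if not (0.0 <= self.spe <= 1.0):
            raise StudyTableError(f"{self.study_id}: SPE {self.spe} outside [0,1]")
        if self.n_case < 1 or self.n_control < 1:
            raise StudyTableError(f"{self.study_id}: non-positive arm size")
        if not (0 <= self.nos <= 9):
            raise StudyTableError(f"{self.study_id}: NOS {self.nos} outside 0-9")
        if self.regulation not in ("up", "down"):
            raise StudyTableError(f"{self.study_id}: regulation {self.regulation!r}")
        if self.location not in _LOCATIONS:
            raise StudyTableError(f"{self.study_id}: location {self.location!r}")
        if self.sample_type not in ("tissue", "circulating", "gastric_juice"):
            raise StudyTableError(f"{self.study_id}: sample type {self.sample_type!r}")

    @property
    def total(self) -> int:
        return self.n_case + self.n_control


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 diagnostic table. Cells are half-integers after continuity correction."""

    tp: float
    fp: float
    fn: float
    tn: float
    corrected: bool = False
    study_id: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise StudyTableError(f"{self.study_id}: negative cell")

    @property
    def n_case(self) -> float:
        return self.tp + self.fn

    @property
    def n_control(self) -> float:
        return self.tn + self.fp

    @property
    def sen(self) -> float:
        return self.tp / self.n_case

    @property
    def spe(self) -> float:
        return self.tn / self.n_control

    @property
    def fpr(self) -> float:
        return self.fp / self.n_control

    @property
    def dor(self) -> float:
        return (self.tp * self.tn) / (self.fp * self.fn)


@dataclass(frozen=True)
class CovariateVector:
    """Binary covariates for subgroup membership, with the missing->0 rule.

    ``location_binary`` is 1 for intergenic and 0 for antisense; rows outside
    the intergenic/antisense contrast encode 0 but are flagged in
    ``excluded_from`` and must be dropped from the corresponding subgroup
    analysis.  Likewise gastric-juice rows encode 0 in ``sample_type_binary``.
    """

    location_binary: int
    sample_type_binary: int
    size_binary: int
    quality_binary: int
    excluded_from: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.location_binary,
            self.sample_type_binary,
            self.size_binary,
            self.quality_binary,
        )


def _parse_number(raw: str, *, row: int, column: str) -> float | None:
    """Parse a numeric cell; 'Unclear'/empty -> None.

    Tolerates stray internal whitespace (the source table prints one AUC as
    '0. 612'); the repair is logged, never silent.
    """
    text = raw.strip()
    if text == "" or text.lower() in ("unclear", "na", "nan"):
        return None
    if any(ch.isspace() for ch in text):
        squeezed = "".join(text.split())
        logger.warning(
            "row %d column %r: numeric cell %r contains whitespace; read as %r",
            row, column, raw, squeezed,
        )
        text = squeezed
    try:
        return float(text)
    except ValueError as exc:
        raise StudyTableError(
            f"row {row}, column {column!r}: malformed numeric cell {raw!r}"
        ) from exc


def _slug(text: str) -> str:
    keep = [c if c.isalnum() else "_" for c in text]
    out = "".join(keep).strip("_")
    while "__" in out:
        out = out.replace("__", "_")
    return out


def parse_study_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[StudyRecord]:
    """Read a study-level CSV table into validated :class:`StudyRecord` rows.

    Parameters
    ----------
    path : path to a CSV file whose header contains (at least) the columns
        named by ``dialect`` values.
    dialect : optional mapping of canonical field -> CSV column name; defaults
        to the packaged fixture schema.

    Raises
    ------
    StudyTableError
        On a missing column, malformed numeric cell, out-of-range proportion,
        inconsistent totals, or duplicate row identifier.
    """
    colmap = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    if not path.exists():
        raise StudyTableError(f"study table not found: {path}")
    records: list[StudyRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise StudyTableError(f"{path}: empty file, no header")
        missing = [c for c in colmap.values() if c not in reader.fieldnames]
        if missing:
            raise StudyTableError(f"{path}: missing columns {missing}")
        for idx, row in enumerate(reader, start=2):  # header is line 1
            get = lambda f: (row[colmap[f]] or "").strip()  # noqa: E731
            specimen = get("sample_type")
            sample_class = _SAMPLE_CLASS.get(specimen.lower())
            if sample_class is None:
                raise StudyTableError(f"row {idx}: unknown sample type {specimen!r}")
            sen = _parse_number(get("sen"), row=idx, column="sen")
            spe = _parse_number(get("spe"), row=idx, column="spe")
            if sen is None or spe is None:
                raise StudyTableError(f"row {idx}: SEN/SPE must be present")
            n_case = int(_parse_number(get("n_case"), row=idx, column="n_case") or 0)
            n_control = int(_parse_number(get("n_control"), row=idx, column="n_control") or 0)
            total_raw = _parse_number(get("total"), row=idx, column="total") if colmap.get("total") else None
            if total_raw is not None and int(total_raw) != n_case + n_control:
                raise StudyTableError(
                    f"row {idx}: stated total {int(total_raw)} != cases+controls "
                    f"{n_case + n_control}"
                )
            study_id = "_".join(
                [_slug(get("author")), get("year"), _slug(get("gene")), _slug(specimen)]
            ).lower()
            if study_id in seen:
                raise StudyTableError(f"row {idx}: duplicate study_id {study_id!r}")
            seen.add(study_id)
            record = StudyRecord(
                study_id=study_id,
                author=get("author"),
                year=int(get("year")),
                ethnicity=get("ethnicity"),
                gene=get("gene"),
                regulation=get("regulation").lower(),
                location=get("location").lower(),
                sample_type=sample_class,
                specimen=specimen,
                sen=sen,
                spe=spe,
                n_case=n_case,
                n_control=n_control,
                nos=int(get("nos")),
                reported_auc=_parse_number(get("reported_auc"), row=idx, column="reported_auc"),
                cutoff=_parse_number(get("cutoff"), row=idx, column="cutoff"),
            )
            records.append(record)
    if not records:
        logger.warning("%s: header-only table, no study rows", path)
    logger.info("parsed %d study rows from %s", len(records), path)
    return records


def load_packaged_table() -> list[StudyRecord]:
    """Load the packaged 54-row gastric-cancer lncRNA study table."""
    with resources.as_file(
        resources.files("dxmeta").joinpath("data/table1_studies.csv")
    ) as p:
        return parse_study_table(p)


def reconstruct_contingency(record: StudyRecord) -> ContingencyTable:
    """Rebuild the 2x2 table from reported SEN/SPE and arm sizes.

    TP = round(SEN x cases) with ties away from zero; FN, TN, FP follow by
    complement.  If any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) and ``corrected`` is set.
    """
    tp = _round_half_up(record.sen * record.n_case)
    fn = record.n_case - tp
    tn = _round_half_up(record.spe * record.n_control)
    fp = record.n_control - tn
    corrected = min(tp, fn, tn, fp) == 0
    if corrected:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    table = ContingencyTable(
        tp=float(tp), fp=float(fp), fn=float(fn), tn=float(tn),
        corrected=corrected, study_id=record.study_id,
    )
    _check_round_trip(record, table)
    return table


def _round_half_up(x: float) -> int:
    # round-to-nearest with .5 away from zero (x is non-negative here)
    return int(math.floor(x + 0.5))


def _check_round_trip(record: StudyRecord, table: ContingencyTable) -> None:
    base_tp = table.tp - (0.5 if table.corrected else 0.0)
    base_tn = table.tn - (0.5 if table.corrected else 0.0)
    if abs(base_tp / record.n_case - record.sen) > 0.5 / record.n_case + 1e-12:
        raise StudyTableError(f"{record.study_id}: SEN round-trip failed")
    if abs(base_tn / record.n_control - record.spe) > 0.5 / record.n_control + 1e-12:
        raise StudyTableError(f"{record.study_id}: SPE round-trip failed")


def reconstruct_all(records: Iterable[StudyRecord]) -> list[ContingencyTable]:
    return [reconstruct_contingency(r) for r in records]


def encode_covariates(record: StudyRecord) -> CovariateVector:
    """Deterministic binary encoding of the four heterogeneity covariates.

    intergenic=1 / antisense=0, circulating=1 / tissue=0, total>200=1,
    NOS>=7=1.  Categories outside a binary contrast (gastric juice; intronic,
    bidirectional or unknown locations) encode 0 and are flagged for exclusion
    from the corresponding subgroup analysis.
    """
    excluded: list[str] = []
    if record.location == "intergenic":
        loc = 1
    elif record.location == "antisense":
        loc = 0
    else:
        loc = 0
        excluded.append("location")
    if record.sample_type == "circulating":
        styp = 1
    elif record.sample_type == "tissue":
        styp = 0
    else:
        styp = 0
        excluded.append("sample_type")
    return CovariateVector(
        location_binary=loc,
        sample_type_binary=styp,
        size_binary=1 if record.total > 200 else 0,
        quality_binary=1 if record.nos >= 7 else 0,
        excluded_from=tuple(excluded),
    )


#: metaregression covariate names, in the order used throughout
COVARIATE_NAMES = ("location", "sample_type", "sample_size", "quality")


def metareg_design(records: Sequence[StudyRecord]) -> dict[str, list[float]]:
    """Ordinal covariate coding used by the meta-regression on ln DOR.

    Each covariate is coded reference=1, index category=2; rows where the
    covariate "lacks a value" (gastric juice for sample type; intronic,
    bidirectional or unknown for genomic location) are coded 0.  This coding
    carries the missing rows as a distinct level rather than collapsing them
    into the reference class, so the binary contrast is still one unit.
    """
    design: dict[str, list[float]] = {name: [] for name in COVARIATE_NAMES}
    for r in records:
        design["location"].append(
            2.0 if r.location == "intergenic" else 1.0 if r.location == "antisense" else 0.0
        )
        design["sample_type"].append(
            2.0 if r.sample_type == "circulating" else 1.0 if r.sample_type == "tissue" else 0.0
        )
        design["sample_size"].append(2.0 if r.total > 200 else 1.0)
        design["quality"].append(2.0 if r.nos >= 7 else 1.0)
    return design


def records_to_frame(records: Sequence[StudyRecord]):
    """Normalized DataFrame view of records (export / reporting helper)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "study_id": [r.study_id for r in records],
            "author": [r.author for r in records],
            "year": [r.year for r in records],
            "gene": [r.gene for r in records],
            "regulation": [r.regulation for r in records],
            "location": [r.location for r in records],
            "sample_type": [r.sample_type for r in records],
            "specimen": [r.specimen for r in records],
            "sen": [r.sen for r in records],
            "spe": [r.spe for r in records],
            "n_case": [r.n_case for r in records],
            "n_control": [r.n_control for r in records],
            "nos": [r.nos for r in records],
        }
    )
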