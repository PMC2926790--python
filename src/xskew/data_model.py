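"""Tabular data model for reciprocal-cross allele-specific expression.

The canonical measurement is the *reference-strain fraction*: for each
(gene, individual, technical replicate) the share of expression signal
attributed to the allele of a designated reference strain (e.g. the PWD
allele in a PWD-AKR strain pair).  Maternal/paternal fractions are derived
views keyed on the cross direction and are never stored, which prevents
sign errors when the reciprocal cross flips which strain is the mother.

Cross identifiers encode the maternal strain first: ``"PWDxAKR"`` means a
PWD mother crossed to an AKR father.  Strain-pair identifiers name the
reference strain first: ``"PWD-AKR"`` designates PWD as the reference.

Internally everything lives in two tidy :class:`pandas.DataFrame` objects
(measurements and gene annotations) wrapped in :class:`ExpressionTable`.
Fractions are always stored in [0, 1]; percent appears only at I/O behind
an explicit unit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: Canonical measurement columns, in the order they are written to disk.
DATA_COLUMNS = [
    "gene_id",
    "individual_id",
    "cross_id",
    "strain_pair_id",
    "litter_id",
    "sex",
    "replicate_index",
    "ref_fraction",
]

#: Canonical annotation columns.
ANNOTATION_COLUMNS = ["gene_id", "chromosome", "position_mb", "xci_class_known"]

#: Recognised X-inactivation status labels.
XCI_CLASSES = frozenset(
    {"inactivated", "escaper", "partial", "inactive_x_expressed", "autosomal", "unknown"}
)

_LABEL_COLUMNS = ["gene_id", "individual_id", "cross_id", "strain_pair_id", "litter_id", "sex"]

# 17 significant digits round-trips any IEEE double exactly.
_FLOAT_FORMAT = "%.17g"


def maternal_strain(cross_id: str) -> str:
    """Maternal strain encoded in a cross id such as ``"PWDxAKR"``."""
    parts = str(cross_id).split("x")
    if len(parts) != 2 or not all(parts):
        raise FormatError(f"cross_id {cross_id!r} is not of the form '<maternal>x<paternal>'")
    return parts[0]


def reference_strain(strain_pair_id: str) -> str:
    """Reference strain encoded in a strain-pair id such as ``"PWD-AKR"``."""
    parts = str(strain_pair_id).split("-")
    if len(parts) != 2 or not all(parts):
        raise FormatError(
            f"strain_pair_id {strain_pair_id!r} is not of the form '<reference>-<other>'"
        )
    return parts[0]


def maternal_is_reference(cross_id: str, strain_pair_id: str) -> bool:
    """True when the reference strain is the mother in this cross."""
    return maternal_strain(cross_id) == reference_strain(strain_pair_id)


@dataclass(frozen=True)
class ExpressionRecord:
    """A single allelic-fraction measurement.

    Mostly useful for constructing small tables by hand; bulk data lives in
    the DataFrame inside :class:`ExpressionTable`.
    """

    gene_id: str
    individual_id: str
    cross_id: str
    strain_pair_id: str
    litter_id: str
    sex: str
    replicate_index: int
    ref_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ref_fraction <= 1.0:
            raise ValueError(
                f"ref_fraction {self.ref_fraction} outside [0, 1] for gene "
                f"{self.gene_id}, individual {self.individual_id}"
            )
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    position_mb: float | None = None
    xci_class_known: str = "unknown"

    def __post_init__(self) -> None:
        if self.xci_class_known not in XCI_CLASSES:
            raise ValueError(f"unknown xci class {self.xci_class_known!r}")


class ExpressionTable:
    """A validated pair of (measurements, gene annotations) frames.

    Parameters
    ----------
    data:
        Tidy frame with the columns of :data:`DATA_COLUMNS`, one row per
        (gene, individual, replicate) measurement.
    annotations:
        Frame with the columns of :data:`ANNOTATION_COLUMNS`, one row per
        gene.
    """

    def __init__(self, data: pd.DataFrame, annotations: pd.DataFrame):
        self.data = _coerce_data(data)
        self.annotations = _coerce_annotations(annotations)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[ExpressionRecord],
        annotations: Iterable[GeneAnnotation],
    ) -> "ExpressionTable":
        data = pd.DataFrame([vars(r) for r in records], columns=DATA_COLUMNS)
        ann = pd.DataFrame([vars(a) for a in annotations], columns=ANNOTATION_COLUMNS)
        return cls(data, ann)

    # -- derived views ---------------------------------------------------

    def maternal_fraction(self) -> pd.Series:
        """Per-row fraction of signal from the maternal allele.

        Equal to ``ref_fraction`` in crosses where the reference strain is
        the mother, and ``1 - ref_fraction`` in the reciprocal cross.
        """
        ref_mat = self.data.apply(
            lambda r: maternal_is_reference(r["cross_id"], r["strain_pair_id"]), axis=1
        )
        return self.data["ref_fraction"].where(ref_mat, 1.0 - self.data["ref_fraction"])

    def gene_classes(self) -> pd.Series:
        """gene_id -> known XCI class."""
        return self.annotations.set_index("gene_id")["xci_class_known"]

    def genes_of_class(self, classes: Sequence[str]) -> list[str]:
        cls = self.gene_classes()
        return sorted(cls.index[cls.isin(classes)])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionTable":
        genes = set(genes)
        return ExpressionTable(
            self.data[self.data["gene_id"].isin(genes)].reset_index(drop=True),
            self.annotations[self.annotations["gene_id"].isin(genes)].reset_index(drop=True),
        )

    def females(self) -> pd.DataFrame:
        return self.data[self.data["sex"] == "female"]

    def design_summary(self) -> dict:
        """Counts describing the experimental design."""
        fem = self.females()
        per_cross = fem.groupby("cross_id")["individual_id"].nunique().to_dict()
        reps = self.data.groupby(["gene_id", "individual_id"]).size()
        return {
            "n_genes": int(self.annotations["gene_id"].nunique()),
            "n_x_genes": int((self.annotations["chromosome"] == "X").sum()),
            "n_autosomal_genes": int((self.annotations["chromosome"] != "X").sum()),
            "n_females": int(fem["individual_id"].nunique()),
            "n_males": int(
                self.data.loc[self.data["sex"] == "male", "individual_id"].nunique()
            ),
            "females_per_cross": per_cross,
            "replicates_per_measurement": float(reps.mean()) if len(reps) else 0.0,
            "n_crosses": int(self.data["cross_id"].nunique()),
            "strain_pairs": sorted(self.data["strain_pair_id"].unique()),
        }

    # -- dunder ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return self.data.equals(other.data) and self.annotations.equals(other.annotations)

    def __repr__(self) -> str:
        s = self.design_summary()
        return (
            f"ExpressionTable({s['n_genes']} genes, {s['n_females']} females, "
            f"{s['n_crosses']} crosses, {len(self.data)} measurements)"
        )


def _coerce_data(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise FormatError(f"measurement table missing required column(s): {', '.join(missing)}")
    data = data[DATA_COLUMNS].copy()
    for col in _LABEL_COLUMNS:
        data[col] = data[col].astype(str)
    data["replicate_index"] = data["replicate_index"].astype(np.int64)
    data["ref_fraction"] = data["ref_fraction"].astype(float)
    bad = data.index[(data["ref_fraction"] < 0) | (data["ref_fraction"] > 1)]
    if len(bad):
        raise ValueError(
            f"ref_fraction outside [0, 1] at row(s) {list(bad[:5])}"
            + ("..." if len(bad) > 5 else "")
        )
    bad_sex = ~data["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValueError(f"sex must be 'female' or 'male' at row(s) {list(data.index[bad_sex][:5])}")
    return data.reset_index(drop=True)


def _coerce_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation table missing required column(s): {', '.join(missing)}")
    ann = ann[ANNOTATION_COLUMNS].copy()
    ann["gene_id"] = ann["gene_id"].astype(str)
    ann["chromosome"] = ann["chromosome"].astype(str)
    ann["position_mb"] = pd.to_numeric(ann["position_mb"], errors="coerce").astype(float)
    ann["xci_class_known"] = ann["xci_class_known"].astype(str)
    bad = ~ann["xci_class_known"].isin(XCI_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown xci_class_known value(s): {sorted(ann.loc[bad, 'xci_class_known'].unique())}"
        )
    return ann.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_table(
    data_path: str | Path,
    annotations_path: str | Path,
    *,
    unit: str = "fraction",
    column_map: dict[str, str] | None = None,
) -> ExpressionTable:
    """Load a measurement CSV/TSV and its annotation CSV into a table.

    Parameters
    ----------
    unit:
        ``"fraction"`` (default) expects ``ref_fraction`` in [0, 1];
        ``"percent"`` expects values in [0, 100] and divides by 100.
        Percent input is honoured only through this explicit flag, never
        auto-detected.
    column_map:
        Optional mapping from file header names to the canonical names,
        e.g. ``{"PWD_pct": "ref_fraction"}``.
    """
    if unit not in ("fraction", "percent"):
        raise ValueError(f"unit must be 'fraction' or 'percent', got {unit!r}")
    data_path, annotations_path = Path(data_path), Path(annotations_path)
    data = pd.read_csv(data_path, sep=_sep_for(data_path), dtype=str)
    if column_map:
        data = data.rename(columns=column_map)
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise FormatError(
            f"{data_path}: missing required column(s): {', '.join(missing)}"
        )
    # numpy's strtod is correctly rounded, so 17-sig-digit round-trips are exact
    data["ref_fraction"] = data["ref_fraction"].to_numpy(dtype=str).astype(float)
    if unit == "percent":
        data["ref_fraction"] = data["ref_fraction"] / 100.0
    data["replicate_index"] = pd.to_numeric(data["replicate_index"]).astype(np.int64)
    ann = pd.read_csv(annotations_path, sep=_sep_for(annotations_path), dtype=str)
    if column_map:
        ann = ann.rename(columns=column_map)
    return ExpressionTable(data, ann)


def write_table(
    table: ExpressionTable,
    data_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Write a table as two delimited files with a deterministic layout.

    Columns appear in canonical order and floats carry 17 significant
    digits so that write -> read round-trips are exact.
    """
    data_path, annotations_path = Path(data_path), Path(annotations_path)
    table.data[DATA_COLUMNS].to_csv(
        data_path, sep=_sep_for(data_path), index=False, float_format=_FLOAT_FORMAT
    )
    table.annotations[ANNOTATION_COLUMNS].to_csv(
        annotations_path,
        sep=_sep_for(annotations_path),
        index=False,
        float_format=_FLOAT_FORMAT,
    )


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`.

    ``errors`` disqualify a table from downstream analysis; ``warnings``
    are advisory.  ``male_control_summary`` records, per X-linked gene,
    the mean maternal fraction among male siblings (expected 1.0: a male's
    single X is maternal, so any gene without a Y homolog must show pure
    maternal signal).
    """

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)
    male_control_summary: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            msgs = "; ".join(f"[{code}] {msg}" for code, msg in self.errors)
            raise FormatError(f"table failed validation: {msgs}")


def validate_table(table: ExpressionTable, *, male_tolerance: float = 0.05) -> ValidationReport:
    """Check a table for structural and biological consistency.

    Pure: the table is never mutated.  Checks performed:

    * duplicate (gene, individual, replicate) keys  -> error
    * measured genes missing from the annotations   -> error
    * non-autosomal XCI class on a non-X chromosome -> error
    * only one cross present                        -> warning
    * male-control deviation: an X-linked gene whose male maternal
      fraction deviates from 1.0 by more than ``male_tolerance``
      -> warning naming the gene and individual
    """
    report = ValidationReport()
    data, ann = table.data, table.annotations

    dupes = data.duplicated(subset=["gene_id", "individual_id", "replicate_index"])
    if dupes.any():
        keys = data.loc[dupes, ["gene_id", "individual_id", "replicate_index"]]
        first = keys.iloc[0]
        report.errors.append(
            (
                "duplicate_key",
                f"{int(dupes.sum())} duplicate (gene, individual, replicate) key(s); "
                f"first: ({first['gene_id']}, {first['individual_id']}, "
                f"{first['replicate_index']})",
            )
        )

    unannotated = sorted(set(data["gene_id"]) - set(ann["gene_id"]))
    if unannotated:
        report.errors.append(
            ("unannotated_gene", f"gene(s) without annotation: {', '.join(unannotated)}")
        )

    bad_chrom = ann[
        (~ann["xci_class_known"].isin(["autosomal", "unknown"])) & (ann["chromosome"] != "X")
    ]
    for _, row in bad_chrom.iterrows():
        report.errors.append(
            (
                "class_chromosome_mismatch",
                f"gene {row['gene_id']} has class {row['xci_class_known']} but is on "
                f"chromosome {row['chromosome']}",
            )
        )

    if data["cross_id"].nunique() < 2:
        report.warnings.append(
            ("single_cross", "only one cross present; reciprocal analyses are unavailable")
        )

    # Male pyrosequencing controls: one maternal X only.
    males = data[data["sex"] == "male"]
    x_genes = set(ann.loc[ann["chromosome"] == "X", "gene_id"])
    males_x = males[males["gene_id"].isin(x_genes)].copy()
    if len(males_x):
        ref_mat = males_x.apply(
            lambda r: maternal_is_reference(r["cross_id"], r["strain_pair_id"]), axis=1
        )
        males_x["maternal_fraction"] = males_x["ref_fraction"].where(
            ref_mat, 1.0 - males_x["ref_fraction"]
        )
        per_ind = males_x.groupby(["gene_id", "individual_id"])["maternal_fraction"].mean()
        for (gene, ind), val in per_ind.items():
            if abs(val - 1.0) > male_tolerance:
                report.warnings.append(
                    (
                        "male_control_deviation",
                        f"gene {gene}, male {ind}: mean maternal fraction {val:.3f} "
                        f"deviates from 1.0 by more than {male_tolerance}",
                    )
                )
        summary = (
            males_x.groupby("gene_id")["maternal_fraction"]
            .agg(["mean", "count"])
            .rename(columns={"mean": "male_mean_maternal_fraction", "count": "n_measurements"})
        )
        summary["expected"] = 1.0
        summary["flagged"] = (
            (summary["male_mean_maternal_fraction"] - 1.0).abs() > male_tolerance
        )
        report.male_control_summary = summary.reset_index()

    return report
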