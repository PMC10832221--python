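"""Reading, validating and writing the tabular inputs and outputs.

All user-facing files are comma-separated UTF-8 CSV with a mandatory header
row and '.' decimals. Expression files carry features in the first column and
one sample per remaining column; the sample annotation maps samples to the
two conditions (``condition_1`` is the control). Gene sets are standard GMT.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IdentifierError,
    MissingColumnError,
    SampleCountError,
    ShapeError,
)

logger = logging.getLogger(__name__)

CONDITION_1 = "condition_1"
CONDITION_2 = "condition_2"
CONDITIONS = (CONDITION_1, CONDITION_2)

MIN_SAMPLES_PER_CONDITION = 3

#: circBase accession form; the common ``has_circ_`` typo is auto-corrected.
CIRC_ID_RE = re.compile(r"^hsa_circ_\d{7}$")
CIRC_TYPO_RE = re.compile(r"^has_circ_(\d{7})$")
MIRNA_ID_RE = re.compile(r"^hsa-(miR|let)-")

#: Columns of the final score matrix, in output order.
SCORE_MATRIX_COLUMNS = [
    "mirna_id",
    "circ_id",
    "s_affinity",
    "s_nbmre",
    "s_enrichmre",
    "s_fc_circ",
    "s_mirexpr",
    "s_targetexpr_circ",
    "s_enrichsg",
    "ss",
    "rank_global",
    "condition",
    "rank_in_condition",
    "n_mrna_targets",
    "mean_sg_of_targets",
    "mrna_target_list",
]

SITE_TABLE_COLUMNS = ["mirna_id", "target_id", "target_type", "raw_score", "site_index"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Features x samples log2-expression for one RNA type."""

    rna_type: str  # "circRNA" | "mRNA" | "miRNA"
    data: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self):
        validate_expression_matrix(self)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def canonical(self) -> "ExpressionMatrix":
        """Return a copy with rows and columns in sorted order."""
        return ExpressionMatrix(
            self.rna_type, self.data.sort_index(axis=0).sort_index(axis=1)
        )


@dataclass
class SampleAnnotation:
    """Mapping sample id -> condition; ``condition_1`` is the control."""

    sample_to_condition: dict[str, str]

    def __post_init__(self):
        bad = {c for c in self.sample_to_condition.values() if c not in CONDITIONS}
        if bad:
            raise ShapeError(f"unknown condition labels: {sorted(bad)}")
        for cond in CONDITIONS:
            n = len(self.samples_for(cond))
            if n < MIN_SAMPLES_PER_CONDITION:
                raise SampleCountError(
                    f"condition '{cond}' has {n} samples; "
                    f"at least {MIN_SAMPLES_PER_CONDITION} are required"
                )

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_to_condition.items() if c == condition]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_condition)


@dataclass
class MirnaSignature:
    """Named per-miRNA expression signature standing in for a miRNA matrix."""

    label: str
    values: dict[str, float]

    def __post_init__(self):
        if not self.values:
            raise ShapeError(f"signature '{self.label}' is empty")
        bad = {m: v for m, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ShapeError(
                f"signature '{self.label}' has non-finite values: {sorted(bad)}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets with uppercase-normalized symbols."""

    sets: dict[str, tuple[str, list[str]]]  # name -> (description, genes)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class InputBundle:
    """All validated inputs for one run."""

    circ_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    annotation: SampleAnnotation
    circ_sites: pd.DataFrame
    mrna_sites: pd.DataFrame
    circ_lengths: dict[str, int]
    mirna_expr: ExpressionMatrix | None = None
    mirna_signature: MirnaSignature | None = None
    mirna_annotation: SampleAnnotation | None = None
    validated: pd.DataFrame | None = None
    dropped_site_targets: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------


def normalize_circ_id(value: str, context: str = "") -> str:
    """Validate a circBase id, auto-correcting the ``has_circ_`` typo."""
    m = CIRC_TYPO_RE.match(value)
    if m:
        fixed = f"hsa_circ_{m.group(1)}"
        logger.warning("%scorrecting circRNA id %r -> %r", context, value, fixed)
        return fixed
    if not CIRC_ID_RE.match(value):
        raise IdentifierError(
            f"{context}invalid circRNA identifier {value!r} "
            "(expected hsa_circ_ followed by 7 digits)"
        )
    return value


def validate_feature_id(value: str, rna_type: str, context: str = "") -> str:
    if rna_type == "circRNA":
        return normalize_circ_id(value, context)
    if rna_type == "miRNA":
        if not MIRNA_ID_RE.match(value):
            raise IdentifierError(
                f"{context}invalid miRNA identifier {value!r} "
                "(expected hsa-miR-* or hsa-let-*)"
            )
        return value
    if rna_type == "mRNA":
        if not value or not str(value).strip():
            raise IdentifierError(f"{context}empty mRNA gene symbol")
        return str(value)
    raise ValueError(f"unknown rna_type {rna_type!r}")


def validate_expression_matrix(mat: ExpressionMatrix) -> None:
    df = mat.data
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ShapeError(f"duplicate feature ids in {mat.rna_type} matrix: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ShapeError(f"duplicate sample ids in {mat.rna_type} matrix: {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ShapeError(f"non-numeric cells in {mat.rna_type} matrix")
    if not np.all(np.isfinite(values)):
        rows = df.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ShapeError(
            f"non-finite values in {mat.rna_type} matrix for features {rows}"
        )
    fixed = [validate_feature_id(f, mat.rna_type, f"{mat.rna_type} matrix: ") for f in df.index]
    if fixed != list(df.index):
        df.index = fixed
        if df.index.has_duplicates:
            raise ShapeError(
                f"duplicate feature ids in {mat.rna_type} matrix after id correction"
            )


def validate_site_table(df: pd.DataFrame, path: str = "<site table>") -> pd.DataFrame:
    """Validate and canonicalize a per-MRE site table."""
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: site table lacks columns {missing}")
    df = df[SITE_TABLE_COLUMNS].copy()
    types = set(df["target_type"].unique())
    if len(types) > 1:
        raise ShapeError(f"{path}: mixed target types {sorted(types)} in one table")
    if types and not types <= {"circRNA", "mRNA"}:
        raise ShapeError(f"{path}: unknown target type {sorted(types)}")
    if not df.empty:
        ttype = df["target_type"].iloc[0]
        df["mirna_id"] = [
            validate_feature_id(m, "miRNA", f"{path}: ") for m in df["mirna_id"]
        ]
        df["target_id"] = [
            validate_feature_id(t, ttype, f"{path}: ") for t in df["target_id"]
        ]
        if not np.issubdtype(df["raw_score"].dtype, np.number):
            raise ShapeError(f"{path}: non-numeric raw_score values")
        if (df["site_index"] < 1).any():
            bad = df.loc[df["site_index"] < 1].iloc[0]
            raise ShapeError(f"{path}: site_index < 1 in row {bad.to_dict()}")
        key = df[["mirna_id", "target_id", "site_index"]]
        if key.duplicated().any():
            bad = key[key.duplicated()].iloc[0].to_dict()
            raise ShapeError(f"{path}: duplicate site row {bad}")
    return df.sort_values(SITE_TABLE_COLUMNS[:3]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_expression_csv(path: str | Path, rna_type: str) -> ExpressionMatrix:
    """Read a features-x-samples expression CSV (first column = feature id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None  # first column name is free-form
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ShapeError(f"{path}: non-numeric cells in sample column {col!r}")
    return ExpressionMatrix(rna_type, df.astype(float)).canonical()


def read_annotation_csv(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path)
    for col in ("samples", "conditions"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: annotation lacks column '{col}'")
    mapping = dict(zip(df["samples"].astype(str), df["conditions"].astype(str)))
    if len(mapping) != len(df):
        dups = df["samples"][df["samples"].duplicated()].tolist()
        raise ShapeError(f"{path}: duplicate samples in annotation: {dups}")
    return SampleAnnotation(mapping)


def read_site_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_site_table(df, str(path))


def read_lengths_csv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    for col in ("circ_id", "length"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: length table lacks column '{col}'")
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        cid = normalize_circ_id(str(row["circ_id"]), f"{path}: ")
        length = int(row["length"])
        if length <= 0:
            raise ShapeError(f"{path}: non-positive length {length} for {cid}")
        if cid in out:
            raise ShapeError(f"{path}: duplicate circRNA {cid} in length table")
        out[cid] = length
    return out


def read_validated_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["mirna_id", "circ_id", "n_clipseq", "n_degradome"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: validated table lacks columns {missing}")
    df = df[needed].copy()
    df["mirna_id"] = [validate_feature_id(m, "miRNA", f"{path}: ") for m in df["mirna_id"]]
    df["circ_id"] = [normalize_circ_id(c, f"{path}: ") for c in df["circ_id"]]
    if df[["mirna_id", "circ_id"]].duplicated().any():
        bad = df[df[["mirna_id", "circ_id"]].duplicated()].iloc[0]
        raise ShapeError(f"{path}: duplicate validated pair {bad.to_dict()}")
    if (df[["n_clipseq", "n_degradome"]] < 0).any().any():
        raise ShapeError(f"{path}: negative evidence counts")
    return df.sort_values(["mirna_id", "circ_id"]).reset_index(drop=True)


def read_signature_csv(path: str | Path, label: str | None = None) -> MirnaSignature:
    df = pd.read_csv(path)
    for col in ("mirna_id", "value"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: signature lacks column '{col}'")
    values = {
        validate_feature_id(str(m), "miRNA", f"{path}: "): float(v)
        for m, v in zip(df["mirna_id"], df["value"])
    }
    return MirnaSignature(label or Path(path).stem, values)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    f"expected >=3: {line!r}"
                )
            name, desc = fields[0], fields[1]
            genes = sorted({g.strip().upper() for g in fields[2:] if g.strip()})
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def load_input_bundle(
    *,
    circ_expr: str | Path,
    mrna_expr: str | Path,
    annotation: str | Path,
    circ_sites: str | Path,
    mrna_sites: str | Path,
    circ_lengths: str | Path,
    mirna_expr: str | Path | None = None,
    mirna_annotation: str | Path | None = None,
    mirna_signature: str | Path | None = None,
    validated: str | Path | None = None,
) -> InputBundle:
    """Load and cross-validate every input file into one bundle.

    Site-table rows whose target has no expression row are dropped with a
    logged count; annotation samples must exist in both the circRNA and mRNA
    matrices (the miRNA matrix may carry its own sample set).
    """
    circ = read_expression_csv(circ_expr, "circRNA")
    mrna = read_expression_csv(mrna_expr, "mRNA")
    annot = read_annotation_csv(annotation)
    if mirna_expr is None and mirna_signature is None:
        raise MissingColumnError(
            "either a miRNA expression matrix or a miRNA signature is required"
        )
    mir = read_expression_csv(mirna_expr, "miRNA") if mirna_expr else None
    mir_annot = read_annotation_csv(mirna_annotation) if mirna_annotation else None
    sig = read_signature_csv(mirna_signature) if mirna_signature else None

    for mat, name in ((circ, circ_expr), (mrna, mrna_expr)):
        missing = sorted(set(annot.samples) - set(mat.sample_ids))
        if missing:
            raise ShapeError(
                f"{name}: annotation samples missing from {mat.rna_type} "
                f"matrix: {missing}"
            )

    csites = read_site_csv(circ_sites)
    msites = read_site_csv(mrna_sites)
    if not csites.empty and csites["target_type"].iloc[0] != "circRNA":
        raise ShapeError(f"{circ_sites}: expected circRNA targets")
    if not msites.empty and msites["target_type"].iloc[0] != "mRNA":
        raise ShapeError(f"{mrna_sites}: expected mRNA targets")

    dropped: dict[str, int] = {}
    keep = csites["target_id"].isin(circ.feature_ids)
    dropped["circ_sites_without_expression"] = int((~keep).sum())
    csites = csites[keep].reset_index(drop=True)
    keep = msites["target_id"].isin(mrna.feature_ids)
    dropped["mrna_sites_without_expression"] = int((~keep).sum())
    msites = msites[keep].reset_index(drop=True)
    for key, n in dropped.items():
        if n:
            logger.info("dropped %d site rows: %s", n, key)

    lengths = read_lengths_csv(circ_lengths)
    missing_len = sorted(set(csites["target_id"]) - set(lengths))
    if missing_len:
        logger.warning(
            "dropping %d circRNA targets without length entries: %s",
            len(missing_len),
            missing_len[:5],
        )
        keep = ~csites["target_id"].isin(missing_len)
        dropped["circ_sites_without_length"] = int((~keep).sum())
        csites = csites[keep].reset_index(drop=True)

    val = read_validated_csv(validated) if validated else None

    logger.info(
        "loaded bundle: %d circRNAs, %d mRNAs, %d miRNAs",
        len(circ.feature_ids),
        len(mrna.feature_ids),
        len(mir.feature_ids) if mir is not None else len(sig.values),
    )
    return InputBundle(
        circ_expr=circ,
        mrna_expr=mrna,
        annotation=annot,
        circ_sites=csites,
        mrna_sites=msites,
        circ_lengths=lengths,
        mirna_expr=mir,
        mirna_signature=sig,
        mirna_annotation=mir_annot,
        validated=val,
        dropped_site_targets=dropped,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_score_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the 16-column score matrix sorted by global rank."""
    missing = [c for c in SCORE_MATRIX_COLUMNS if c not in matrix.columns]
    if missing:
        raise MissingColumnError(f"score matrix lacks columns {missing}")
    if matrix.empty:
        logger.warning("writing empty score matrix to %s", path)
    out = matrix[SCORE_MATRIX_COLUMNS].sort_values("rank_global")
    out.to_csv(path, index=False)


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "mirna_id": str,
            "circ_id": str,
            "condition": str,
            "mrna_target_list": str,
        },
    )
    missing = [c for c in SCORE_MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: score matrix lacks columns {missing}")
    return df[SCORE_MATRIX_COLUMNS]


def write_expression_csv(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.data.to_csv(path, index_label="feature_id")


def write_annotation_csv(annot: SampleAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"samples": annot.samples, "conditions": [annot.sample_to_condition[s] for s in annot.samples]}
    ).to_csv(path, index=False)


def write_site_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[SITE_TABLE_COLUMNS].to_csv(path, index=False)


def write_lengths_csv(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"circ_id": list(lengths), "length": [lengths[c] for c in lengths]}
    ).to_csv(path, index=False)


def write_validated_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_signature_csv(sig: MirnaSignature, path: str | Path) -> None:
    pd.DataFrame(
        {"mirna_id": list(sig.values), "value": list(sig.values.values())}
    ).to_csv(path, index=False)
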