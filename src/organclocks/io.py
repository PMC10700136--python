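"""Readers and writers for the pipeline's file formats.

Expression comes in as GCT 1.2 (two header lines, then NAME/Description +
samples) or plain TSV with the gene id in the first column; the
sample->tissue map is a two-column TSV. Plasma abundances are CSV/TSV with
subjects in rows and raw positive RFU-like values that are log10
transformed on load. Metadata columns are matched case-insensitively
(Age, Sex, Cohort, HealthStatus) and sex F/M is coerced to 1/0 with a log
entry. All tabular outputs are TSV with a header; floats are written with
repr-level precision so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockModel, CohortData
from .enrichment import ExpressionMatrix, ProteinSetCatalog

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix (genes x samples, Description column dropped)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"{path}: not a GCT 1.2 file (got {version!r})")
        n_genes, n_samples = map(int, fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=[c for c in ("Description", "description") if c in df.columns])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path}: header promises {n_genes}x{n_samples}, found {df.shape}"
        )
    return df


def write_gct(values: pd.DataFrame, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        out = values.copy()
        out.insert(0, "Description", "na")
        out.index.name = "NAME"
        out.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_expression(matrix_path, tissue_map_path) -> ExpressionMatrix:
    """Load expression (GCT or TSV) plus the 2-column sample->tissue TSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".gct":
        values = read_gct(matrix_path)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    tmap = pd.read_csv(tissue_map_path, sep="\t")
    if tmap.shape[1] < 2:
        raise ValueError("tissue map must have sample and tissue columns")
    mapping = dict(zip(tmap.iloc[:, 0].astype(str), tmap.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values, mapping)


def write_tissue_map(sample_to_tissue: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(sample_to_tissue), "tissue": list(sample_to_tissue.values())}
    ).to_csv(path, sep="\t", index=False)


_META_ALIASES = {
    "age": "age",
    "sex": "sex",
    "cohort": "cohort",
    "healthstatus": "healthy",
    "healthy": "healthy",
}


def read_metadata(path) -> pd.DataFrame:
    """Metadata CSV/TSV with case-insensitive standard columns."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    renames = {}
    for col in df.columns:
        key = col.strip().lower().replace("_", "")
        if key in _META_ALIASES:
            renames[col] = _META_ALIASES[key]
    df = df.rename(columns=renames)
    if "sex" in df.columns and df["sex"].dtype == object:
        coded = df["sex"].str.upper().map({"F": 1, "M": 0})
        if coded.isna().any():
            raise ValueError("sex column has values other than F/M or 1/0")
        logger.info("coerced sex F/M to 1/0")
        df["sex"] = coded
    return df


def read_proteins(path, log10_transform: bool = True) -> pd.DataFrame:
    """Subject-by-probe abundance matrix; raw positive values are log10ed."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if log10_transform:
        if (df.to_numpy() <= 0).any():
            raise ValueError("raw abundances must be positive for log10 transform")
        df = np.log10(df)
    return df


def write_proteins_raw(log10_values: pd.DataFrame, path) -> None:
    """Write a cohort's protein matrix back on the raw (10**x) scale."""
    (10.0 ** log10_values).to_csv(path, float_format=FLOAT_FORMAT)


def read_cohort(proteins_path, meta_path, log10_transform: bool = True) -> CohortData:
    proteins = read_proteins(proteins_path, log10_transform)
    meta = read_metadata(meta_path)
    meta.index = meta.index.astype(proteins.index.dtype, errors="ignore")
    common = proteins.index.intersection(meta.index)
    if len(common) < len(proteins):
        logger.warning(
            "%d subjects lack metadata and were dropped", len(proteins) - len(common)
        )
    return CohortData(proteins.loc[common], meta.loc[common])


def write_catalog(catalog: ProteinSetCatalog, path) -> None:
    Path(path).write_text(json.dumps(catalog.to_dict(), indent=1, sort_keys=True))


def read_catalog(path) -> ProteinSetCatalog:
    return ProteinSetCatalog.from_dict(json.loads(Path(path).read_text()))


def write_model(model: ClockModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_model(path) -> ClockModel:
    return ClockModel.from_json(Path(path).read_text())


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
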