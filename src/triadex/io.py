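"""Readers and writers for the pipeline's plain-text table dialects.

All formats are diff-able text: counts as TSV (gene rows, ``gene_id``
first column), sample sheets / phenotypes / CT tables as CSV, annotation
maps as two-column TSV or GMT.  Readers validate structure and report
offending line numbers; every writer/reader pair round-trips.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, Mapping, Set, Union

import pandas as pd

PathLike = Union[str, Path]


def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: PathLike) -> pd.DataFrame:
    """Read a gene × sample counts TSV, validating integer non-negativity."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        line = int(df.index[df["gene_id"] == dup][1]) + 2
        raise ValueError(f"{path}:{line}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in header")
    df = df.set_index("gene_id")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            line = int(df.index.get_indexer([df.index[bad][0]])[0]) + 2
            raise ValueError(
                f"{path}:{line}: column {col!r} has a non-integer or "
                "negative count"
            )
    return df.astype("int64")


def write_sample_sheet(samples: pd.DataFrame, path: PathLike) -> None:
    samples.to_csv(path, index=False)


SAMPLE_COLUMNS = ["sample_id", "genotype", "role", "time_point", "replicate"]
ROLES = {"female_parent", "male_parent", "hybrid"}


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "genotype": str, "time_point": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"{path}: unknown roles {sorted(bad_roles)}")
    return df


def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id",
                       dtype={"planted_class": str})


def write_phenotypes(pheno: pd.DataFrame, path: PathLike) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"genotype": str, "trait": str, "time_point": str})
    required = {"genotype", "trait", "time_point", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df


def write_annotation_tsv(annotation: Mapping[str, Iterable[str]], path: PathLike) -> None:
    """Two-column (gene_id, term_id) TSV, sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for term in sorted(annotation):
            for gene in sorted(annotation[term]):
                fh.write(f"{gene}\t{term}\n")


def read_annotation_tsv(path: PathLike) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "term_id"]:
            raise ValueError(f"{path}:1: expected header 'gene_id\\tterm_id'")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{path}:{lineno}: malformed annotation row")
            gene, term = parts
            out.setdefault(term, set()).add(gene)
    return out


def write_gmt(annotation: Mapping[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            genes = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def read_gmt(path: PathLike, min_term: int = 1) -> Dict[str, Set[str]]:
    """Read a GMT file (term, description, genes...); terms below
    ``min_term`` genes are skipped with a warning."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, "
                                 "description and >= 1 gene")
            term, genes = parts[0], [g for g in parts[2:] if g]
            if len(genes) < min_term:
                warnings.warn(f"{path}:{lineno}: term {term!r} has "
                              f"{len(genes)} gene(s) < min_term={min_term}; skipped")
                continue
            out[term] = set(genes)
    return out


def write_ct(ct: pd.DataFrame, path: PathLike) -> None:
    ct.to_csv(path, index=False)


def read_ct(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "genotype": str, "gene": str})
    required = {"sample_id", "genotype", "gene", "replicate", "CT"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CT table missing columns {sorted(missing)}")
    return df


def write_de_table(de: pd.DataFrame, path: PathLike, float_format: str = "%.6g") -> None:
    de.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def write_table(df: pd.DataFrame, path: PathLike, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
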