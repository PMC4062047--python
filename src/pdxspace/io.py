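"""Readers and writers for the pipeline's file formats.

All tables are tab-delimited with a header row; matrices have features
(genes or probes) in rows and samples in columns. GCT 1.2 is accepted
as an alternative matrix format. Gene sets use GMT lines
(name, description, members...); sample annotations use a controlled
vocabulary for the sample class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pdxspace.synthdata import GeneSignature

VALID_CLASSES = ("primary", "pdx", "cell_line")


def _check_header_duplicates(path, header_line: str) -> None:
    cols = header_line.rstrip("\n").split("\t")[1:]
    seen: set = set()
    dupes = [c for c in cols if c in seen or seen.add(c)]
    if dupes:
        raise ValueError(f"{path}: duplicated sample ids {sorted(set(dupes))[:5]}")


def read_matrix(path) -> pd.DataFrame:
    """Read a genes-x-samples matrix from TSV or GCT (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"{path}: unsupported GCT version line {version!r}")
            fh.readline()  # dimensions line (validated against the body below)
            _check_header_duplicates(path, fh.readline())
            fh.seek(0)
            fh.readline()
            fh.readline()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
    else:
        with open(path) as fh:
            _check_header_duplicates(path, fh.readline())
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated feature ids {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample ids {dup[:5]}")
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        raise ValueError(f"{path}: {n} missing values in the matrix")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a genes-x-samples matrix as TSV (genes in rows)."""
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature")


def read_calls(path) -> pd.DataFrame:
    """Read a binary call matrix, checking that every value is 0/1."""
    df = read_matrix(path)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: call matrix contains non-binary values")
    return df.astype(np.int8)


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation table (sample, class[, tissue, ...]).

    The ``class`` column is validated against the controlled
    vocabulary ``primary | pdx | cell_line``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "class" not in df.columns:
        raise ValueError(f"{path}: annotation needs a 'class' column")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample ids {dup[:5]}")
    bad = df.index[~df["class"].isin(VALID_CLASSES)]
    if len(bad) > 0:
        lines = [df.index.get_loc(b) + 2 for b in bad[:5]]
        raise ValueError(
            f"{path}: unknown class labels at lines {lines} "
            f"(allowed: {', '.join(VALID_CLASSES)})"
        )
    return df


def read_probe_map(path) -> pd.Series:
    """Two-column TSV (probe, gene) -> Series probe -> gene."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe, gene)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].tolist()
        raise ValueError(f"{path}: probes mapped more than once: {dup[:5]}")
    return pd.Series(genes.to_numpy(), index=probes.to_numpy(), name="gene")


def read_gmt(path) -> dict:
    """GMT file -> {set name: set of gene ids}."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description and >= 1 gene"
                )
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = set(genes)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            members = sorted(set(genes))
            fh.write("\t".join([name, description, *members]) + "\n")


def read_signatures(path) -> tuple:
    """Read stromal and immune signatures from a GMT file.

    Expects sets named ``stromal`` and ``immune`` (case-insensitive).
    """
    sets = {k.lower(): v for k, v in read_gmt(path).items()}
    try:
        return (
            GeneSignature("stromal", frozenset(sets["stromal"])),
            GeneSignature("immune", frozenset(sets["immune"])),
        )
    except KeyError as exc:
        raise ValueError(
            f"{path}: signature GMT must contain sets named 'stromal' and 'immune'"
        ) from exc


def write_rnk(ranked, path) -> None:
    """Write a ranked list as a 2-column RNK-style TSV."""
    pd.DataFrame({"gene": ranked.genes, "metric": ranked.metric}).to_csv(
        path, sep="\t", index=False
    )


def read_design(path) -> pd.DataFrame:
    """Passage design TSV: sample, patient, passage."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("patient", "passage"):
        if col not in df.columns:
            raise ValueError(f"{path}: design needs a {col!r} column")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
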