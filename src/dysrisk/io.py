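"""Readers and writers for count tables, metadata, questionnaire responses.

All tabular formats are plain TSV/CSV with a header row.  Count tables may be
oriented either way; orientation is auto-detected by matching identifiers
against sample metadata (or a taxonomy column), and can be forced.  A minimal
BIOM format v1 (JSON) reader is provided for count tables.
"""

from __future__ import annotations

import json
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .model import (
    CountTable,
    ResponseMatrix,
    SampleMetadata,
    ValidationError,
)
from .registry import ITEM_IDS

_TAXONOMY_COLS = ("taxonomy", "lineage", "Taxonomy", "Lineage")

#: Default value coding for questionnaire answers (case-insensitive keys).
DEFAULT_DIALECT: Mapping[str, int] = {
    "yes": 1, "no": 0, "y": 1, "n": 0,
    "true": 1, "false": 0, "1": 1, "0": 0,
}


def _read_table(path, **kw) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0, **kw)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited lineage string into rank -> name.

    Handles both Greengenes-style prefixed ranks (``p__Firmicutes``) and bare
    Silva-style name lists (kingdom;phylum;...), where the second field is the
    phylum.
    """
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    ranks = {}
    prefixes = {"k": "kingdom", "d": "kingdom", "p": "phylum", "c": "class",
                "o": "order", "f": "family", "g": "genus", "s": "species"}
    bare: list[str] = []
    for part in parts:
        if len(part) > 2 and part[1:3] == "__":
            rank = prefixes.get(part[0].lower())
            name = part[3:].strip()
            if rank and name:
                ranks[rank] = name
        else:
            bare.append(part)
    if not ranks and bare:
        order = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
        ranks = dict(zip(order, bare))
    return ranks


def phylum_of(lineage: str) -> str | None:
    return parse_lineage(lineage).get("phylum")


def load_count_table(
    path,
    taxonomy_path=None,
    *,
    orientation: str = "auto",
    metadata: SampleMetadata | None = None,
) -> CountTable:
    """Load a samples x taxa count table from TSV/CSV.

    Parameters
    ----------
    path
        Table with one id column (index) and a numeric body.  A column named
        ``taxonomy``/``lineage`` marks rows as taxa and is consumed as the
        taxonomy map.
    taxonomy_path
        Optional two-column companion table ``taxon_id<TAB>lineage``.
    orientation
        ``"samples"`` (rows are samples), ``"taxa"`` (rows are taxa) or
        ``"auto"``: use the taxonomy column if present, else match row ids
        against ``metadata`` sample ids, else assume rows are samples.
    """
    df = _read_table(path)
    taxonomy: dict[str, str] = {}
    tax_col = next((c for c in _TAXONOMY_COLS if c in df.columns), None)
    if tax_col is not None:
        taxonomy = {str(t): str(l) for t, l in df[tax_col].dropna().items()}
        df = df.drop(columns=[tax_col])
        if orientation == "auto":
            orientation = "taxa"
    if orientation == "auto":
        if metadata is not None:
            row_hits = len(set(map(str, df.index)) & set(metadata.sample_ids))
            col_hits = len(set(map(str, df.columns)) & set(metadata.sample_ids))
            orientation = "samples" if row_hits >= col_hits else "taxa"
        else:
            orientation = "samples"
    if orientation == "taxa":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")

    if taxonomy_path is not None:
        tdf = _read_table(taxonomy_path, header=None)
        if tdf.shape[1] >= 1:
            taxonomy.update({str(t): str(l) for t, l in tdf.iloc[:, 0].items()})

    table = CountTable(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        counts=df.to_numpy(),
        taxonomy=taxonomy,
    )
    if taxonomy and table.unclassified:
        warnings.warn(
            f"{len(table.unclassified)} taxa absent from taxonomy; flagged unclassified",
            stacklevel=2,
        )
    return table


def write_count_table(table: CountTable, path, taxonomy_path=None) -> None:
    """Write samples-as-rows TSV; taxonomy to a companion file if requested."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_frame().to_csv(path, sep=sep, index_label="sample_id")
    if taxonomy_path is not None and table.taxonomy:
        pd.Series(table.taxonomy).to_csv(
            taxonomy_path, sep="\t", header=False
        )


def load_biom(path) -> CountTable:
    """Read a BIOM format v1 (JSON) OTU/ASV table."""
    with open(path) as fh:
        doc = json.load(fh)
    shape = doc["shape"]  # rows = observations (taxa), cols = samples
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"])
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        lin = md.get("taxonomy")
        if lin:
            taxonomy[str(r["id"])] = (
                ";".join(lin) if isinstance(lin, (list, tuple)) else str(lin)
            )
    return CountTable(samples, taxa, mat.T, taxonomy)


def load_metadata(path, levels: tuple[str, str] = ("CD", "HC")) -> SampleMetadata:
    """Load sample metadata (sample_id, group) and validate group labels."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("metadata needs at least (sample_id, group) columns")
    cols = {c.lower(): c for c in df.columns}
    sid = cols.get("sample_id", df.columns[0])
    grp = cols.get("group", df.columns[1])
    if df[grp].isna().any():
        bad = df.loc[df[grp].isna(), sid].tolist()
        raise ValidationError(f"empty group label for samples {bad}")
    labels = sorted(df[grp].unique())
    if len(labels) > 2:
        raise ValidationError(
            f"more than two group labels without an explicit mapping: {labels}"
        )
    return SampleMetadata(
        sample_ids=df[sid].astype(str).tolist(),
        groups=df[grp].astype(str).tolist(),
        levels=levels,
    )


def write_metadata(meta: SampleMetadata, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta.to_frame().to_csv(path, sep=sep, index=False)


def load_responses(
    path,
    dialect: Mapping[str, int] | None = None,
    *,
    strict: bool = False,
    allow_missing: bool = False,
) -> ResponseMatrix:
    """Load a binary questionnaire table (subjects in rows, items in columns).

    Values are decoded through ``dialect`` (case-insensitive; defaults accept
    yes/no, y/n, true/false, 1/0).  With ``strict=True`` the columns must be
    exactly the canonical 15-item registry; they are reordered canonically.
    Missing cells raise unless ``allow_missing=True``, in which case they are
    masked explicitly.
    """
    dialect = {k.lower(): v for k, v in (dialect or DEFAULT_DIALECT).items()}
    df = _read_table(path, dtype=str)
    sample_ids = [str(s) for s in df.index]
    item_ids = [str(c) for c in df.columns]

    if strict:
        extra = sorted(set(item_ids) - set(ITEM_IDS))
        absent = sorted(set(ITEM_IDS) - set(item_ids))
        if extra or absent:
            raise ValidationError(
                f"strict mode: items not in registry {extra}, registry items missing {absent}"
            )
        df = df[list(ITEM_IDS)]
        item_ids = list(ITEM_IDS)

    values = np.zeros(df.shape, dtype=np.int8)
    missing = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip().lower() in ("", "na", "nan")
            ):
                if not allow_missing:
                    raise ValidationError(
                        f"missing answer at subject {sample_ids[i]!r}, "
                        f"item {item_ids[j]!r} (pass allow_missing=True to mask)"
                    )
                missing[i, j] = True
                continue
            key = str(cell).strip().lower()
            if key not in dialect:
                raise ValidationError(
                    f"uncodable value {cell!r} at subject {sample_ids[i]!r}, "
                    f"item {item_ids[j]!r}"
                )
            values[i, j] = dialect[key]
    return ResponseMatrix(sample_ids, item_ids, values, missing)


def write_responses(responses: ResponseMatrix, path, *, coding=("no", "yes")) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(
        np.where(responses.responses == 1, coding[1], coding[0]),
        index=responses.sample_ids,
        columns=responses.item_ids,
    ).astype(object)
    df[pd.DataFrame(responses.missing, index=df.index, columns=df.columns)] = ""
    df.to_csv(path, sep=sep, index_label="sample_id")


DEFAULT_CONFIG: dict = {
    "outcome": {"reference_group": "HC", "quantile": 0.25, "quantile_method": "linear"},
    "optimizer": {
        "max_weight": 4,
        "objective": "auc",
        "search": "auto",
        "restarts": 25,
        "seed": 0,
        "exhaustive_item_limit": 7,
    },
    "beta": {"n_permutations": 999, "seed": 0, "sqrt_jsd": False},
}


def load_config(path=None) -> dict:
    """Load a YAML/JSON run configuration merged over package defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg
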