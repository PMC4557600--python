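"""Plain-text file formats for every pipeline artifact.

Everything is TSV with a canonical column order and '.' decimals; gene
sets use GMT; networks are exported as GraphML and SIF.  Lines starting
with ``#`` are comments (used to stamp artifacts with the producing
config hash and seed) and are skipped by every reader.  Writing then
reading any table reproduces it exactly.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS, ExpressionMatrix, SampleDesign
from .enrich import ENRICHMENT_COLUMNS, Pathway, PathwayCollection
from .network import CombinedNetwork, InteractionDB, NetworkResults
from .qpcr import CT_COLUMNS, CtTable
from .simulate import SyntheticTruth


class FormatError(ValueError):
    """Malformed input file; the message carries the file and line number."""


def _read_tsv(path) -> tuple[pd.DataFrame, list[int]]:
    """Read a TSV skipping comment lines; return (df, 1-based data line numbers)."""
    path = Path(path)
    kept, line_nos = [], []
    with open(path) as fh:
        for no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            kept.append(line)
            line_nos.append(no)
    if not kept:
        raise FormatError(f"{path}: no data lines")
    df = pd.read_csv(_io.StringIO("".join(kept)), sep="\t", dtype=str)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}:{line_nos[0]}: duplicate column header {dup!r}")
    return df, line_nos[1:]  # first kept line is the header


def _to_float(df: pd.DataFrame, columns, path, line_nos) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}:{line_nos[i]}: non-numeric value {out[col].iloc[i]!r} "
                f"in column {col!r}"
            )
        # python float(): correctly-rounded parsing, so repr round-trips exactly
        out[col] = out[col].map(lambda v: float(v) if pd.notna(v) else np.nan)
    return out


def _write_lines(path, header_comment: str | None, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(text)


# -- expression matrices ----------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path, comment: str | None = None) -> None:
    df = matrix.values.copy()
    df.insert(0, "feature_id", df.index)
    _write_lines(path, comment, df.to_csv(sep="\t", index=False))


def read_expression(path, kind: str = "mRNA") -> ExpressionMatrix:
    df, line_nos = _read_tsv(path)
    if df.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column must be 'feature_id'")
    dup = df["feature_id"].duplicated()
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        raise FormatError(
            f"{path}:{line_nos[i]}: duplicate feature id {df['feature_id'].iloc[i]!r}"
        )
    sample_cols = list(df.columns[1:])
    df = _to_float(df, sample_cols, path, line_nos)
    values = df.set_index("feature_id")[sample_cols]
    values.index.name = None
    return ExpressionMatrix(values, kind)


# -- sample sheet -----------------------------------------------------------

def write_sample_sheet(design: SampleDesign, path, comment: str | None = None) -> None:
    _write_lines(path, comment, design.table[DESIGN_COLUMNS].to_csv(sep="\t", index=False))


def read_sample_sheet(path) -> SampleDesign:
    df, line_nos = _read_tsv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    df = _to_float(df, ["bio_rep", "tech_rep"], path, line_nos)
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    return SampleDesign(df[DESIGN_COLUMNS])


# -- interaction DB ---------------------------------------------------------

def write_interaction_db(db: InteractionDB, path, comment: str | None = None) -> None:
    _write_lines(path, comment, db.records.to_csv(sep="\t", index=False))


def read_interaction_db(path) -> InteractionDB:
    df, _ = _read_tsv(path)
    return InteractionDB(df)


# -- Ct tables --------------------------------------------------------------

def write_ct_table(table: CtTable, path, comment: str | None = None) -> None:
    ref = "reference_targets: " + ",".join(table.reference_targets)
    head = f"{comment}\n# {ref}" if comment else ref
    _write_lines(path, head, table.records[CT_COLUMNS].to_csv(sep="\t", index=False))


def read_ct_table(path) -> CtTable:
    refs: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "reference_targets:" in line:
                refs = [
                    t.strip()
                    for t in line.split("reference_targets:", 1)[1].split(",")
                    if t.strip()
                ]
    df, line_nos = _read_tsv(path)
    df = _to_float(df, ["replicate", "ct"], path, line_nos)
    df["replicate"] = df["replicate"].astype(int)
    return CtTable(df[CT_COLUMNS], reference_targets=refs)


# -- DE tables --------------------------------------------------------------

DE_COLUMNS = ["feature_id", "log2fc", "fc", "p", "fdr", "significant"]


def write_de_table(table: pd.DataFrame, path, comment: str | None = None) -> None:
    table = table.table if hasattr(table, "table") else table
    out = table.reset_index()
    if "feature_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "feature_id"})
    _write_lines(path, comment, out[DE_COLUMNS].to_csv(sep="\t", index=False))


def read_de_table(path) -> pd.DataFrame:
    df, line_nos = _read_tsv(path)
    df = _to_float(df, ["log2fc", "fc", "p", "fdr"], path, line_nos)
    df["significant"] = df["significant"] == "True"
    return df.set_index("feature_id")


# -- enrichment tables ------------------------------------------------------

def write_enrichment(table: pd.DataFrame, path, comment: str | None = None) -> None:
    table = table.table if hasattr(table, "table") else table
    out = table.copy()
    out["hit_genes"] = out["hit_genes"].map(
        lambda g: ",".join(g) if not isinstance(g, str) else g
    )
    _write_lines(path, comment, out[ENRICHMENT_COLUMNS].to_csv(sep="\t", index=False))


def read_enrichment(path) -> pd.DataFrame:
    df, line_nos = _read_tsv(path)
    df = _to_float(df, ["n_pathway", "n_hits", "p", "fdr"], path, line_nos)
    df["n_pathway"] = df["n_pathway"].astype(int)
    df["n_hits"] = df["n_hits"].astype(int)
    df["hit_genes"] = df["hit_genes"].fillna("").map(
        lambda s: [g for g in s.split(",") if g]
    )
    return df[ENRICHMENT_COLUMNS]


# -- GMT gene sets ----------------------------------------------------------

def write_gmt(collection: PathwayCollection, path) -> None:
    """GMT: id <tab> 'source|name' <tab> genes...; source tag per the report key."""
    lines = []
    for pw in collection.pathways:
        genes = "\t".join(sorted(pw.genes))
        lines.append(f"{pw.pathway_id}\t{pw.source}|{pw.name}\t{genes}\n")
    _write_lines(path, None, "".join(lines))


def read_gmt(path, universe=None) -> PathwayCollection:
    pathways = []
    with open(path) as fh:
        for no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{no}: GMT line needs id, description, genes")
            pid, desc, genes = parts[0], parts[1], parts[2:]
            source, _, name = desc.partition("|")
            pathways.append(Pathway(pid, name or pid, source, frozenset(genes)))
    return PathwayCollection(pathways, frozenset(universe) if universe else frozenset())


# -- networks ---------------------------------------------------------------

NETWORK_EDGE_COLUMNS = [
    "cell_line", "miRNA_id", "gene_id", "r",
    "miRNA_direction", "gene_direction", "validated",
]


def write_edge_table(net, path, comment: str | None = None) -> None:
    edges = net.edges if hasattr(net, "edges") else net
    _write_lines(path, comment, edges[NETWORK_EDGE_COLUMNS].to_csv(sep="\t", index=False))


def write_sif(net, path) -> None:
    """SIF: miRNA <tab> represses <tab> gene, one edge per line."""
    edges = net.edges if hasattr(net, "edges") else net
    lines = [
        f"{row.miRNA_id}\trepresses\t{row.gene_id}\n"
        for row in edges.itertuples(index=False)
    ]
    _write_lines(path, None, "".join(lines))


def write_graphml(net: NetworkResults | CombinedNetwork, path) -> None:
    g = net.to_networkx()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)


# -- JSON artifacts ---------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
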