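"""Readers and writers for the pipeline's external formats.

Tables are TSV (the transcriptome-matrix convention); gene sets are GMT;
networks go out as GraphML (full attributes) or SIF (interaction tags
``pos``/``neg``).  Readers validate and raise :class:`FormatError` naming the
offending row/column rather than silently coercing malformed input.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable, LesionRecord, SegmentProfile

__all__ = [
    "FormatError",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_cohort_table",
    "write_cohort_table",
    "read_lesion_records",
    "write_lesion_records",
    "read_module_assignment",
    "write_module_assignment",
]


class FormatError(ValueError):
    """Malformed external file."""


# ---------------------------------------------------------------------------
# Expression matrices and sample sheets


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 matrix from TSV (first column = gene ID)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicated gene IDs: {dup}")
    try:
        body = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value at gene {gene!r}, column {col!r}"
                ) from None
        raise
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().values)[0]
        raise FormatError(
            f"{path}: missing value at gene {body.index[r]!r}, "
            f"column {body.columns[c]!r}"
        )
    body.index.name = "gene"
    return body


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV at 6 significant digits."""
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample, condition) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: sample sheet needs sample and condition columns")
    samples, conditions = df.iloc[:, 0], df.iloc[:, 1]
    dup = samples[samples.duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicated sample IDs: {dup}")
    return pd.Series(
        conditions.values, index=pd.Index(samples, name="sample"), name="condition"
    )


def write_sample_sheet(sheet: pd.Series, path: str | Path) -> None:
    sheet.rename("condition").to_csv(path, sep="\t", index_label="sample")


def read_module_assignment(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return pd.Series(
        df.iloc[:, 1].astype(int).values,
        index=pd.Index(df.iloc[:, 0], name="gene"),
        name="module",
    )


def write_module_assignment(modules: pd.Series, path: str | Path) -> None:
    modules.rename("module").to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass(frozen=True)
class GeneSetCollection:
    """Annotation terms with member gene sets (GMT semantics)."""

    term_ids: tuple[str, ...]
    term_names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.term_ids)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, then member genes, tab-separated.

    Duplicate member genes within a line are de-duplicated; duplicate term IDs
    across lines are an error.
    """
    path = Path(path)
    term_ids: list[str] = []
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in members:
                raise FormatError(f"{path}: line {lineno}: duplicate term ID {term!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: term {term!r} has no members")
            term_ids.append(term)
            names[term] = desc
            members[term] = frozenset(genes)
    if not term_ids:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(tuple(term_ids), names, members)


def write_gmt(gmt: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in gmt.term_ids:
            genes = "\t".join(sorted(gmt.members[term]))
            fh.write(f"{term}\t{gmt.term_names[term]}\t{genes}\n")


# ---------------------------------------------------------------------------
# Networks


def write_network(network: nx.DiGraph, path: str | Path, dialect: str = "graphml") -> None:
    """Write a signed gene network as GraphML or SIF.

    GraphML preserves node/edge attributes (module label, sign, weight); SIF
    writes tab-separated ``source  pos|neg  target`` triples, which keeps node
    IDs containing spaces intact.
    """
    if not nx.is_directed_acyclic_graph(network):
        raise ValueError("network must be acyclic")
    path = Path(path)
    if dialect == "graphml":
        nx.write_graphml(network, path)
    elif dialect == "sif":
        with open(path, "w") as fh:
            for u, v, data in network.edges(data=True):
                tag = "pos" if data.get("sign", "+") == "+" else "neg"
                fh.write(f"{u}\t{tag}\t{v}\n")
            for node in nx.isolates(network):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_network(path: str | Path, dialect: str = "graphml") -> nx.DiGraph:
    path = Path(path)
    if dialect == "graphml":
        g = nx.read_graphml(path)
        return nx.DiGraph(g)
    if dialect == "sif":
        g = nx.DiGraph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0]:
                    g.add_node(fields[0])
                elif len(fields) == 3:
                    src, tag, dst = fields
                    if tag not in ("pos", "neg"):
                        raise FormatError(
                            f"{path}: line {lineno}: unknown interaction {tag!r}"
                        )
                    g.add_edge(src, dst, sign="+" if tag == "pos" else "-", weight=1.0)
                elif any(fields):
                    raise FormatError(f"{path}: line {lineno}: expected 1 or 3 fields")
        return g
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Cohort tables and lesion profiles


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read a TSV with columns group, ad_pos, ad_neg."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need columns group, ad_pos, ad_neg")
    try:
        pos = df.iloc[:, 1].astype(int)
        neg = df.iloc[:, 2].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: counts must be integers ({exc})") from exc
    return CohortTable(tuple(df.iloc[:, 0]), tuple(pos), tuple(neg))


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    pd.DataFrame(
        {"group": table.groups, "ad_pos": table.ad_pos, "ad_neg": table.ad_neg}
    ).to_csv(path, sep="\t", index=False)


def write_lesion_records(records: list[LesionRecord], path: str | Path) -> None:
    """Long-format TSV: mouse, group, segment, position, diameter, reference."""
    rows = []
    for rec in records:
        for seg in rec.segments:
            positions = np.arange(seg.diameters.size) * seg.spacing
            for pos, d in zip(positions, seg.diameters):
                rows.append(
                    (rec.mouse_id, rec.group, seg.name, pos, d, seg.reference_diameter)
                )
    pd.DataFrame(
        rows, columns=["mouse", "group", "segment", "position", "diameter", "reference"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_lesion_records(path: str | Path) -> list[LesionRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"mouse", "group", "segment", "position", "diameter", "reference"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    records = []
    for mouse, mdf in df.groupby("mouse", sort=False):
        segments = []
        for seg, sdf in mdf.groupby("segment", sort=False):
            sdf = sdf.sort_values("position")
            pos = sdf["position"].to_numpy()
            spacing = float(pos[1] - pos[0]) if pos.size > 1 else 1.0
            refs = sdf["reference"].unique()
            if refs.size != 1:
                raise FormatError(
                    f"{path}: mouse {mouse!r} segment {seg!r}: "
                    "inconsistent reference diameters"
                )
            segments.append(
                SegmentProfile(
                    name=str(seg),
                    reference_diameter=float(refs[0]),
                    spacing=spacing,
                    diameters=sdf["diameter"].to_numpy(dtype=float),
                )
            )
        records.append(
            LesionRecord(
                mouse_id=str(mouse), group=str(mdf["group"].iloc[0]), segments=segments
            )
        )
    return records
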