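"""Readers and writers for every external representation the pipeline touches.

Formats:

* count tables — TSV (orientation auto-detected from the header keyword,
  ``#SampleID`` meaning samples-as-rows) and minimal BIOM-JSON (dense or
  sparse matrix, observations x samples as deposited by QIIME-era tools);
* sample metadata, taxonomy and phenotype TSVs;
* co-abundance networks — SIF and GraphML (Cytoscape-loadable) and a plain
  edge TSV;
* generic results tables (TSV, stable column order, 6 significant digits).

Parsing is strict: malformed cells raise errors naming the offending
row/column, duplicate identifiers are rejected, and any record that is
dropped or modified produces a log entry. Proportion tables are rejected
here — counts are the single source of scale, normalisation belongs to the
CLR layer.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    CountTable,
    PhenotypeTable,
    SampleFrame,
    TaxonomyTable,
    ValidationError,
    DEFAULT_GROUPS,
    DEFAULT_TIMEPOINTS,
)

if TYPE_CHECKING:  # pragma: no cover
    from .network import CoabundanceNetwork

logger = logging.getLogger("rumenet")

_SAMPLE_KEYWORDS = ("sampleid", "sample_id", "sample")
_TAXON_KEYWORDS = ("otuid", "otu_id", "otu", "asvid", "asv_id", "asv",
                   "featureid", "feature_id", "taxon", "taxon_id")


def _read_tsv_lines(path) -> tuple[list[str], list[list[str]]]:
    """Split a TSV into (header cells, data rows), honouring '#' comments.

    A '#'-prefixed line containing tabs immediately before the data block is
    treated as the header (the BIOM/QIIME convention, e.g. ``#SampleID`` or
    ``#OTU ID``); tab-free '#' lines are comments and ignored.
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "\t" in line and not rows:
                    header = line.lstrip("#").split("\t")
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ValidationError(f"{path}: no samples (empty file)")
    return header, rows


def _detect_orientation(first_header_cell: str) -> str | None:
    key = first_header_cell.strip().lstrip("#").replace(" ", "").lower()
    if any(k in key for k in _SAMPLE_KEYWORDS):
        return "samples"
    if any(k in key for k in _TAXON_KEYWORDS):
        return "taxa"
    return None


def read_count_table(
    path,
    format: str = "tsv",
    orientation: str = "auto",
    drop_empty: bool = True,
) -> CountTable:
    """Read a count table from TSV or BIOM-JSON into a validated CountTable.

    ``orientation`` applies to TSV input: ``"samples"`` (rows are samples),
    ``"taxa"`` (rows are ASVs) or ``"auto"`` to detect from the header
    keyword. The result is always normalised to samples x ASVs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom-json":
        return _read_biom_json(path, drop_empty=drop_empty)
    if format != "tsv":
        raise ValueError(f"unknown count table format {format!r}")

    header, rows = _read_tsv_lines(path)
    if not rows:
        raise ValidationError(f"{path}: no samples (header only)")
    if orientation == "auto":
        detected = _detect_orientation(header[0])
        if detected is None:
            raise ValidationError(
                f"{path}: cannot detect orientation from header cell "
                f"{header[0]!r}; pass orientation='samples' or 'taxa'"
            )
        orientation = detected

    col_ids = [c.strip() for c in header[1:]]
    row_ids, matrix = [], []
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValidationError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )
        row_ids.append(row[0].strip())
        vals = []
        for j, cell in enumerate(row[1:], start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: malformed numeric cell at row {row[0]!r}, "
                    f"column {header[j]!r}: {cell!r}"
                ) from None
        matrix.append(vals)
    df = pd.DataFrame(matrix, index=row_ids, columns=col_ids)
    if orientation == "taxa":
        df = df.T
    return CountTable.from_frame(df, drop_empty=drop_empty)


def _read_biom_json(path: Path, drop_empty: bool = True) -> CountTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        obs_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        matrix_type = doc.get("matrix_type", "dense")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: not a minimal BIOM-JSON table ({exc})") from None
    mat = np.zeros((len(obs_ids), len(sample_ids)))
    if matrix_type == "dense":
        mat[:] = np.asarray(data, dtype=float)
    elif matrix_type == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = v
    else:
        raise ValidationError(f"{path}: unsupported matrix_type {matrix_type!r}")
    # BIOM stores observations x samples; normalise to samples x ASVs
    df = pd.DataFrame(mat.T, index=sample_ids, columns=obs_ids)
    return CountTable.from_frame(df, drop_empty=drop_empty)


def write_count_table(t: CountTable, path, orientation: str = "samples") -> None:
    """Write a count table as TSV with a ``#SampleID`` / ``#ASV_ID`` header."""
    df = t.data if orientation == "samples" else t.data.T
    label = "#SampleID" if orientation == "samples" else "#ASV_ID"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(label + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            fh.write(str(idx) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_sample_frame(
    path,
    groups: Sequence[str] = DEFAULT_GROUPS,
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    label_map: Mapping[str, str] | None = None,
) -> SampleFrame:
    """Read per-sample metadata (sample_id, animal_id, group, timepoint, day)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header, rows = _read_tsv_lines(path)
    if not rows:
        raise ValidationError(f"{path}: no samples")
    header = [h.strip().lstrip("#") for h in header]
    if "sample_id" not in header:
        raise ValidationError(f"{path}: missing required column(s): ['sample_id']")
    df = pd.DataFrame(rows, columns=header).set_index("sample_id")
    return SampleFrame.from_frame(df, groups=groups, timepoints=timepoints,
                                  label_map=label_map)


def write_sample_frame(frame: SampleFrame, path) -> None:
    df = frame.data.reset_index(names="sample_id")
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV: asv_id plus rank columns or one lineage column.

    A single ``taxonomy``/``lineage`` column is split on ``;`` and rank
    prefixes like ``g__`` are stripped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header, rows = _read_tsv_lines(path)
    header = [h.strip().lstrip("#") for h in header]
    df = pd.DataFrame(rows, columns=header)
    id_col = header[0]
    df = df.set_index(id_col)
    lineage_col = next((c for c in ("taxonomy", "lineage", "Taxon") if c in df.columns), None)
    if lineage_col is not None:
        parsed = []
        for lin in df[lineage_col]:
            parts = [p.strip() for p in str(lin).split(";")]
            parts = [p.split("__", 1)[-1] if "__" in p else p for p in parts]
            parts = [p if p else np.nan for p in parts]
            parts = (parts + [np.nan] * len(RANKS))[: len(RANKS)]
            parsed.append(parts)
        df = pd.DataFrame(parsed, index=df.index, columns=list(RANKS))
    return TaxonomyTable.from_frame(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.data.reset_index(names="asv_id")
    df.to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> PhenotypeTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    if "animal_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column(s): ['animal_id']")
    return PhenotypeTable.from_frame(df.set_index("animal_id"))


def write_phenotype(pheno: PhenotypeTable, path) -> None:
    pheno.data.reset_index(names="animal_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(
    net: "CoabundanceNetwork",
    path,
    format: str = "edge-tsv",
    taxonomy: TaxonomyTable | None = None,
) -> None:
    """Export a co-abundance network as SIF, GraphML or edge TSV.

    SIF carries one ``A co_ab B`` line per edge (isolated nodes are not
    representable and are omitted); GraphML carries rho/p/q as edge
    attributes and, when a taxonomy is given, rank annotations as node
    attributes. All three load in Cytoscape.
    """
    if len(net.edges) == 0:
        logger.warning("writing empty network to %s", path)
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in net.edges.itertuples():
                fh.write(f"{e.source}\tco_ab\t{e.target}\n")
    elif format == "edge-tsv":
        net.edges[["source", "target", "rho", "p", "q"]].to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
    elif format == "graphml":
        _write_graphml(net, path, taxonomy)
    else:
        raise ValueError(f"unknown network format {format!r}")


def _write_graphml(net, path, taxonomy: TaxonomyTable | None) -> None:
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    keys = {}

    def key(name, for_, type_):
        kid = f"k{len(keys)}"
        el = ET.SubElement(root, f"{{{ns}}}key",
                           id=kid, attrib={"attr.name": name, "attr.type": type_,
                                           "for": for_})
        keys[(name, for_)] = kid
        return kid

    for attr in ("rho", "p", "q"):
        key(attr, "edge", "double")
    rank_keys = {}
    if taxonomy is not None:
        for rank in RANKS:
            rank_keys[rank] = key(rank, "node", "string")
    graph = ET.SubElement(root, f"{{{ns}}}graph", id="G", edgedefault="undirected")
    for node in net.node_ids:
        el = ET.SubElement(graph, f"{{{ns}}}node", id=str(node))
        if taxonomy is not None and node in taxonomy.data.index:
            for rank in RANKS:
                val = taxonomy.data.loc[node, rank]
                if not pd.isna(val):
                    d = ET.SubElement(el, f"{{{ns}}}data", key=rank_keys[rank])
                    d.text = str(val)
    for i, e in enumerate(net.edges.itertuples()):
        el = ET.SubElement(graph, f"{{{ns}}}edge", id=f"e{i}",
                           source=str(e.source), target=str(e.target))
        for attr in ("rho", "p", "q"):
            d = ET.SubElement(el, f"{{{ns}}}data", key=keys[(attr, "edge")])
            d.text = f"{getattr(e, attr):.12g}"
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def write_results_table(rows: Iterable[Mapping] | pd.DataFrame, path) -> None:
    """Write homogeneous result records as TSV.

    Column order follows the first record; floats are serialised with six
    significant digits. An empty result set yields a header-only file when
    the input is a DataFrame, or an empty file for an empty record list.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
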