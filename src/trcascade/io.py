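"""Readers and writers for the pipeline's delimited text formats.

Expression matrices, network edge lists, annotation maps and cascade
exports are all plain delimited text so that any spreadsheet or Unix tool
can inspect them.  Delimiters are auto-detected among comma, tab and
semicolon unless given explicitly.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .dataset import ExpressionDataset, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "read_expression",
    "write_expression",
    "read_network_edges",
    "read_annotations",
    "export_cascade",
    "read_cascade_table",
    "CASCADE_FORMATS",
]

_DELIMS = [",", "\t", ";"]


def _sniff_delim(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else None


# ----------------------------------------------------------------------
# expression matrices
# ----------------------------------------------------------------------

# default label parse: first number = time point; an optional second number
# introduced by 'r'/'rep'/'_'/'.'/'-' = replicate ("d0_r1", "T2.2", "day 4 rep 3")
_TIME_RE = re.compile(r"(\d+(?:\.\d+)?)")
_REP_RE = re.compile(r"[_.\-\s]+(?:r|rep|replicate)?[_\s]*(\d+)\s*$", re.IGNORECASE)


def _parse_label(label: str) -> tuple[float, int | None] | None:
    m = _TIME_RE.search(label)
    if m is None:
        return None
    time = float(m.group(1))
    rest = label[m.end():]
    rm = _REP_RE.search(rest)
    rep = int(rm.group(1)) if rm else None
    return time, rep


def _design_from_labels(labels: list[str], design_spec) -> pd.DataFrame:
    """Build a sample design from column labels.

    ``design_spec`` is one of:

    * ``"auto"`` — parse the first number in each label as the time point
      and a trailing ``r<k>``-style suffix as the replicate; if any label
      has no number, every column becomes its own time point in column
      order (the algorithm only needs the order of time points).
    * a regex string with a named group ``time`` and optionally ``rep``.
    * a mapping ``label -> (time, replicate)`` or a DataFrame indexed by
      label with ``time``/``replicate`` columns (sidecar table).
    """
    if isinstance(design_spec, pd.DataFrame):
        design_spec = {
            s: (row["time"], row.get("replicate", 0))
            for s, row in design_spec.iterrows()
        }
    if isinstance(design_spec, Mapping):
        parsed = []
        for lab in labels:
            if lab not in design_spec:
                raise ValueError(f"sample {lab!r} missing from design table")
            t, r = design_spec[lab]
            parsed.append((float(t), int(r)))
    elif design_spec == "auto" or isinstance(design_spec, str):
        if design_spec == "auto":
            raw = [_parse_label(lab) for lab in labels]
        else:
            rx = re.compile(design_spec)
            raw = []
            for lab in labels:
                m = rx.search(lab)
                if m is None:
                    raw.append(None)
                    continue
                rep = m.groupdict().get("rep")
                raw.append((float(m.group("time")), int(rep) if rep else None))
        if any(r is None for r in raw):
            # unparseable labels: rank time points by column order
            parsed = [(float(i), 0) for i in range(len(labels))]
        else:
            parsed = [(t, -1 if r is None else r) for t, r in raw]
            # unmarked replicates: number duplicates of a time point by order
            seen: dict[float, int] = {}
            fixed = []
            for t, r in parsed:
                if r < 0:
                    r = seen.get(t, 0)
                    seen[t] = r + 1
                fixed.append((t, r))
            parsed = fixed
    else:
        raise TypeError(f"unsupported design_spec: {design_spec!r}")

    times = sorted({t for t, _ in parsed})
    t_index = {t: i for i, t in enumerate(times)}
    design = pd.DataFrame(
        {
            "time": [t for t, _ in parsed],
            "time_index": [t_index[t] for t, _ in parsed],
            "replicate": [r for _, r in parsed],
        },
        index=pd.Index(labels, name="sample"),
    )
    # re-rank replicate numbers within each time point to 0..k-1
    design["replicate"] = (
        design.groupby("time_index")["replicate"].rank(method="first").astype(int) - 1
    )
    return design


def read_expression(
    path, design_spec="auto", sep: str | None = None
) -> ExpressionDataset:
    """Read a delimited gene x sample matrix into an :class:`ExpressionDataset`.

    The first column holds gene symbols, the header row holds sample
    labels.  Raises on duplicate genes, negative or non-numeric values and
    designs with fewer than two distinct time points.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file or missing header row")
    if sep is None:
        sep = _sniff_delim(first)
        if sep is None:
            raise ValueError(f"{path}: could not detect a delimiter in the header")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: header row has no sample columns")

    originals = [str(g) for g in df.index]
    normalized = [normalize_symbol(g) for g in originals]
    dupes = pd.Index(normalized)[pd.Index(normalized).duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicated gene row {dupes[0]!r}")
    df.index = pd.Index(normalized, name="gene")

    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        # float() parses correctly rounded, so written values round-trip
        # to full precision
        try:
            values[col] = [float(v) for v in df[col]]
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"{path}: non-numeric value at gene {bad!r}, column {col!r}"
            ) from None

    design = _design_from_labels(list(values.columns), design_spec)
    display = {n: o for n, o in zip(normalized, originals) if n != o}
    return ExpressionDataset(values, design, display)


def write_expression(ds: ExpressionDataset, path, sep: str = ",") -> None:
    """Write the matrix back out; round-trips the values to full precision."""
    out = ds.values.copy()
    out.index = [ds.display(g) for g in out.index]
    out.index.name = "gene"
    # repr() is the shortest exact representation, so values survive the
    # text round trip bit-for-bit
    out.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))


# ----------------------------------------------------------------------
# network edge lists
# ----------------------------------------------------------------------

def read_network_edges(path) -> list[tuple[str, str]]:
    """Read a two-column regulator -> target edge list.

    Duplicate edges collapse to one (first-seen order kept); self-edges
    are retained, since a TF may bind its own promoter.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    delim = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delim(line)
            fields = line.split(delim) if delim else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            edge = (normalize_symbol(fields[0]), normalize_symbol(fields[1]))
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    if not edges:
        logger.warning("%s: empty edge list", path)
    return edges


# ----------------------------------------------------------------------
# annotation maps
# ----------------------------------------------------------------------

class AnnotationMap:
    """Flat gene -> GO-term annotation map.

    ``term_to_genes`` maps a term id to the set of annotated (normalized)
    gene symbols; ``term_names`` carries an optional human-readable label.
    No ontology-graph propagation is performed; the map is taken as given.
    """

    def __init__(
        self,
        term_to_genes: Mapping[str, Iterable[str]],
        term_names: Mapping[str, str] | None = None,
    ):
        self.term_to_genes: dict[str, frozenset[str]] = {}
        self.term_names: dict[str, str] = dict(term_names or {})
        for term, genes in term_to_genes.items():
            gset = frozenset(normalize_symbol(g) for g in genes)
            if not gset:
                logger.warning("annotation term %s has no genes; dropped", term)
                continue
            self.term_to_genes[term] = gset

    def __len__(self) -> int:
        return len(self.term_to_genes)

    def __contains__(self, term: str) -> bool:
        return term in self.term_to_genes

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)

    def name(self, term: str) -> str:
        return self.term_names.get(term, term)


def read_annotations(path, format: str = "auto") -> AnnotationMap:
    """Read gene annotations from GMT or two-column (gene, term) text."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return AnnotationMap({})
    if format == "auto":
        delim = _sniff_delim(lines[0]) or "\t"
        n_fields = len(lines[0].split(delim))
        format = "gmt" if n_fields > 2 else "two-column"
    if format not in {"gmt", "two-column"}:
        raise ValueError(f"unknown annotation format {format!r}")

    term_to_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    delim = _sniff_delim(lines[0]) or "\t"
    if format == "gmt":
        for ln in lines:
            fields = [f.strip() for f in ln.split(delim)]
            if len(fields) < 2:
                raise ValueError(f"{path}: GMT line with < 2 fields: {ln!r}")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            term_to_genes.setdefault(term, set()).update(genes)
            if desc:
                term_names[term] = desc
    else:
        for lineno, ln in enumerate(lines, start=1):
            fields = [f.strip() for f in ln.split(delim)]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 fields (gene, term), got "
                    f"{len(fields)}"
                )
            gene, term = fields
            term_to_genes.setdefault(term, set()).add(gene)
    return AnnotationMap(term_to_genes, term_names)


# ----------------------------------------------------------------------
# cascade export
# ----------------------------------------------------------------------

CASCADE_FORMATS = ("edge-table", "sif", "graphml", "cytoscape-json")


def _cascade_graph(cascade) -> nx.DiGraph:
    g = nx.DiGraph()
    for stage, column in cascade.stages:
        for gene, r in column:
            g.add_node(gene, stage=int(stage), correlation=float(r))
    for src, s_stage, tgt, t_stage, kind in sorted(cascade.edges):
        g.add_edge(src, tgt, type=kind)
    for node in g.nodes:
        g.nodes[node]["indegree"] = g.in_degree(node)
        g.nodes[node]["outdegree"] = g.out_degree(node)
    return g


def export_cascade(cascade, path, format: str = "edge-table") -> None:
    """Write a cascade to disk.

    ``edge-table`` is the package's own round-trippable TSV (node rows
    followed by edge rows); ``sif``, ``graphml`` and ``cytoscape-json``
    are standard network-tool formats.  Node attributes carry stage index,
    template correlation and cascade in/out degree; edge attributes carry
    the type (``within`` or ``cross``).
    """
    path = Path(path)
    if format not in CASCADE_FORMATS:
        raise ValueError(
            f"unknown cascade format {format!r}; choose from {CASCADE_FORMATS}"
        )
    g = _cascade_graph(cascade)
    if format == "edge-table":
        with open(path, "w") as fh:
            fh.write("record\tgene\tstage\tcorrelation\tindegree\toutdegree\n")
            for stage, column in cascade.stages:
                for gene, r in column:
                    nd = g.nodes[gene]
                    fh.write(
                        f"node\t{gene}\t{stage}\t{r!r}\t"
                        f"{nd['indegree']}\t{nd['outdegree']}\n"
                    )
            fh.write("record\tsource\tsource_stage\ttarget\ttarget_stage\ttype\n")
            for src, s_stage, tgt, t_stage, kind in sorted(cascade.edges):
                fh.write(f"edge\t{src}\t{s_stage}\t{tgt}\t{t_stage}\t{kind}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for src, _, tgt, _, _ in sorted(cascade.edges):
                fh.write(f"{src}\tregulates\t{tgt}\n")
            for n in g.nodes:
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:  # cytoscape-json
        with open(path, "w") as fh:
            json.dump(nx.cytoscape_data(g), fh, indent=1)


def read_cascade_table(path):
    """Read an ``edge-table`` export back into a :class:`TemporalCascade`."""
    from .core import TemporalCascade

    stages: dict[int, list[tuple[str, float]]] = {}
    edges: set[tuple[str, int, str, int, str]] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "node":
                _, gene, stage, r = fields[:4]
                stages.setdefault(int(stage), []).append((gene, float(r)))
            elif fields[0] == "edge":
                _, src, s_stage, tgt, t_stage, kind = fields
                edges.add((src, int(s_stage), tgt, int(t_stage), kind))
    columns = [(s, stages[s]) for s in sorted(stages)]
    return TemporalCascade(stages=columns, edges=frozenset(edges))
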