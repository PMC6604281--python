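"""Processing of externally downloaded cohorts (GEO series matrices).

The healthy-vs-FA bone-marrow comparison (GEO accession GSE16334) is not
redistributable with the package; when the series matrix has been
downloaded locally, :func:`analyze_gse16334` runs it through the full
pipeline: parse, collapse probes to gene symbols, unit-rescale, estimate
circuit activities on the curated FA map, and test FA vs normal per circuit.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path

import pandas as pd

from . import differential, knowledge_base, mechanistic, preprocess


def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parse a GEO series matrix: returns (probe x sample table, metadata).

    Metadata maps each ``!Sample_*`` key to its per-sample values.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *values = line.split("\t")
                meta.setdefault(key.lstrip("!"), []).extend(
                    v.strip('"') for v in values
                )
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    return table, meta


def infer_groups(meta: dict[str, list[str]], case_pattern: str = r"\bFA\b|Fanconi") -> list[str]:
    """'case'/'control' per sample from the title/characteristics metadata."""
    fields = meta.get("Sample_title", [])
    extra = [
        " ".join(vals)
        for vals in zip(*[v for k, v in meta.items() if k.startswith("Sample_characteristics")])
    ] or [""] * len(fields)
    labels = []
    for title, chars in zip(fields, extra):
        text = f"{title} {chars}"
        labels.append("case" if re.search(case_pattern, text, re.I) else "control")
    return labels


def collapse_probes(
    table: pd.DataFrame, probe_to_symbol: pd.Series
) -> pd.DataFrame:
    """Average probes mapping to the same gene symbol (unmapped probes drop)."""
    symbols = probe_to_symbol.reindex(table.index).dropna()
    sub = table.loc[symbols.index]
    sub.index = symbols.to_numpy()
    return sub.groupby(level=0).mean()


def analyze_gse16334(
    path: str | Path,
    probe_map_path: str | Path | None = None,
) -> differential.DifferentialReport:
    """Healthy-vs-FA differential circuit activity from the GEO series matrix.

    ``probe_map_path`` points to a two-column TSV (probe id, gene symbol)
    derived from the array's platform annotation; when omitted the matrix is
    assumed to be gene-level already.
    """
    table, meta = read_series_matrix(path)
    if probe_map_path is not None:
        probe_map = pd.read_csv(
            probe_map_path, sep="\t", index_col=0
        ).iloc[:, 0]
        table = collapse_probes(table, probe_map)
    labels = pd.Series(infer_groups(meta), index=table.columns)
    expr = preprocess.rescale_unit(
        preprocess.ExpressionMatrix(table.astype(float), scale="normalized")
    )
    graph = knowledge_base.load_pathway()
    activities = mechanistic.circuit_activities(expr, graph)
    return differential.differential_report(activities, labels, case_level="case")
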