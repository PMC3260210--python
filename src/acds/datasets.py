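"""Bundled reference tables for worked examples and table arithmetic.

These small TSVs hold the published census of the Ac/Ds element family in
the maize B73 reference genome: per-chromosome counts by class, annotation
status against the prior genome annotation, insertion-context counts, and
the per-chromosome counts of elements carrying three or more subterminal
AAACGG hexamers.  They are count *tables*, not catalogs; use
:func:`catalog_from_counts` to expand a table into a per-element catalog
frame that the reporting operations accept.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "acds.data"


def _load(name: str, index_col: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={index_col: str})
    return df.set_index(index_col)


def load_b73_census() -> pd.DataFrame:
    """Per-chromosome element counts by class (rows: chromosomes 1-10 and
    'Unknown' for unplaced scaffolds; columns: the five element classes)."""
    return _load("b73_census.tsv", "chromosome")


def load_b73_annotation_status() -> pd.DataFrame:
    """Counts of new / partially annotated / fully annotated elements per
    class, relative to the prior genome annotation."""
    return _load("b73_annotation_status.tsv", "class")


def load_b73_insertion_context() -> pd.DataFrame:
    """Counts of elements per class inserted in or within 200 bp of a gene
    model, in repetitive DNA, or in intergenic DNA."""
    return _load("b73_insertion_context.tsv", "class")


def load_b73_hexamer_census() -> pd.DataFrame:
    """Per-chromosome counts of elements with >= 3 subterminal AAACGG
    hexamer copies, by class."""
    return _load("b73_hexamer_census.tsv", "chromosome")


def catalog_from_counts(table: pd.DataFrame, row_field: str = "seq_id",
                        col_field: str = "label") -> pd.DataFrame:
    """Expand a count table into a one-row-per-element catalog frame."""
    rows = []
    for row_value, row in table.iterrows():
        for col_value, count in row.items():
            rows.extend({row_field: str(row_value), col_field: str(col_value)}
                        for _ in range(int(count)))
    return pd.DataFrame(rows)
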