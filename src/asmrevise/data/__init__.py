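"""Shipped reference tables: the published before/after census of the
Aegilops tauschii Aet v4.0 / v5.0 pseudomolecule assemblies and its
annotation summaries, used as worked-example inputs for the report layer."""

from importlib import resources

import pandas as pd

TABLES = (
    "aet_census_v40", "aet_census_v50", "aet_te_classes_v50",
    "aet_intact_ltr", "aet_gene_annotation", "aet_rga_counts", "aet_busco",
)


def load_table(name: str) -> pd.DataFrame:
    """Load a shipped TSV table by name (see :data:`TABLES`)."""
    if name not in TABLES:
        raise KeyError(f"unknown table {name!r}; available: {TABLES}")
    ref = resources.files(__package__) / "tables" / f"{name}.tsv"
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")
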