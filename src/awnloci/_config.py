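"""Loaders for packaged configuration: CDS fixtures, diagnostic-variant
tables, and the known awn-gene catalogue."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml


@lru_cache(maxsize=1)
def load_fixture_config() -> dict:
    """Parsed ``data/fixtures.yaml`` (CDS fixtures + diagnostic tables)."""
    text = resources.files("awnloci.data").joinpath("fixtures.yaml").read_text()
    cfg = yaml.safe_load(text)
    # YAML folded scalars keep single spaces at fold points; strip them.
    for gene in ("rae1", "rae2"):
        cfg[gene]["cds"] = cfg[gene]["cds"].replace(" ", "").replace("\n", "")
    return cfg


@lru_cache(maxsize=1)
def load_gene_catalogue() -> pd.DataFrame:
    """Known awn genes/loci: name, chromosome, start, end, scope, source.

    ``scope`` is ``gene`` for loci with printed coordinates and
    ``chromosome`` for loci known only to chromosome resolution (start/end
    are then missing).
    """
    with resources.files("awnloci.data").joinpath("awn_gene_catalogue.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["."])
    return df
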