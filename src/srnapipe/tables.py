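"""Published worked-example tables shipped with the package.

Two small differential-expression tables from a growth-hormone study of
primary chicken hepatocytes (chGH-treated vs PBS control, one pooled
library per condition) are included as desk-scale fixtures:

- the differential-miRNA table (known chicken miRNAs, cross-species
  homologs and predicted novel miRNAs, with RPM in each condition, the
  printed fold change and P-value);
- the top-10 up- and down-regulated gene table (RPKM pairs).

They exercise the zero-revision rule, the fold-change arithmetic and the
up/down decision rule against independently published numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("srnapipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_dem_table() -> pd.DataFrame:
    """Differential-miRNA table: columns mirna, tier (known/homolog/novel),
    direction, rpm_control (PBS), rpm_treated (chGH), fold_printed,
    p_value."""
    return _load("dem_table.tsv")


def load_deg_table() -> pd.DataFrame:
    """Top differential genes: columns gene, direction, rpkm_control,
    rpkm_treated, fold_printed, p_value."""
    return _load("deg_top_table.tsv")


def printed_decimals(value: float) -> int:
    """Decimal places a printed fold change uses (1 above 1, up to 3 below
    — mirrors the mixed precision of the published tables)."""
    s = f"{value}"
    return len(s.split(".")[1]) if "." in s else 0
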