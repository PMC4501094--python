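"""Published reference summary of tRFs in *Triops cancriformis*.

The deep-sequencing study of tadpole-shrimp development (six stages: egg,
four larval instars, adult) reported per-anticodon tRF read totals and
the dominant structural region for the mitochondrial and the 16 most
abundant nuclear anticodon families, together with headline totals.  That
printed summary is embedded here as a reference dataset so internal
consistency of the published arithmetic can be checked and so analyses of
synthetic libraries can be compared against the published layout.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_table",
    "mitochondrial_total",
    "nuclear_fold_ratio",
    "anticodon_share_percent",
    "count_main_region_rows",
    "PRINTED",
]

# compartment, isotype, anticodon (RNA alphabet), total reads, main region
_ROWS = [
    ("mitochondrial", "Ser", "GCU", 3678, "5' half"),
    ("mitochondrial", "Val", "UAC", 1784, "3' end"),
    ("mitochondrial", "Lys", "CUU", 1606, "5' half"),
    ("mitochondrial", "Thr", "UGU", 1547, "5' end and 3' half"),
    ("mitochondrial", "Ile", "GAU", 795, "5' end and 3' half"),
    ("mitochondrial", "Phe", "GAA", 713, "3' end"),
    ("mitochondrial", "Gly", "UCC", 583, "AC stem-loop"),
    ("mitochondrial", "Asn", "GUU", 403, "3' end and AC stem-loop"),
    ("mitochondrial", "Met", "CAU", 316, "AC stem-loop"),
    ("mitochondrial", "Tyr", "GUA", 294, "5' half and AC stem-loop"),
    ("mitochondrial", "Asp", "GUC", 218, "3' end and AC stem-loop"),
    ("mitochondrial", "Cys", "GCA", 144, "3' half"),
    ("mitochondrial", "Pro", "UGG", 67, "5' and 3' end"),
    ("mitochondrial", "Gln", "UUG", 56, "5' half and AC stem-loop"),
    ("mitochondrial", "Leu", "UAA", 30, "3' end"),
    ("mitochondrial", "Ala", "UCG", 6, "3' end"),
    ("nuclear", "Gly", "GCC", 3_674_244, "5' half"),
    ("nuclear", "Gly", "CCC", 749_207, "5' half"),
    ("nuclear", "Glu", "CUC", 280_322, "5' half"),
    ("nuclear", "Lys", "CUU", 102_190, "5' half"),
    ("nuclear", "Asp", "GUC", 88_065, "5' half"),
    ("nuclear", "Glu", "UUC", 62_011, "5' end"),
    ("nuclear", "His", "GUG", 29_698, "5' end"),
    ("nuclear", "Thr", "UGU", 10_286, "3' end"),
    ("nuclear", "Gly", "UCC", 9_046, "5' half"),
    ("nuclear", "SeC", "UCA", 6_911, "5' half"),
    ("nuclear", "Pro", "CGG", 6_616, "5' half"),
    ("nuclear", "Pro", "UGG", 5_842, "5' half"),
    ("nuclear", "Cys", "GCA", 3_808, "5' half"),
    ("nuclear", "Gln", "CUG", 3_654, "AC stem-loop"),
    ("nuclear", "Ala", "CGC", 3_413, "5' half"),
    ("nuclear", "Gln", "UUG", 2_478, "5' half"),
]

#: headline numbers as printed in the published summary
PRINTED = {
    "total_raw_reads": 151_340_419,
    "unique_reads_retained": 1_162_917,
    "mitochondrial_trf_reads": 12_240,
    "nuclear_trf_reads": 5_048_874,
    "nuclear_over_mito_fold": 412,
    "gly_gcc_percent_of_nuclear": 72.9,
    "gly_ccc_percent_of_nuclear": 14.8,
    "n_mito_anticodons_with_trfs": 16,
    "n_nuclear_anticodons_with_trfs": 39,
    "n_nuclear_5p_half_of_top16": 12,
}


def reference_table() -> pd.DataFrame:
    """The published per-anticodon tRF summary as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["compartment", "isotype", "anticodon", "total_reads", "main_region"],
    )


def mitochondrial_total(table: pd.DataFrame | None = None) -> int:
    """Sum of the mitochondrial per-anticodon totals."""
    t = table if table is not None else reference_table()
    return int(t.loc[t.compartment == "mitochondrial", "total_reads"].sum())


def nuclear_fold_ratio() -> float:
    """Published nuclear tRF total over the mitochondrial row sum."""
    return PRINTED["nuclear_trf_reads"] / mitochondrial_total()


def anticodon_share_percent(isotype: str, anticodon: str) -> float:
    """One nuclear anticodon's share of the published nuclear total, %."""
    t = reference_table()
    row = t[
        (t.compartment == "nuclear")
        & (t.isotype == isotype)
        & (t.anticodon == anticodon)
    ]
    if row.empty:
        raise KeyError(f"{isotype}({anticodon}) not in the reference table")
    return float(row.total_reads.iloc[0]) / PRINTED["nuclear_trf_reads"] * 100.0


def count_main_region_rows(compartment: str, main_region: str | None = None) -> int:
    """Number of reference rows in a compartment, optionally restricted
    to one exact main-region label."""
    t = reference_table()
    sel = t.compartment == compartment
    if main_region is not None:
        sel &= t.main_region == main_region
    return int(sel.sum())
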