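"""Bundled reference tables from the forest musk deer SSR survey.

Small published summary tables shipped with the package so that the
arithmetic aggregation layer can be exercised against real printed values
without any download: the genome-wide / per-region per-type locus counts,
and the diversity statistics of the 22-locus tetranucleotide marker panel
genotyped in 36 captive forest musk deer.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fmd_type_region_counts", "load_fmd_marker_panel"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ssrmine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_fmd_type_region_counts() -> pd.DataFrame:
    """Per-repeat-type locus counts, genome-wide and per genomic region.

    Columns: region ('genome', "5'UTR", 'CDS', 'intron', "3'UTR", 'TE',
    'intergenic'), unit_length (1-6), n_loci.  Region/type totals are not
    stored; the summary builders recompute them.
    """
    return _read("fmd_type_region_counts.tsv")


def load_fmd_marker_panel() -> pd.DataFrame:
    """Diversity statistics of the published tetranucleotide marker panel.

    One row per locus: n, k, ho, he, ar, pic, hwe_p and a ``retained`` flag
    (False for the HWE-deviant locus LS-55-1, for which only k and Ar were
    reported).
    """
    df = _read("fmd_marker_panel.tsv")
    df["retained"] = df["retained"].astype(bool)
    return df
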