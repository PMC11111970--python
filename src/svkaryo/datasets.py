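"""Bundled reference tables for the REH cell line.

The package ships the published table of 23 confirmed large-scale /
interchromosomal structural variants and the seven confirmed expressed
fusion genes of REH.  These serve as a truth set for caller evaluation
and as worked-example input; users characterizing another sample supply
their own tables in the same TSV schema.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .records import Callset, SvRecord, SvType, Technology

_TECH_COLUMNS = {
    "pacbio": ("support_pacbio", Technology.LONG_READ, 15.0, "sniffles"),
    "ont": ("support_ont", Technology.LONG_READ, 18.0, "sniffles"),
    "illumina": ("support_illumina", Technology.SHORT_READ, 34.0, "tiddit"),
}

#: mean WGS depth of coverage of the three REH datasets, reads
REH_MEAN_DEPTHS = {"illumina": 34.0, "ont": 18.0, "pacbio": 15.0}


def _data_path(name: str):
    return resources.files("svkaryo").joinpath("data", name)


def load_reh_confirmed_svs() -> pd.DataFrame:
    """The confirmed REH SV table (one row per event)."""
    with resources.as_file(_data_path("reh_confirmed_svs.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)


def load_reh_confirmed_fusions() -> pd.DataFrame:
    """The seven confirmed REH fusion genes with read support."""
    with resources.as_file(_data_path("reh_confirmed_fusions.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def _row_record(row, idx: int, tech_key: str) -> SvRecord:
    col, tech, _, caller = _TECH_COLUMNS[tech_key]
    return SvRecord(
        id=f"reh_{idx}",
        caller=caller,
        technology=tech,
        svtype=SvType(row["svtype"]),
        chrom1=row["chrom1"],
        pos1=int(row["pos1"]),
        chrom2=row["chrom2"],
        pos2=int(row["pos2"]),
        size=int(row["size"]),
        support=int(row[col]),
    )


def reh_truth_records() -> list[SvRecord]:
    """The 23 confirmed SVs as normalized records (truth set).

    Support is arbitrarily taken from the ONT column; truth matching
    ignores it.
    """
    df = load_reh_confirmed_svs()
    return [_row_record(row, i, "ont") for i, row in df.iterrows()]


def reh_table_records(tech_key: str) -> list[SvRecord]:
    """All 23 confirmed SVs carrying one technology's read-support column
    (the table reports support from every technology even for events a
    given callset missed)."""
    df = load_reh_confirmed_svs()
    return [_row_record(row, i, tech_key) for i, row in df.iterrows()]


def _called_in(called_in: str, tech_key: str) -> bool:
    return called_in == "all" or tech_key in called_in.split("_")


def reh_callset(tech_key: str) -> Callset:
    """The confirmed-SV calls one technology actually made, with that
    technology's read support — i.e. the true-positive portion of its
    callset."""
    col, tech, depth, caller = _TECH_COLUMNS[tech_key]
    df = load_reh_confirmed_svs()
    records = [
        _row_record(row, i, tech_key)
        for i, row in df.iterrows()
        if _called_in(row["called_in"], tech_key)
    ]
    return Callset(
        name=tech_key, caller=caller, technology=tech, mean_depth=depth, records=records
    )
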