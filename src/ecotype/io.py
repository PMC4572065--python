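"""Readers and writers for the package's plain-text formats.

FASTA goes through Biopython; tables are TSV/CSV via pandas.  The
accession table mirrors a seedbank passport layout: ID, Accession,
Country, Longitude, Latitude, Altitude, Region.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

ACCESSION_COLUMNS = (
    "Accession",
    "Country",
    "Longitude",
    "Latitude",
    "Altitude",
    "Region",
)


def read_contigs(path: str | Path) -> dict[str, str]:
    """Contig id -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_contigs(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "nonspecific_flag" in df.columns:
        df["nonspecific_flag"] = df["nonspecific_flag"].astype(bool)
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_blast_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_accession_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "ID" not in df.columns:
        raise FormatError("accession table lacks required column 'ID'")
    return df.set_index("ID")


def write_accession_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True, index_label="ID")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
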