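"""Readers and writers for the pipeline's standard formats.

FASTA goes through Biopython, newick through dendropy; tabular data are
TSV/CSV via pandas with schema checks that name the offending column,
and the distance matrix is written as square PHYLIP.  All round-trips
are lossless on valid input.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "write_phylip",
    "read_chamber_series",
    "write_json",
]

METADATA_COLUMNS = [
    "sequence_id", "individual_id", "station_id", "latitude", "longitude",
    "date", "depth_min", "depth_max", "morphospecies", "quality",
]


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id; rejects duplicates and empty records."""
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record {rec.id!r} (#{i})")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty sequence in record {rec.id!r} (#{i})")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path, required=METADATA_COLUMNS) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sequence_id": str,
                                               "individual_id": str,
                                               "station_id": str})
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"{path}: metadata missing required column {col!r}")
    return frame


def write_metadata(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def write_phylip(dm, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for i, taxon in enumerate(dm.taxa):
            row = " ".join(f"{v:.6f}" for v in dm.d[i])
            fh.write(f"{taxon:<12s} {row}\n")


def read_chamber_series(path):
    from .ontogeny import ChamberSeries

    frame = pd.read_csv(path)
    for col in ("chamber_index", "volume_um3", "x_um", "y_um", "z_um",
                "H_um", "L_um"):
        if col not in frame.columns:
            raise ValueError(f"{path}: chamber series missing column {col!r}")
    return ChamberSeries.from_frame(frame, specimen_id=Path(path).stem)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
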