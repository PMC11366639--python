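"""File I/O: protein FASTA, tab-separated tables, Newick trees."""
from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .architecture import ProteinRecord
from .phylo import read_newick, write_newick  # noqa: F401  (re-exported)


def read_fasta(path) -> list:
    """Protein records from FASTA; id is the description up to the first whitespace."""
    records = []
    seen = set()
    dupes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    if dupes:
        raise ValueError(f"duplicate FASTA ids: {sorted(set(dupes))}")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns.size == 0:
        raise ValueError(f"no header row in {path}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
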