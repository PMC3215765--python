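"""Readers and writers for the TSV/FASTA dialects used by the pipeline.

All tables are UTF-8 TSV with a mandatory header row; lines starting with
``#`` are comments.  Coordinates in files are 1-based inclusive (Pfam
convention); in-memory indices are 0-based.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .model import DomainHit
from .pairs import ScoreTable

__all__ = [
    "read_hits",
    "write_hits",
    "write_clan_map",
    "write_clusters",
    "read_scores",
    "write_scores",
    "read_inparanoid_sqltable",
    "read_aligned_pairs",
    "write_aligned_pairs",
    "read_identities",
    "write_tsv",
]

HITS_COLUMNS = ["protein_id", "accession", "start", "end", "type_class"]
SCORES_COLUMNS = ["query_id", "subject_id", "bits"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_hits(path) -> dict[str, list[DomainHit]]:
    """Domain hits grouped by protein, in file order."""
    df = _read_table(path, HITS_COLUMNS)
    out: dict[str, list[DomainHit]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[row.protein_id].append(
            DomainHit(
                row.protein_id,
                row.accession,
                int(row.start),
                int(row.end),
                row.type_class,
            )
        )
    return dict(out)


def write_hits(path, hits: Iterable[DomainHit]) -> None:
    rows = [
        (h.protein_id, h.accession, h.start, h.end, h.type_class) for h in hits
    ]
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False)


def write_clan_map(path, mapping: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tclan\n")
        for acc in sorted(mapping):
            fh.write(f"{acc}\t{mapping[acc]}\n")


def write_clusters(path, clusters) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster_id\tspecies\tprotein_id\tis_seed\n")
        for c in clusters:
            seeds = set(c.seed_pair or ())
            for pid, sp in c.members:
                fh.write(f"{c.cluster_id}\t{sp}\t{pid}\t{int(pid in seeds)}\n")


def read_scores(path) -> ScoreTable:
    """BLAST-tabular-like subset: query_id, subject_id, bits and optional
    overlap_frac / segment_frac coverage columns."""
    df = _read_table(path, SCORES_COLUMNS)
    table = ScoreTable()
    has_cov = {"overlap_frac", "segment_frac"} <= set(df.columns)
    for row in df.itertuples(index=False):
        kwargs = {}
        if has_cov:
            kwargs = {
                "overlap_frac": float(row.overlap_frac) if pd.notna(row.overlap_frac) else None,
                "segment_frac": float(row.segment_frac) if pd.notna(row.segment_frac) else None,
            }
        table.add(row.query_id, row.subject_id, float(row.bits), **kwargs)
    return table


def write_scores(path, entries: Iterable[tuple]) -> None:
    """Entries are (query, subject, bits) or (query, subject, bits, overlap, segment)."""
    entries = list(entries)
    with_cov = entries and len(entries[0]) == 5
    cols = SCORES_COLUMNS + (["overlap_frac", "segment_frac"] if with_cov else [])
    pd.DataFrame(entries, columns=cols).to_csv(path, sep="\t", index=False)


def read_inparanoid_sqltable(path) -> pd.DataFrame:
    """Convenience reader for InParanoid's ``sqltable`` layout.

    Columns (no header): cluster_id, bit_score, species, inparalog_score,
    protein_id.  Returns a normalized DataFrame with the columns of the
    native clusters dialect; a member is a seed when its inparalog score
    equals 1.0.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["cluster_id", "bit_score", "species", "inparalog_score", "protein_id"],
        dtype={"cluster_id": str, "species": str, "protein_id": str},
    )
    return pd.DataFrame(
        {
            "cluster_id": df["cluster_id"],
            "species": df["species"],
            "protein_id": df["protein_id"],
            "is_seed": (df["inparalog_score"].astype(float) == 1.0).astype(int),
        }
    )


def read_aligned_pairs(path) -> list[tuple[str, str, str, str]]:
    """Aligned FASTA as a paired stream: records 2k and 2k+1 form one
    pairwise alignment.  Returns (id1, seq1, id2, seq2) tuples."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: odd number of records in paired alignment stream")
    out = []
    for r1, r2 in zip(records[0::2], records[1::2]):
        out.append((r1.id, str(r1.seq), r2.id, str(r2.seq)))
    return out


def write_aligned_pairs(path, pairs: Iterable[tuple[str, str, str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for id1, seq1, id2, seq2 in pairs:
            fh.write(f">{id1}\n{seq1}\n>{id2}\n{seq2}\n")


def read_identities(path) -> dict[tuple[str, str], float]:
    """Precomputed identity hook: TSV with id1, id2, identity."""
    df = _read_table(path, ["id1", "id2", "identity"])
    return {
        tuple(sorted((row.id1, row.id2))): float(row.identity)
        for row in df.itertuples(index=False)
    }


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
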