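"""Readers and writers for the package's plain-text interchange formats.

Formats (all TSV with header, UTF-8):

* protein annotations: ``protein_id, go_ids`` (semicolon-separated), ``top_hit_taxon``
* PSM tables: ``peptide, run_id, spectral_count``
* OTU class tables: ``run_id, class, fraction``
* ratio matrices: ``row_id, day_<d>...``
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .records import PeptideObservation, ProteinRecord

logger = logging.getLogger(__name__)


def read_protein_fasta(path) -> dict[str, str]:
    """Protein id -> uppercase amino-acid sequence."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise InputError(f"no FASTA records in {path}")
    return seqs


def write_protein_fasta(proteins, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "go_ids", "top_hit_taxon"}
    if not required.issubset(df.columns):
        raise InputError(
            f"annotation table must have columns {sorted(required)}"
        )
    return df


def load_proteins(fasta_path, annotation_path) -> list[ProteinRecord]:
    """Join a protein FASTA with its annotation table into records.

    Proteins without an annotation row get empty GO sets and no taxon;
    annotation rows without a sequence are an input error (ids must match).
    """
    seqs = read_protein_fasta(fasta_path)
    ann = read_annotation_table(annotation_path)
    missing = set(ann["protein_id"]) - set(seqs)
    if missing:
        raise InputError(
            f"annotation rows reference proteins absent from FASTA: "
            f"{sorted(missing)[:5]}..."
        )
    rows = {r.protein_id: r for r in ann.itertuples(index=False)}
    records = []
    for pid, seq in seqs.items():
        row = rows.get(pid)
        if row is None:
            records.append(ProteinRecord(id=pid, sequence=seq))
            continue
        go_ids = frozenset(g for g in row.go_ids.split(";") if g)
        taxon = row.top_hit_taxon or None
        records.append(
            ProteinRecord(id=pid, sequence=seq, go_ids=go_ids, top_hit_taxon=taxon)
        )
    return records


def write_annotation_table(proteins, path) -> None:
    rows = [
        (p.id, ";".join(sorted(p.go_ids)), p.top_hit_taxon or "")
        for p in proteins
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "go_ids", "top_hit_taxon"]
    ).to_csv(path, sep="\t", index=False)


def read_psm_table(path) -> list[PeptideObservation]:
    """Read a PSM table; rows with spectral_count < 1 or peptides
    shorter than 5 residues are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "run_id": str})
    required = {"peptide", "run_id", "spectral_count"}
    if not required.issubset(df.columns):
        raise InputError(f"PSM table must have columns {sorted(required)}")
    obs = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        count = int(row.spectral_count)
        if count < 0:
            raise InputError(f"negative spectral count for {row.peptide}")
        if count < 1 or len(row.peptide) < 5:
            n_dropped += 1
            continue
        obs.append(
            PeptideObservation(
                peptide=row.peptide, run_id=row.run_id, spectral_count=count
            )
        )
    if n_dropped:
        logger.warning("dropped %d PSM rows (zero count or peptide < 5 aa)", n_dropped)
    return obs


def write_psm_table(observations, path) -> None:
    rows = [(o.peptide, o.run_id, o.spectral_count) for o in observations]
    pd.DataFrame(
        rows, columns=["peptide", "run_id", "spectral_count"]
    ).to_csv(path, sep="\t", index=False)


def read_otu_table(path) -> dict[str, dict[str, float]]:
    """run_id -> {class name -> fraction}."""
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "class": str})
    required = {"run_id", "class", "fraction"}
    if not required.issubset(df.columns):
        raise InputError(f"OTU table must have columns {sorted(required)}")
    out: dict[str, dict[str, float]] = {}
    for run_id, cls, frac in df[["run_id", "class", "fraction"]].itertuples(
        index=False, name=None
    ):
        out.setdefault(run_id, {})[cls] = float(frac)
    return out


def read_ratio_matrix(path):
    """Read a ``row_id, day_<d>...`` TSV into a dynamics RatioMatrix."""
    from .dynamics import RatioMatrix

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "row_id":
        raise InputError("ratio matrix TSV must start with a row_id column")
    day_cols = [c for c in df.columns[1:] if c.startswith("day_")]
    if len(day_cols) < 2:
        raise InputError("ratio matrix needs at least two day_ columns")
    days = [float(c[4:]) for c in day_cols]
    return RatioMatrix(
        row_ids=list(df["row_id"].astype(str)),
        days=np.asarray(days, dtype=float),
        values=df[day_cols].to_numpy(dtype=float),
    )


def write_ratio_matrix(matrix, path) -> None:
    cols = ["row_id"] + [
        f"day_{int(d) if float(d).is_integer() else d}" for d in matrix.days
    ]
    df = pd.DataFrame(matrix.values, columns=cols[1:])
    df.insert(0, "row_id", matrix.row_ids)
    df.to_csv(path, sep="\t", index=False)
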