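"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular artifacts are tab-separated text; sequences are FASTA and gene
models GFF3, written through Biopython / standard conventions so they remain
consumable by ordinary genomics tooling.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand", "frame",
                "attributes"]


def write_expression(x: pd.DataFrame, path: str | Path) -> None:
    """Expression TSV: row 1 = sample ids, column 1 = gene ids."""
    x.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_accession", "term_name"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    return ann


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Probe hit TSV: probe_set_id, probe_id, gene_id, perfect in {0,1}."""
    hits = pd.read_csv(path, sep="\t", dtype={"perfect": int})
    required = {"probe_set_id", "probe_id", "gene_id", "perfect"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    if not hits["perfect"].isin((0, 1)).all():
        bad = hits.index[~hits["perfect"].isin((0, 1))][0]
        raise ValueError(f"hit table line {bad + 2}: perfect must be 0 or 1")
    return hits


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        features.to_csv(fh, sep="\t", header=False, index=False)


def write_promoters_fasta(promoters: dict[str, str], path: str | Path) -> None:
    write_fasta(promoters, path)


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Known-CRE catalog TSV: accession, consensus (IUPAC), description."""
    cat = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "consensus", "description"}
    missing = required - set(cat.columns)
    if missing:
        raise ValueError(f"catalog missing columns {sorted(missing)}")
    return cat
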