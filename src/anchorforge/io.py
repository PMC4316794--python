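"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; the tabular formats (variant/genotype/map
TSVs, AGP v2.0, GFF3) are plain pandas tables with fixed column orders so
that runs are byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "component_id", "component_beg", "component_end", "orientation",
]
GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_fasta(path, records, wrap: int = 60) -> None:
    """Write (id, sequence) pairs as 60-column wrapped FASTA."""
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_agp(path, rows: list[dict]) -> None:
    """AGP v2.0. Component rows carry the 9 standard columns; gap rows use
    type U with gap_type/linkage/evidence in columns 6-9."""
    with open(path, "w") as fh:
        fh.write("##agp-version 2.0\n")
        for r in rows:
            if r["component_type"] in ("U", "N"):
                cols = [r["object"], r["object_beg"], r["object_end"],
                        r["part_number"], r["component_type"], r["gap_length"],
                        r.get("gap_type", "scaffold"), r.get("linkage", "yes"),
                        r.get("evidence", "map")]
            else:
                cols = [r[c] for c in AGP_COLUMNS]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_agp(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        row = {"object": f[0], "object_beg": int(f[1]), "object_end": int(f[2]),
               "part_number": int(f[3]), "component_type": f[4]}
        if f[4] in ("U", "N"):
            row.update({"gap_length": int(f[5]), "gap_type": f[6],
                        "linkage": f[7], "evidence": f[8]})
        else:
            row.update({"component_id": f[5], "component_beg": int(f[6]),
                        "component_end": int(f[7]), "orientation": f[8]})
        rows.append(row)
    return pd.DataFrame(rows)


def write_gff3(path, features: pd.DataFrame) -> None:
    """Write a feature table (seqid, type, start, end, strand, attr_id, name)
    as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in features.itertuples():
            attrs = f"ID={ft.attr_id}"
            if getattr(ft, "name", None):
                attrs += f";Name={ft.name}"
            fh.write(
                "\t".join([
                    str(ft.seqid), "anchorforge", str(ft.type), str(int(ft.start)),
                    str(int(ft.end)), ".", str(ft.strand), ".", attrs,
                ]) + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append({"seqid": f[0], "source": f[1], "type": f[2],
                     "start": int(f[3]), "end": int(f[4]), "score": f[5],
                     "strand": f[6], "phase": f[7],
                     "attr_id": attrs.get("ID", ""), "name": attrs.get("Name", "")})
    return pd.DataFrame(rows)


def write_bed(path, intervals: pd.DataFrame) -> None:
    """BED (0-based half-open) from 1-based inclusive interval columns."""
    with open(path, "w") as fh:
        for iv in intervals.itertuples():
            name = getattr(iv, "name", ".")
            fh.write(f"{iv.seqid}\t{int(iv.start) - 1}\t{int(iv.end)}\t{name}\n")
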