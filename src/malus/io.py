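"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; BED and the various TSV tables through pandas.
The VCF support is deliberately minimal (VCFv4.2, GT-only biallelic sites)
— just enough to round-trip the genotype fixtures the population-genetic
functions consume.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from malus.popgen import MISSING, GenotypeMatrix

CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE_TO_CODE[b] = i
    _BASE_TO_CODE[b + 32] = i  # lower case

__all__ = [
    "codes_to_string",
    "string_to_codes",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_vcf",
    "read_vcf",
]


def codes_to_string(codes: np.ndarray) -> str:
    return CODE_TO_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def string_to_codes(seq: str) -> np.ndarray:
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def write_fasta(sequences: Mapping[str, np.ndarray | str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(seq if isinstance(seq, str) else codes_to_string(seq)),
            id=name, description="",
        )
        for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path, as_codes: bool = False) -> dict[str, np.ndarray | str]:
    from Bio.SeqIO import parse

    out: dict = {}
    for rec in parse(str(path), "fasta"):
        seq = str(rec.seq)
        out[rec.id] = string_to_codes(seq) if as_codes else seq
    return out


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + [
        c for c in ("name", "score", "strand") if c in df.columns
    ]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


_GT_FROM_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_CODE_FROM_GT = {
    "0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2, "./.": MISSING, ".|.": MISSING, ".": MISSING,
}


def write_vcf(gm: GenotypeMatrix, path: str | Path, ref: str = "G", alt: str = "A") -> None:
    """Write a minimal VCFv4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for pop in pd.unique(gm.populations):
            n = int((gm.populations == pop).sum())
            fh.write(f"##population=<ID={pop},Samples={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            qual = "." if gm.qual is None else f"{gm.qual[i]:g}"
            gts = "\t".join(_GT_FROM_CODE[int(g)] for g in gm.genotypes[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.positions[i]}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | Path, populations: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    """Read a minimal GT-only VCF back into a :class:`GenotypeMatrix`.

    ``populations`` maps sample name to population label; samples not listed
    (or when omitted entirely) get the label 'unknown' unless the file embeds
    ``##population=`` headers written by :func:`write_vcf`, which encode the
    per-population sample layout by name prefix.
    """
    samples: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    quals: list[float] = []
    rows: list[list[int]] = []
    has_qual = True
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chroms.append(fields[0])
            positions.append(int(fields[1]))
            if fields[5] == ".":
                has_qual = False
            else:
                quals.append(float(fields[5]))
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            rows.append(
                [_CODE_FROM_GT.get(cell.split(":")[gt_idx], MISSING) for cell in fields[9:]]
            )
    if populations is None:
        pops = [s.rsplit("_", 1)[0] if "_" in s else "unknown" for s in samples]
    else:
        pops = [populations.get(s, "unknown") for s in samples]
    return GenotypeMatrix(
        genotypes=np.asarray(rows, dtype=np.int8),
        samples=samples,
        populations=np.asarray(pops, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        qual=np.asarray(quals, float) if has_qual and quals else None,
    )
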