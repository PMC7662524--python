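"""File formats and coordinate conventions.

Internal coordinates are 1-based inclusive on the forward strand
everywhere in the package; BED output is converted to 0-based
half-open by the writer. FASTA/FASTQ go through Biopython. The motif
exchange format is MEME-minimal (version header, alphabet, background
frequencies, letter-probability matrix with nsites and E-value).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import PositionWeightMatrix, BASES
from .readprep import ReadRecord
from .scan import MotifHit


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ReadRecord]:
    return [ReadRecord(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs, ReadRecords, or plain strings."""
    recs = []
    for i, r in enumerate(records):
        if isinstance(r, ReadRecord):
            rid, seq = r.id, r.sequence
        elif isinstance(r, str):
            rid, seq = f"seq{i+1}", r
        else:
            rid, seq = r
        recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[ReadRecord]:
    return [ReadRecord(rec.id, str(rec.seq),
                       tuple(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(path, pwm: PositionWeightMatrix, name: str = "MOTIF1",
               nsites: float = 20, e_value: float = 0.0) -> None:
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, pwm.background)),
        "",
        f"MOTIF {name}",
        (f"letter-probability matrix: alength= 4 w= {pwm.width} "
         f"nsites= {int(round(nsites))} E= {e_value:.3e}"),
    ]
    for row in pwm.probs:
        lines.append(" " + " ".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path) -> tuple[PositionWeightMatrix, dict]:
    """Parse a MEME-minimal file; returns (pwm, metadata)."""
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]
    bg = np.full(4, 0.25)
    meta: dict = {}
    rows: list[list[float]] = []
    i = 0
    try:
        while i < len(lines):
            ln = lines[i]
            if ln.startswith("Background letter frequencies"):
                parts = lines[i + 1].split()
                bg = np.array([float(parts[2 * BASES.index(b) + 1])
                               for b in BASES])
                i += 2
                continue
            if ln.startswith("MOTIF"):
                meta["name"] = ln.split(maxsplit=1)[1].strip()
            if ln.startswith("letter-probability matrix"):
                kv = ln.split(":", 1)[1].split()
                d = {kv[j].rstrip("="): kv[j + 1]
                     for j in range(0, len(kv), 2)}
                w = int(d["w"])
                meta["nsites"] = float(d.get("nsites", 0))
                meta["e_value"] = float(d.get("E", 0))
                for k in range(w):
                    i += 1
                    rows.append([float(x) for x in lines[i].split()])
            i += 1
    except (ValueError, IndexError) as exc:
        raise ValueError(
            f"malformed MEME-minimal file near line {i + 1}") from exc
    if not rows:
        raise ValueError("no letter-probability matrix found")
    probs = np.array(rows)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(probs, bg), meta


# ---------------------------------------------------------------------------
# sensorgrams, expression, annotation tables
# ---------------------------------------------------------------------------

def write_sensorgrams(path, frames: list[pd.DataFrame]) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams(path) -> list[pd.DataFrame]:
    df = pd.read_csv(path)
    required = {"time_s", "response", "concentration_M", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram CSV missing columns {sorted(missing)}")
    return [g.reset_index(drop=True)
            for _, g in df.groupby("concentration_M", sort=True)]


def write_expression(path, matrix: pd.DataFrame) -> None:
    """Genes x samples TSV; first header row = sample ids, second =
    group labels."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(
            matrix.columns.get_level_values("sample_id")) + "\n")
        fh.write("group\t" + "\t".join(
            matrix.columns.get_level_values("group")) + "\n")
        for gene, row in matrix.iterrows():
            fh.write(gene + "\t" + "\t".join(
                f"{v:.6g}" for v in row.to_numpy()) + "\n")


def read_expression(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")[1:]
        groups = fh.readline().strip().split("\t")[1:]
    df = pd.read_csv(path, sep="\t", skiprows=2, header=None,
                     index_col=0)
    df.index.name = "gene_id"
    df.columns = pd.MultiIndex.from_arrays([header, groups],
                                           names=["sample_id", "group"])
    return df


def write_gene_table(path, genes: pd.DataFrame) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"gene_id": str, "strand": str,
                              "operon_id": str, "operon_pos": str})


# ---------------------------------------------------------------------------
# hits: TSV and BED
# ---------------------------------------------------------------------------

def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start": h.start, "end": h.end, "strand": h.strand,
          "score": h.score, "p_value": h.p_value, "q_value": h.q_value,
          "sequence": h.matched_sequence} for h in hits])


def write_hits(path, hits: list[MotifHit]) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    return bed_start + 1, bed_end


def write_bed(path, hits: list[MotifHit], chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for h in hits:
            b0, b1 = to_bed_interval(h.start, h.end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{h.matched_sequence}\t"
                     f"{min(1000, int(round(h.score * 10)))}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# round-trip dispatcher
# ---------------------------------------------------------------------------

_READERS = {
    "FASTA": read_fasta, "FASTQ": read_fastq,
    "MEME-minimal": read_meme, "sensorgram-CSV": read_sensorgrams,
    "expression-TSV": read_expression, "gene-TSV": read_gene_table,
}

_WRITERS = {
    "FASTA": write_fasta, "FASTQ": None,
    "MEME-minimal": lambda p, obj: write_meme(p, obj[0]),
    "sensorgram-CSV": write_sensorgrams,
    "expression-TSV": write_expression, "gene-TSV": write_gene_table,
}


def format_roundtrip(path, fmt: str, tmp_path=None):
    """Parse a file and re-serialize it; returns the parsed object.

    For canonical dialects the rewrite is byte-stable; used by the
    pipeline to validate stage handoffs.
    """
    if fmt not in _READERS:
        raise ValueError(f"unknown format {fmt!r}")
    obj = _READERS[fmt](path)
    writer = _WRITERS.get(fmt)
    if writer is not None and tmp_path is not None:
        writer(tmp_path, obj)
    return obj
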