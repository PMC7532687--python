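"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are BED-style 0-based half-open internally.  GTF
(1-based inclusive) and SEG (1-based inclusive) are converted on read and
on write.  Matrices travel as TSV with feature IDs in column 1 and one
header row of sample IDs.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd


class ParseError(ValueError):
    """Malformed record in an input file; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------- intervals

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED (>=3 columns) into chrom/start/end/id/score/strand.

    Missing names are filled with ``<path stem>_<lineno>``; missing strand
    with '.'.  Raises :class:`ParseError` with the offending line number.
    """
    rows = []
    stem = Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if not (0 <= start < end):
                raise ParseError(path, lineno, f"invalid interval [{start},{end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{stem}_{lineno}"
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path, extra_columns=()) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns] + list(extra_columns)
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = "."
    if "strand" not in out.columns:
        out["strand"] = "."
    cols = ["chrom", "start", "end", "id", "score", "strand"] + list(extra_columns)
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------- gene model


def read_gtf(path) -> dict:
    """Read a GTF gene model into a dict of DataFrames.

    Returns ``{"genes": ..., "exons": ...}``.  Gene rows carry
    chrom/start/end/strand/gene_id and a strand-aware ``tss`` (start on +,
    end-1 on -); exon rows carry chrom/start/end/gene_id.  Coordinates are
    converted to 0-based half-open.
    """
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(path, lineno, "fewer than 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            gene_id = None
            for field in attrs.strip().strip(";").split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gene_id = field.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            recs.append((feature, chrom, start_i, end_i, strand, gene_id))
    df = pd.DataFrame(recs, columns=["feature", "chrom", "start", "end", "strand", "gene_id"])
    genes = df[df.feature == "gene"].drop(columns="feature").reset_index(drop=True)
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)
    exons = df[df.feature == "exon"][["chrom", "start", "end", "gene_id"]].reset_index(drop=True)
    return {"genes": genes, "exons": exons}


def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Write gene/exon rows as GTF (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for _, e in exons[exons.gene_id == g.gene_id].iterrows():
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ----------------------------------------------------------------- matrices


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample TSV with feature IDs in column 1."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, float_format=None) -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, float_format=None) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------- SEG

SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2ratio", "integer_cn"]


def read_seg(path) -> pd.DataFrame:
    """Read a SEG-like table (1-based inclusive on disk -> half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing SEG columns: {missing}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_seg(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    cols = [c for c in SEG_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- GMT


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets: one set per line, name<TAB>description<TAB>gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "GMT line needs name, description, genes")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "."] + list(genes)) + "\n")
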