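"""Offline gene-proximity annotation from a user-supplied GFF3.

Replaces the online genome-browser lookup: for each significant SNP, report
genes overlapping it, the nearest gene within a window, and a coarse
variant-context class (genic / upstream / downstream / intergenic).
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    """One gene span: 1-based inclusive coordinates, strand in {+, -, .}."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


def read_gff3_genes(path, feature_types=("gene",)) -> list:
    """Parse gene-type features from a GFF3 file.

    The ID attribute (falling back to Name, then a positional label) names
    the record; Name is reported alongside when present.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            attr = {}
            for pair in attrs.split(";"):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    attr[k.strip()] = urllib.parse.unquote(v.strip())
            gene_id = attr.get("ID") or attr.get("Name") or f"gene@{chrom}:{start}"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    name=attr.get("Name", gene_id),
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else ".",
                )
            )
    return genes


def sort_genes(genes) -> dict:
    """Group genes by chromosome, sorted by (start, end)."""
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda g: (g.start, g.end, g.gene_id))
    return by_chrom


def _distance(pos: int, g: GeneRecord) -> int:
    if g.start <= pos <= g.end:
        return 0
    return min(abs(pos - g.start), abs(pos - g.end))


def nearest_genes(snps, genes, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Overlapping and nearest genes per SNP.

    ``snps``: iterable of (chrom, pos[, name]).  Distance is 0 inside the
    gene span, else the base-pair gap to the closer end; genes farther than
    ``window`` are omitted.  Nearest-distance ties are all reported
    (comma-joined).  A chromosome absent from the GFF3 gives an empty row
    with a note.
    """
    by_chrom = sort_genes(genes)
    rows = []
    for rec in snps:
        chrom, pos = rec[0], int(rec[1])
        name = rec[2] if len(rec) > 2 else f"{chrom}:{pos}"
        row = {
            "snp": name, "chrom": chrom, "pos": pos,
            "overlapping_genes": "", "nearest_gene": "",
            "distance_bp": pd.NA, "note": "",
        }
        cands = by_chrom.get(chrom)
        if not cands:
            row["note"] = "chromosome absent from annotation"
            rows.append(row)
            continue
        dists = [(g, _distance(pos, g)) for g in cands]
        overlapping = sorted(g.gene_id for g, d in dists if d == 0)
        within = [(g, d) for g, d in dists if d <= window]
        if overlapping:
            row["overlapping_genes"] = ",".join(overlapping)
        if within:
            dmin = min(d for _, d in within)
            nearest = sorted(g.gene_id for g, d in within if d == dmin)
            row["nearest_gene"] = ",".join(nearest)
            row["distance_bp"] = dmin
        else:
            row["note"] = f"no gene within {window} bp"
        rows.append(row)
    return pd.DataFrame(rows)


def classify_context(chrom: str, pos: int, genes,
                     window: int = DEFAULT_WINDOW) -> str:
    """Coarse context class relative to the nearest gene within ``window``.

    genic if inside a span; upstream/downstream of the nearest gene taken in
    strand orientation (5' of a plus-strand gene is upstream); intergenic
    when no gene lies within the window or the nearest gene is unstranded.
    """
    cands = [g for g in genes if g.chrom == chrom]
    if any(g.start <= pos <= g.end for g in cands):
        return "genic"
    within = [(g, _distance(pos, g)) for g in cands if _distance(pos, g) <= window]
    if not within:
        return "intergenic"
    g, _ = min(within, key=lambda t: (t[1], t[0].start))
    if g.strand == "+":
        return "upstream" if pos < g.start else "downstream"
    if g.strand == "-":
        return "upstream" if pos > g.end else "downstream"
    return "intergenic"


def annotate_results(rt: pd.DataFrame, snp_meta: pd.DataFrame, genes,
                     q_max: float = 0.05, q_col: str = "q_G",
                     window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Annotate significant rows of a result table with nearest genes."""
    sig = rt[rt[q_col].to_numpy(dtype=float) < q_max].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["snp", "chrom", "pos", "overlapping_genes",
                     "nearest_gene", "distance_bp", "note", "context"]
        )
    sig["snp"] = sig["indicator"].str.rsplit("_", n=1).str[0]
    meta = snp_meta.set_index("name")
    uniq = sorted(set(sig["snp"]))
    missing = [s for s in uniq if s not in meta.index]
    if missing:
        raise AnnotationError(f"no coordinates for SNPs: {missing[:10]}")
    triples = [(meta.loc[s, "chrom"], int(meta.loc[s, "pos"]), s) for s in uniq]
    ann = nearest_genes(triples, genes, window)
    ann["context"] = [
        classify_context(c, p, genes, window) for c, p, _ in triples
    ]
    return ann
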