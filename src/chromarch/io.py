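"""Readers and writers for the interchange formats the pipeline speaks.

Contact matrices travel as sparse upper-triangle triplet text (``bin_i
bin_j count`` per line, one file per chromosome); regions as BED (0-based
half-open), loops as BEDPE, signal as bedGraph, gene models as a
tab-delimited (gene, chrom, tss, tes, strand) table, expression as a TSV
matrix with a sample -> lineage sidecar, gene sets as GMT, and PWMs as a
tab-delimited four-column probability matrix. Every writer emits files its
paired reader parses back identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .intervals import GeneModel, GenomicInterval
from .lineage import ExpressionMatrix
from .loop_hubs import Loop, LoopSet
from .motifs import PWM

log = logging.getLogger(__name__)


# -- contact triplets --------------------------------------------------------

def read_contact_triplets(
    path: str | Path, bin_size: int, chrom_length: int, chrom: str = "chr1"
) -> ContactMap:
    """Read (bin_i, bin_j, count) rows into a symmetric contact matrix;
    missing pairs are zero."""
    n_bins = -(-chrom_length // bin_size)
    counts = np.zeros((n_bins, n_bins))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ValueError(f"{path}:{lineno}: bin index out of range")
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
    return ContactMap(chrom, bin_size, counts)


def write_contact_triplets(cmap: ContactMap, path: str | Path) -> None:
    iu, ju = np.triu_indices(cmap.n_bins)
    vals = cmap.counts[iu, ju]
    nz = vals != 0
    with open(path, "w") as fh:
        for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:g}\n")


# -- BED / BEDPE / bedGraph --------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            out.append(GenomicInterval(
                f[0], start, end,
                name=f[3] if len(f) > 3 else None,
                score=float(f[4]) if len(f) > 4 and f[4] != "." else None,
                strand=f[5] if len(f) > 5 and f[5] in "+-" else None,
            ))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path: str | Path) -> LoopSet:
    """BEDPE loops; anchors are canonicalized (sorted by start); rows on two
    chromosomes are retained but flagged interchromosomal."""
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: fewer than 6 BEDPE columns")
            s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            if e1 <= s1 or e2 <= s2:
                raise ValueError(f"{path}:{lineno}: end <= start")
            a1 = GenomicInterval(f[0], s1, e1)
            a2 = GenomicInterval(f[3], s2, e2)
            strength = float(f[7]) if len(f) > 7 and f[7] not in (".", "") else None
            loops.append(Loop(a1, a2, strength=strength))
    n_inter = sum(lp.interchromosomal for lp in loops)
    if n_inter:
        log.warning("%s: %d interchromosomal loop rows flagged", path, n_inter)
    return LoopSet(loops)


def write_bedpe(loops: LoopSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            row = [lp.anchor1.chrom, str(lp.anchor1.start), str(lp.anchor1.end),
                   lp.anchor2.chrom, str(lp.anchor2.start), str(lp.anchor2.end),
                   lp.annotation or ".",
                   f"{lp.strength:g}" if lp.strength is not None else "."]
            fh.write("\t".join(row) + "\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: bedGraph rows with end <= start")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def track_to_bins(track: pd.DataFrame, chrom: str, bin_size: int,
                  n_bins: int) -> np.ndarray:
    """Overlap-weighted sum of bedGraph values per fixed-size bin."""
    out = np.zeros(n_bins)
    sub = track[track["chrom"] == chrom]
    for _, row in sub.iterrows():
        b0 = int(row["start"]) // bin_size
        b1 = min(-(-int(row["end"]) // bin_size), n_bins)
        for b in range(max(b0, 0), b1):
            lo = max(int(row["start"]), b * bin_size)
            hi = min(int(row["end"]), (b + 1) * bin_size)
            out[b] += row["value"] * (hi - lo) / bin_size
    return out


# -- gene models, expression, GMT, PWM, FASTA --------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Tab-delimited (gene, chrom, tss, tes, strand), optional header."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "gene" and lineno == 1:
                continue
            genes.append(GeneModel(f[0], f[1], int(f[2]), int(f[3]), f[4]))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\ttes\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene}\t{g.chrom}\t{g.tss}\t{g.tes}\t{g.strand}\n")


def read_expression(matrix_path: str | Path,
                    metadata_path: str | Path) -> ExpressionMatrix:
    """TSV genes x samples matrix plus a (sample, lineage[, replicate])
    sidecar."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    lineages = dict(zip(meta["sample"], meta["lineage"]))
    return ExpressionMatrix(values, lineages)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    expr.values.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame({
        "sample": list(expr.values.columns),
        "lineage": [expr.lineages[s] for s in expr.values.columns],
    })
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            sets[f[0]] = [g for g in f[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "chromarch") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_pwm(path: str | Path) -> PWM:
    """Tab-delimited probability matrix, one row per position, columns
    A C G T (optional header)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.strip().split("\t")
            if not f or not f[0]:
                continue
            if f[0].upper() in ("A", "POS", "#"):
                continue
            rows.append([float(x) for x in f[-4:]])
    return PWM(np.array(rows))


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("A\tC\tG\tT\n")
        for row in pwm.probs:
            fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
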