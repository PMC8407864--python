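"""Probe filtering/harmonization across arrays and gene-to-probe mapping.

Meta-analysis starts from the probes common to both the 450k and EPIC
arrays, minus control/QC probes, probes overlapping SNPs, cross-hybridizing
probes and the sex chromosomes. Candidate-gene analyses map gene intervals
(1-based, closed, GeneCards-style coordinates) to the probes they contain.
"""

from __future__ import annotations

from collections import OrderedDict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError

__all__ = [
    "ANNOTATION_COLUMNS",
    "filter_probes",
    "map_genes_to_probes",
    "read_annotation",
    "write_annotation",
    "read_gene_intervals",
    "genes_to_bed",
]

ANNOTATION_COLUMNS = ("probe_id", "chr", "pos", "on_450k", "on_epic",
                      "is_control", "on_snp", "cross_hybridizing")
VALID_CHROMOSOMES = frozenset([str(c) for c in range(1, 23)] + ["X", "Y"])

# Exclusion rules in application order; later rules only count probes that
# survived the earlier ones (no double counting).
FILTER_RULES = OrderedDict([
    ("not_on_both_arrays", lambda a: ~(a["on_450k"] & a["on_epic"])),
    ("control_probe", lambda a: a["is_control"].astype(bool)),
    ("snp_probe", lambda a: a["on_snp"].astype(bool)),
    ("cross_hybridizing", lambda a: a["cross_hybridizing"].astype(bool)),
    ("sex_chromosome", lambda a: a["chr"].astype(str).isin(["X", "Y"])),
])


def _validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise AnnotationError(f"annotation columns missing: {missing}")
    if annotation["probe_id"].duplicated().any():
        raise AnnotationError("duplicate probe ids in annotation")
    chroms = set(annotation["chr"].astype(str))
    unknown = chroms - VALID_CHROMOSOMES
    if unknown:
        raise AnnotationError(f"unknown chromosome labels: {sorted(unknown)}")
    if (annotation["pos"] < 1).any():
        raise AnnotationError("positions must be 1-based (>= 1)")
    return annotation


def filter_probes(
    annotation: pd.DataFrame,
) -> tuple[pd.Index, "OrderedDict[str, int]"]:
    """Apply the five harmonization rules; return retained probe ids and
    per-rule exclusion counts (in application order, no double counting)."""
    if len(annotation) == 0:
        raise AnnotationError("annotation table is empty")
    ann = _validate_annotation(annotation)
    alive = pd.Series(True, index=ann.index)
    counts: OrderedDict[str, int] = OrderedDict()
    for rule, fn in FILTER_RULES.items():
        hit = fn(ann) & alive
        counts[rule] = int(hit.sum())
        alive &= ~hit
    retained = pd.Index(ann.loc[alive, "probe_id"], name="probe_id")
    if len(retained) == 0:
        import logging
        logging.getLogger(__name__).warning("no probes retained by filtering")
    return retained, counts


def map_genes_to_probes(
    genes: pd.DataFrame,
    annotation: pd.DataFrame,
) -> dict[str, set[str]]:
    """Assign probes to gene intervals (same chromosome, closed interval
    start <= pos <= end). A probe may map to several overlapping genes."""
    ann = _validate_annotation(annotation)
    for col in ("gene", "chr", "start", "end"):
        if col not in genes.columns:
            raise AnnotationError(f"gene table missing column {col!r}")
    if (genes["start"] > genes["end"]).any():
        raise AnnotationError("gene interval with start > end")
    unknown = set(genes["chr"].astype(str)) - VALID_CHROMOSOMES
    if unknown:
        raise AnnotationError(f"unknown chromosome labels: {sorted(unknown)}")

    by_chr: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in ann.groupby(ann["chr"].astype(str)):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        by_chr[chrom] = (pos[order], grp["probe_id"].to_numpy()[order])

    mapping: dict[str, set[str]] = {}
    for row in genes.itertuples(index=False):
        chrom = str(row.chr)
        hits: set[str] = set()
        if chrom in by_chr:
            pos, ids = by_chr[chrom]
            lo = np.searchsorted(pos, row.start, side="left")
            hi = np.searchsorted(pos, row.end, side="right")
            hits = set(ids[lo:hi])
        mapping.setdefault(str(row.gene), set()).update(hits)
    return mapping


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return _validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    _validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chr": str})


def genes_to_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Export gene intervals as BED (0-based half-open: start-1, end)."""
    bed = pd.DataFrame({
        "chrom": genes["chr"].astype(str),
        "chromStart": genes["start"].astype(int) - 1,
        "chromEnd": genes["end"].astype(int),
        "name": genes["gene"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
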