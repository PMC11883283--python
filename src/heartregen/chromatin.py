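"""Promoter chromatin-mark annotation of differential transcripts.

Assigns genes to chromatin categories by overlapping a promoter window
around each TSS with two interval sets: a cardiomyocyte-specific histone
H3.3 turnover signal (H3.3-CM) and the active mark H3K27ac. A gene whose
promoter overlaps H3.3-CM is called CM-expressed; one overlapping only
H3K27ac is attributed to other cell types; the rest are 'neither'.
Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "IntervalSet",
    "GeneModelTable",
    "promoter_windows",
    "categorize_genes",
    "read_bed",
    "write_bed",
    "read_gene_models",
]

CATEGORY_H33 = "H3.3_CM"
CATEGORY_K27_ONLY = "K27ac_only"
CATEGORY_NEITHER = "neither"


@dataclass
class IntervalSet:
    """A labeled set of genomic intervals in 0-based half-open coordinates."""

    records: list[tuple[str, int, int, str]]  # (chrom, start, end, name)
    label: str = ""
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.records:
            if start >= end:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} has start >= end"
                )
        self.records = sorted(self.records, key=lambda r: (r[0], r[1], r[2]))
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, _ in self.records:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self._trees = trees

    def __len__(self) -> int:
        return len(self.records)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval on chrom (half-open:
        touching intervals do not overlap)."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


@dataclass(frozen=True)
class GeneModelTable:
    """Per-gene TSS records: identifier, chromosome, TSS (0-based), strand."""

    table: pd.DataFrame  # index gene, columns chrom, tss, strand

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        bad = ~t["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"invalid strand for gene(s) {t.index[bad].tolist()[:5]}"
            )

    def __len__(self) -> int:
        return len(self.table)


def promoter_windows(
    genes: GeneModelTable, upstream: int = 1000, downstream: int = 1000
) -> IntervalSet:
    """Strand-aware promoter windows around each TSS.

    For a + strand gene the window is [TSS - upstream, TSS + downstream);
    for - strand it is mirrored, [TSS - downstream, TSS + upstream).
    Windows are clipped at coordinate 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("promoter window cannot be empty")
    records = []
    for gene, row in genes.table.iterrows():
        tss = int(row["tss"])
        if row["strand"] == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        records.append((str(row["chrom"]), max(0, start), end, str(gene)))
    return IntervalSet(records, label="promoters")


def categorize_genes(
    promoters: IntervalSet,
    h33: IntervalSet,
    k27ac: IntervalSet,
    gene_subset: list[str],
) -> tuple[pd.DataFrame, dict]:
    """Assign each gene in ``gene_subset`` a promoter chromatin category.

    Categories: H3.3_CM (promoter overlaps any H3.3-CM interval, regardless
    of H3K27ac), K27ac_only (overlaps H3K27ac but not H3.3-CM), neither.
    Overlap is any shared base (>= 1 bp, half-open semantics).

    Returns
    -------
    (table, summary): ``table`` indexed by gene with columns category,
    chrom, start, end; ``summary`` has counts, fractions of the subset,
    and an ``unresolved`` list of subset genes with no promoter record.
    """
    by_gene = {name: (chrom, start, end) for chrom, start, end, name in promoters.records}
    rows = []
    unresolved = []
    for gene in gene_subset:
        if gene not in by_gene:
            unresolved.append(gene)
            continue
        chrom, start, end = by_gene[gene]
        if h33.overlaps(chrom, start, end):
            cat = CATEGORY_H33
        elif k27ac.overlaps(chrom, start, end):
            cat = CATEGORY_K27_ONLY
        else:
            cat = CATEGORY_NEITHER
        rows.append({"gene": gene, "category": cat, "chrom": chrom, "start": start, "end": end})
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["category", "chrom", "start", "end"]
    )
    n = len(table)
    counts = {
        cat: int((table["category"] == cat).sum()) if n else 0
        for cat in (CATEGORY_H33, CATEGORY_K27_ONLY, CATEGORY_NEITHER)
    }
    summary = {
        "n_genes": n,
        "counts": counts,
        "fractions": {cat: (c / n if n else 0.0) for cat, c in counts.items()},
        "unresolved": unresolved,
    }
    return table, summary


# ---------------------------------------------------------------------------
# I/O (BED3+ and TSV gene models)

def read_bed(path, label: str = "") -> IntervalSet:
    """Strict BED3+ reader; malformed lines raise with their line number."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval {start}-{end}")
            name = parts[3] if len(parts) > 3 else ""
            records.append((chrom, start, end, name))
    return IntervalSet(records, label=label or str(path))


def write_bed(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in ivs.records:
            fields = [chrom, str(start), str(end)] + ([name] if name else [])
            fh.write("\t".join(fields) + "\n")


def read_gene_models(path) -> GeneModelTable:
    """Read a TSV with columns gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"gene model table missing column(s): {sorted(missing)}")
    return GeneModelTable(df.set_index("gene"))
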