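"""FPKM-based expression categorization and census.

Family members are binned into three categories: expressed (FPKM >= 1,
boundary inclusive), extremely weakly expressed (0 < FPKM < 1) and not
expressed (FPKM = 0).  A configurable "preferentially expressed" flag marks
genes far above the within-species expressed median (the study's
"one or several genes with very high expression" observation, made
computable with an explicit threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ExpressionRecord", "fpkm", "categorize", "category_census",
    "preferential_flags", "load_expression_table",
]

CATEGORIES = ("expressed", "weak", "silent")


@dataclass
class ExpressionRecord:
    gene_id: str
    fpkm: float
    category: str
    preferential: bool = False


def fpkm(read_count: int, transcript_length: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if read_count < 0:
        raise ValueError("negative read count")
    if transcript_length <= 0 or library_size <= 0:
        raise ValueError("transcript length and library size must be positive")
    return read_count * 1e9 / (library_size * transcript_length)


def categorize(value: float) -> str:
    if value < 0:
        raise ValueError("negative FPKM")
    if value >= 1.0:
        return "expressed"
    if value > 0.0:
        return "weak"
    return "silent"


def make_records(fpkm_by_gene: dict[str, float]) -> list[ExpressionRecord]:
    return [ExpressionRecord(g, v, categorize(v))
            for g, v in fpkm_by_gene.items()]


def category_census(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Counts and percentages (2 decimals) per category; sums to n / 100%."""
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    n = len(records)
    return pd.DataFrame({
        "category": list(CATEGORIES),
        "count": [counts[c] for c in CATEGORIES],
        "pct": [round(100.0 * counts[c] / n, 2) if n else 0.0
                for c in CATEGORIES],
    })


def preferential_flags(records: list[ExpressionRecord],
                       tau: float = 10.0) -> list[ExpressionRecord]:
    """Flag genes with FPKM >= tau x median FPKM of expressed records.

    The records passed in should belong to one species' family members; with
    no expressed gene every flag is False.
    """
    expressed = sorted(r.fpkm for r in records if r.category == "expressed")
    if not expressed:
        for r in records:
            r.preferential = False
        return records
    mid = len(expressed) // 2
    median = (expressed[mid] if len(expressed) % 2 == 1
              else (expressed[mid - 1] + expressed[mid]) / 2)
    for r in records:
        r.preferential = r.fpkm >= tau * median
    return records


def load_expression_table(path, library_size: int | None = None,
                          ) -> dict[str, float]:
    """Read a TSV of (gene, fpkm) or (gene, count, length) + library size."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "fpkm" in cols:
        return dict(zip(df[cols["gene_id"] if "gene_id" in cols else df.columns[0]],
                        df[cols["fpkm"]].astype(float)))
    if "count" in cols and "length" in cols:
        if library_size is None:
            raise ValueError("library_size required for count tables")
        gene_col = cols.get("gene_id", df.columns[0])
        return {
            g: fpkm(int(c), int(l), library_size)
            for g, c, l in zip(df[gene_col], df[cols["count"]], df[cols["length"]])
        }
    raise ValueError("expression table needs fpkm or count+length columns")
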