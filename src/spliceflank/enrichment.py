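"""Gene-level aggregation, enrichment statistics and conservation summaries.

Per-gene junction-variant counts are normalised by exon count (genes with many
exons would otherwise dominate), the top genes are ranked, gene-set overlaps
are tested with the hypergeometric upper tail, LOEUF constraint bins are
compared between datasets with a chi-square test, tissue distributions with
Kruskal-Wallis, and per-site conservation scores are summarised by quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, ValidationError
from .junctions import POSITIONS
from .variants import AnnotatedJunctionVariant

LOEUF_BIN_EDGES = (0.33, 0.66, 1.0)
LOEUF_BIN_LABELS = ("<0.33", "0.33-0.66", "0.66-1", ">=1")


@dataclass
class GeneSummary:
    gene_id: str
    exon_count: int
    counts: dict[str, int] = field(default_factory=dict)  # per position label
    loeuf: float | None = None
    memberships: frozenset[str] = frozenset()

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def per_exon(self, position: str | None = None) -> float:
        count = self.total if position is None else self.counts.get(position, 0)
        return count / self.exon_count

    @property
    def total_per_exon(self) -> float:
        return self.per_exon()


@dataclass
class EnrichmentResult:
    set_name: str
    universe_size: int
    set_size: int
    draws: int
    overlap: int
    p_value: float


def per_exon_gene_scores(
    annotated: Iterable[AnnotatedJunctionVariant],
    gene_exon_counts: Mapping[str, int],
    loeuf: Mapping[str, float] | None = None,
    gene_sets: Mapping[str, set[str]] | None = None,
) -> list[GeneSummary]:
    """Unique-variant counts per gene per position, normalised by exon count.

    Genes present in ``gene_exon_counts`` but without variants appear with
    all-zero counts.  A variant mapping to labels in two genes counts in each
    gene's tally.
    """
    counts: dict[str, dict[str, int]] = {}
    seen: set[tuple] = set()
    for av in annotated:
        for gene in av.site.gene_ids:
            key = (gene, av.key, av.position_label)
            if key in seen:
                continue
            seen.add(key)
            counts.setdefault(gene, {}).setdefault(av.position_label, 0)
            counts[gene][av.position_label] += 1
    missing = sorted(set(counts) - set(gene_exon_counts))
    if missing:
        raise ValidationError(f"genes without exon counts: {missing[:10]}")
    summaries = []
    for gene in sorted(gene_exon_counts):
        summaries.append(
            GeneSummary(
                gene_id=gene,
                exon_count=int(gene_exon_counts[gene]),
                counts={p: counts.get(gene, {}).get(p, 0) for p in POSITIONS},
                loeuf=None if loeuf is None else loeuf.get(gene),
                memberships=frozenset(
                    name
                    for name, members in (gene_sets or {}).items()
                    if gene in members
                ),
            )
        )
    return summaries


def rank_top_genes(
    summaries: Sequence[GeneSummary],
    m: int = 100,
    key: str = "total_per_exon",
    floor: float | None = 0.4,
) -> list[GeneSummary]:
    """Top ``m`` genes by per-exon normalised count, highest first.

    ``key`` is ``total_per_exon`` or one of the position labels.  Genes at or
    below ``floor`` are dropped.  Ties break by larger raw count, then gene_id,
    so the order is a total order independent of input order.
    """
    if key != "total_per_exon" and key not in POSITIONS:
        raise ValidationError(f"unknown ranking key {key!r}")
    position = None if key == "total_per_exon" else key

    def score(s: GeneSummary) -> float:
        return s.per_exon(position)

    pool = [s for s in summaries if floor is None or score(s) > floor]
    pool.sort(key=lambda s: (-score(s), -s.total, s.gene_id))
    return pool[:m]


def hypergeom_overlap(
    genes_selected: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric P[X >= k] for the overlap of two gene lists."""
    universe = set(universe)
    selected = set(genes_selected)
    members = set(gene_set)
    if not members <= universe:
        raise ValidationError("gene set is not a subset of the universe")
    if not selected <= universe:
        raise ValidationError("selected genes are not a subset of the universe")
    big_n, big_k, n = len(universe), len(members), len(selected)
    k = len(selected & members)
    # sf(k-1) is the survival function at k-1, i.e. P[X >= k]; log-stable in scipy
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        set_name=set_name,
        universe_size=big_n,
        set_size=big_k,
        draws=n,
        overlap=k,
        p_value=p,
    )


def loeuf_bin(value: float) -> str:
    """Left-closed constraint bins: [0,0.33), [0.33,0.66), [0.66,1), [1,inf)."""
    for edge, label in zip(LOEUF_BIN_EDGES, LOEUF_BIN_LABELS):
        if value < edge:
            return label
    return LOEUF_BIN_LABELS[-1]


def loeuf_bin_table(
    ranked_lists: Mapping[str, Sequence[str]],
    loeuf_table: Mapping[str, float],
    m: int = 100,
) -> pd.DataFrame:
    """Constraint-bin counts of the top ``m`` ranked genes per dataset.

    Genes absent from the LOEUF table are excluded from the bins and counted
    in the ``missing`` column.
    """
    rows = {}
    for dataset, genes in ranked_lists.items():
        top = list(genes)[:m]
        counts = {label: 0 for label in LOEUF_BIN_LABELS}
        missing = 0
        for gene in top:
            value = loeuf_table.get(gene)
            if value is None:
                missing += 1
            else:
                counts[loeuf_bin(float(value))] += 1
        counts["missing"] = missing
        rows[dataset] = counts
    return pd.DataFrame.from_dict(rows, orient="index")[
        list(LOEUF_BIN_LABELS) + ["missing"]
    ]


def low_loeuf_contingency(
    bin_table: pd.DataFrame, boundary: str = "0.66"
) -> np.ndarray:
    """2 x d table of (low, high) constraint gene counts per dataset."""
    if boundary == "0.66":
        low_cols = ["<0.33", "0.33-0.66"]
    elif boundary == "1":
        low_cols = ["<0.33", "0.33-0.66", "0.66-1"]
    else:
        raise ValidationError(f"unsupported boundary {boundary!r}")
    high_cols = [c for c in LOEUF_BIN_LABELS if c not in low_cols]
    low = bin_table[low_cols].sum(axis=1).to_numpy()
    high = bin_table[high_cols].sum(axis=1).to_numpy()
    return np.vstack([low, high])


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    Yates continuity correction is applied iff the table is 2x2, matching the
    default of the classical R implementation.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValidationError("need an r x c table with r, c >= 2")
    total = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total if total else None
    if expected is None or (expected <= 0).any():
        raise DegenerateTableError("zero expected cell count")
    correction = arr.shape == (2, 2)
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = groups - 1)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("every group needs at least one value")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations tied: H defined as 0, no evidence of difference
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def conservation_summary(
    annotated: Sequence[AnnotatedJunctionVariant],
    score_table: Mapping[tuple[str, int], float],
) -> pd.DataFrame:
    """Median and quartiles of per-site conservation scores, per position x dataset.

    Scores must lie in [0, 1] (conservation probabilities).  Sites lacking a
    score are excluded and counted.  Quantiles use linear interpolation.
    """
    for key, value in score_table.items():
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"conservation score {value} at {key} outside [0,1]")
    per_cell: dict[tuple[str, str], dict[tuple, float | None]] = {}
    for av in annotated:
        cell = (av.position_label, av.variant.dataset)
        score = score_table.get((av.site.contig, av.site.genomic_position))
        per_cell.setdefault(cell, {})[av.site_key] = score
    rows = []
    for (position, dataset), sites in sorted(per_cell.items()):
        scored = [s for s in sites.values() if s is not None]
        n_missing = sum(1 for s in sites.values() if s is None)
        if scored:
            q1, med, q3 = np.percentile(scored, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append(
            {
                "position": position,
                "dataset": dataset,
                "n_sites": len(scored),
                "n_missing": n_missing,
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
            }
        )
    return pd.DataFrame(rows)


def gene_summary_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"gene": s.gene_id, "exon_count": s.exon_count}
        for p in POSITIONS:
            row[p] = s.counts.get(p, 0)
            row[f"{p}_per_exon"] = s.per_exon(p)
        row["total"] = s.total
        row["total_per_exon"] = s.total_per_exon
        row["loeuf"] = s.loeuf
        row["sets"] = ",".join(sorted(s.memberships))
        rows.append(row)
    return pd.DataFrame(rows)
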