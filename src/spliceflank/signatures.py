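"""Composition and substitution-spectrum tables.

Two counting conventions coexist and are kept explicit: composition tables
count *sites* (unique genomic positions, once each regardless of how many
alternate alleles were seen there), substitution matrices count *unique
variants* (contig, pos, ref, alt).  Percentages are written to one decimal
with round-half-even.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyInputError, UndefinedPercentageError, ValidationError
from .junctions import BASES, POSITIONS, SiteIndex
from .variants import CONSEQUENCES, SUBSTITUTIONS, AnnotatedJunctionVariant


@dataclass
class CompositionTable:
    """Per position-label x base counts on the coding strand."""

    counts: pd.DataFrame  # index POSITIONS, columns BASES, integer counts
    scope: str  # genome_background | variant_sites

    @property
    def fractions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        frac = self.counts.div(totals.where(totals > 0), axis=0)
        return frac

    def fraction(self, position: str, base: str) -> float:
        return float(self.fractions.loc[position, base])


@dataclass
class SubstitutionMatrix:
    """Per position-label x 12 ordered coding-strand substitutions, unique-variant counts."""

    combined: pd.DataFrame
    silent: pd.DataFrame | None = None
    missense: pd.DataFrame | None = None


def _empty_counts(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(0, index=list(POSITIONS), columns=list(columns), dtype=int)


def background_composition(site_index: SiteIndex) -> CompositionTable:
    """Coding-strand base counts per position over all non-redundant sites."""
    if len(site_index) == 0:
        raise EmptyInputError("empty site index")
    counts = _empty_counts(BASES)
    for site in site_index:
        counts.loc[site.label, site.ref_base] += 1
    return CompositionTable(counts=counts, scope="genome_background")


def variant_site_composition(
    annotated: Iterable[AnnotatedJunctionVariant],
) -> CompositionTable:
    """Base counts over unique sites carrying at least one variant.

    A site with two alternate alleles contributes once.
    """
    counts = _empty_counts(BASES)
    seen: set[tuple] = set()
    for av in annotated:
        if av.site_key in seen:
            continue
        seen.add(av.site_key)
        counts.loc[av.position_label, av.coding_ref] += 1
    return CompositionTable(counts=counts, scope="variant_sites")


def substitution_matrix(
    annotated: Iterable[AnnotatedJunctionVariant],
    split_by_consequence: bool = False,
) -> SubstitutionMatrix:
    """Unique-variant counts per (position, substitution).

    Only silent and missense variants are tallied; a variant that maps to
    junction labels in several genes counts once per (variant, position label).
    """
    combined = _empty_counts(SUBSTITUTIONS)
    silent = _empty_counts(SUBSTITUTIONS)
    missense = _empty_counts(SUBSTITUTIONS)
    seen: set[tuple] = set()
    for av in annotated:
        if av.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {av.consequence!r}")
        if av.consequence not in ("silent", "missense"):
            continue
        key = (av.key, av.position_label, av.site.strand)
        if key in seen:
            continue
        seen.add(key)
        combined.loc[av.position_label, av.substitution] += 1
        target = silent if av.consequence == "silent" else missense
        target.loc[av.position_label, av.substitution] += 1
    if split_by_consequence:
        return SubstitutionMatrix(combined=combined, silent=silent, missense=missense)
    return SubstitutionMatrix(combined=combined)


def consequence_proportions(
    annotated: Sequence[AnnotatedJunctionVariant], site_index: SiteIndex
) -> pd.DataFrame:
    """Per position: % of sites bearing a variant, and the missense/silent split.

    ``pct_missense + pct_silent == 100`` among silent+missense variants.
    """
    if not annotated or len(site_index) == 0:
        raise EmptyInputError("need both annotated variants and a site index")
    total_sites = {p: 0 for p in POSITIONS}
    for site in site_index:
        total_sites[site.label] += 1

    bearing: dict[str, set] = {p: set() for p in POSITIONS}
    n_missense = {p: 0 for p in POSITIONS}
    n_silent = {p: 0 for p in POSITIONS}
    seen_variants: set[tuple] = set()
    for av in annotated:
        label = av.position_label
        bearing[label].add(av.site_key)
        vkey = (av.key, label, av.site.strand)
        if vkey in seen_variants:
            continue
        seen_variants.add(vkey)
        if av.consequence == "missense":
            n_missense[label] += 1
        elif av.consequence == "silent":
            n_silent[label] += 1

    rows = []
    for p in POSITIONS:
        if total_sites[p] == 0:
            if bearing[p]:
                raise UndefinedPercentageError(
                    f"variants observed at position {p} but the index has no "
                    f"{p} sites"
                )
            continue  # position absent from this annotation
        n_sm = n_missense[p] + n_silent[p]
        rows.append(
            {
                "position": p,
                "n_sites": total_sites[p],
                "n_sites_with_variant": len(bearing[p]),
                "pct_sites_with_variant": 100.0 * len(bearing[p]) / total_sites[p],
                "n_missense": n_missense[p],
                "n_silent": n_silent[p],
                "pct_missense": 100.0 * n_missense[p] / n_sm if n_sm else float("nan"),
                "pct_silent": 100.0 * n_silent[p] / n_sm if n_sm else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("position")


def round_percent(value: float) -> float:
    """One-decimal percentage with banker's (round-half-even) rounding."""
    from decimal import ROUND_HALF_EVEN, Decimal

    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))
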