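"""Reference tallies reported for the full-scale COSMIC v98 / GENCODE v43 study.

These printed counts are inputs for arithmetic cross-checks and documented
reference patterns; they are not desk-reproducible without the full database
downloads and are never used as fitted values anywhere in the package.
"""

#: Unique silent+missense SNVs per exonic flank position in COSMIC v98.
UNIQUE_SNV_COUNTS: dict[str, int] = {
    "d1": 30738,
    "d2": 19008,
    "d3": 19642,
    "a1": 20863,
    "a2": 18083,
    "a3": 20317,
}

#: Total exonic splice-junction sites carried through the predictor stages.
PIPELINE_TOTAL_SNVS: int = 128651

#: ClinVar classification counts of the d1 COSMIC variants.
CLINVAR_D1: dict[str, int] = {
    "total": 1584,
    "pathogenic_or_likely": 261,
    "benign_or_likely": 103,
    "uncertain": 1020,
}

#: SpliceVarDB outcome percentages of the d1 variants found in that database.
SPLICEVARDB_D1_PCT: dict[str, float] = {
    "splice_altering": 47.0,
    "low_frequency": 43.0,
    "normal": 10.0,
}

#: Headline composition/constraint figures, for documentation and sanity
#: checks of synthetic defaults (not test targets).
HEADLINE = {
    "d1_G_fraction_background": 0.80,
    "d1_G_fraction_variant_sites": 0.87,
    "a1_G_fraction_background": 0.49,
    "a1_G_fraction_variant_sites": 0.69,
    "d1_missense_pct": 78.0,
    "d1_G>T_count": 12176,
    "d1_G>A_count": 12071,
    "auc": {"spliceai": 0.9, "pangolin": 0.9, "maxentscan": 0.9, "spip": 0.87, "cadd": 0.74},
}
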