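"""Default feature schema: 5 statistics + 28 annotation features = 33 predictors.

The schema is configuration, not code: any ordered name list is accepted by
:func:`deepgwas.annotations.assemble_features` and the network, provided the
model input width agrees. The default ships the canonical composition —
GWAS statistics (−log10 p, OR), population genetics (MAF, two LD scores),
one eQTL membership flag, three pathogenic scores, adult/fetal open
chromatin, adult/fetal FIREs and super FIREs, selective sweeps, five cCRE
marks, eleven Jaccard-clustered epigenomic meta-annotations, and one
user-configurable slot.
"""

STAT_FEATURES: list[str] = [
    "neglog10_p",
    "odds_ratio",
    "maf",
    "ld_score_overall",
    "ld_score_known",
]

META_ANNOTATIONS: list[str] = [f"meta_{i:02d}" for i in range(1, 12)]

ANNOTATION_FEATURES: list[str] = [
    "eqtl",
    "phylop",
    "fathmm_xf",
    "cadd_phred",
    "open_chromatin_adult",
    "open_chromatin_fetal",
    "fire_adult",
    "fire_fetal",
    "superfire_adult",
    "superfire_fetal",
    "selective_sweep",
    "ccre_dhs",
    "ccre_h3k27ac",
    "ccre_h3k4me3",
    "ccre_ctcf",
    "ccre_tf",
    *META_ANNOTATIONS,
    "user_slot",
]

DEFAULT_SCHEMA: list[str] = STAT_FEATURES + ANNOTATION_FEATURES

assert len(ANNOTATION_FEATURES) == 28
assert len(DEFAULT_SCHEMA) == 33

# Binary interval tracks in the default schema, in schema order.
DEFAULT_INTERVAL_FEATURES: list[str] = [
    "open_chromatin_adult",
    "open_chromatin_fetal",
    "fire_adult",
    "fire_fetal",
    "superfire_adult",
    "superfire_fetal",
    "selective_sweep",
    "ccre_dhs",
    "ccre_h3k27ac",
    "ccre_h3k4me3",
    "ccre_ctcf",
    "ccre_tf",
]

# Per-variant continuous score tracks (pathogenicity) in the default schema.
DEFAULT_SCORE_FEATURES: list[str] = ["phylop", "fathmm_xf", "cadd_phred"]
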