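"""Published summary tables from a truffle multi-omics sequencing study.

These are printed reference numbers used as inputs for the toolkit's
arithmetic (mapability from read counts, fold changes from RPKM pairs).
RPKM values below were published rounded, so recomputed fold changes can
differ from the printed ones by input rounding alone; see
``fold_change_bounds`` for the attainable interval given that rounding.

``LIBRARY_COUNTS``: (sample, platform, raw_reads, uniquely_mapped,
printed_mapability_percent, read_length_bp). The two 5-aza BS-seq rows
print mapability percentages that are not reproducible from the printed
counts (presumably computed on QC-filtered reads) and are flagged.
"""

from __future__ import annotations

LIBRARY_COUNTS = [
    # sample, platform, raw, unique, printed %, read len, counts_consistent
    ("FLM", "BS-seq", 122_903_319, 78_983_505, 64.26, 100, True),
    ("FB", "BS-seq", 184_692_678, 86_778_157, 46.99, 100, True),
    ("ECM", "BS-seq", 182_286_685, 3_268_721, 1.79, 90, True),
    ("5-aza treated", "BS-seq", 99_836_913, 41_349_427, 70.48, 51, False),
    ("5-aza untreated", "BS-seq", 84_315_198, 35_348_536, 70.19, 51, False),
    ("FLM", "WG-seq", 57_386_669, 45_239_191, 78.83, 51, True),
    ("FB", "WG-seq", 70_844_918, 50_646_551, 71.49, 51, True),
    ("FLM", "RNA-seq", 68_287_049, 63_751_666, 93.36, 50, True),
    ("FB", "RNA-seq", 87_310_639, 74_090_987, 84.86, 50, True),
    ("5-aza treated", "RNA-seq", 72_050_137, 60_644_746, 84.17, 51, True),
    ("5-aza untreated", "RNA-seq", 75_043_437, 62_107_389, 82.76, 51, True),
]

#: (gene_id, rpkm_untreated, rpkm_treated, printed_fold_change) for genes
#: differentially expressed between untreated and 5-aza treated mycelia
AZA_FOLD_CHANGES = [
    ("GSTUMT00004482001", 8, 258, 33.80),
    ("GSTUMT00009102001", 18, 196, 10.71),
    ("GSTUMT00002834001", 47, 414, 8.84),
    ("GSTUMT00006862001", 4355, 34021, 7.81),
    ("GSTUMT00005793001", 1590, 8041, 5.06),
    ("GSTUMT00000137001", 3, 17, 5.06),
    ("GSTUMT00006911001", 19, 90, 4.64),
    ("GSTUMT00008228001", 34, 147, 4.35),
    ("GSTUMT00002706001", 4, 14, 3.61),
    ("GSTUMT00000322001", 137, 48, 0.35),
    ("GSTUMT00000528001", 334, 110, 0.33),
    ("GSTUMT00007846001", 172, 56, 0.33),
    ("GSTUMT00002653001", 104, 31, 0.30),
    ("GSTUMT00000530001", 61, 18, 0.30),
    ("GSTUMT00012134001", 4704, 1368, 0.29),
    ("GSTUMT00000158001", 54, 15, 0.28),
    ("GSTUMT00002858001", 22, 5, 0.25),
    ("GSTUMT00012200001", 71, 15, 0.21),
    ("GSTUMT00001645001", 219, 34, 0.16),
    ("GSTUMT00006980001", 1022, 146, 0.14),
    ("GSTUMT00007117001", 4, 0.4, 0.10),
    ("GSTUMT00001488001", 163, 737, 4.53),
    ("GSTUMT00003668001", 20, 82, 4.03),
    ("GSTUMT00010777001", 16, 66, 4.03),
    ("GSTUMT00008972001", 16, 64, 4.02),
    ("GSTUMT00001400001", 86, 295, 3.44),
    ("GSTUMT00000284001", 1082, 366, 0.34),
    ("GSTUMT00008966001", 27, 9, 0.34),
    ("GSTUMT00000070001", 119, 30, 0.25),
    ("GSTUMT00004586001", 32, 5, 0.17),
    ("GSTUMT00005001001", 663, 84, 0.13),
    ("GSTUMT00005836001", 1, 18, 17.23),
    ("GSTUMT00010369001", 1, 7, 12.50),
    ("GSTUMT00004615001", 2, 10, 6.40),
    ("GSTUMT00004613001", 90, 402, 4.49),
    ("GSTUMT00003504001", 1522, 467, 0.31),
    ("GSTUMT00008986001", 0.2, 5, 25.60),
    ("GSTUMT00001850001", 94, 1499, 16.02),
    ("GSTUMT00012011001", 7, 57, 7.73),
    ("GSTUMT00005539001", 27, 195, 7.18),
    ("GSTUMT00010778001", 230, 1316, 5.72),
    ("GSTUMT00011981001", 298, 1376, 4.62),
    ("GSTUMT00007852001", 166, 704, 4.25),
    ("GSTUMT00003032001", 1222, 4444, 3.64),
    ("GSTUMT00001583001", 273, 968, 3.54),
    ("GSTUMT00005439001", 214, 758, 3.54),
    ("GSTUMT00001660001", 109, 374, 3.43),
    ("GSTUMT00006417001", 417, 1410, 3.38),
    ("GSTUMT00007213001", 74, 239, 3.25),
    ("GSTUMT00002512001", 99, 311, 3.14),
    ("GSTUMT00000969001", 840, 270, 0.32),
    ("GSTUMT00004040001", 54, 209, 3.84),
    ("GSTUMT00007138001", 401, 1134, 2.83),
    ("GSTUMT00004012001", 72, 23, 0.33),
    ("GSTUMT00004681001", 52, 339, 6.53),
    ("GSTUMT00002939001", 361, 1730, 4.80),
    ("GSTUMT00010365001", 8, 39, 4.66),
    ("GSTUMT00006611001", 999, 3827, 3.83),
    ("GSTUMT00006718001", 228, 80, 0.35),
    ("GSTUMT00008071001", 1272, 413, 0.32),
    ("GSTUMT00001676001", 96, 31, 0.32),
    ("GSTUMT00006632001", 3053, 724, 0.24),
]


def _half_ulp(value: float) -> float:
    """Half the printing resolution of a published value."""
    return 0.05 if value != int(value) else 0.5


def fold_change_bounds(rpkm_untreated: float,
                       rpkm_treated: float) -> tuple[float, float]:
    """Attainable fold-change interval given that both published RPKMs were
    rounded to their printing resolution."""
    hu, ht = _half_ulp(rpkm_untreated), _half_ulp(rpkm_treated)
    lo = (rpkm_treated - ht) / (rpkm_untreated + hu)
    hi = (rpkm_treated + ht) / max(rpkm_untreated - hu, 1e-9)
    return lo, hi
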