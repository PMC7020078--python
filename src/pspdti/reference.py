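"""Bundled reference severity equations.

These four linear models — one per clinical scale — are previously
published whole-brain DTI predictive equations for PSP severity, shipped
as data (not as fits): they were estimated on clinical images that are not
publicly available, so they cannot be re-derived here. They serve
equation-evaluation tests, blind-application demos, and as a template for
the export format. Each has eleven terms over FA/MD percentile features
named in the modified-cytoarchitecture grammar.
"""

from __future__ import annotations

from .regression import SeverityModel

_REFERENCE_TERMS: dict[str, tuple[float, list[tuple[str, float]]]] = {
    "UPDRS3": (
        -100.6,
        [
            ("MD50_PhG_L_6_1", 48.7),
            ("MD10_PrG_L_6_2", 51.2),
            ("FA90_GP_L", 28.3),
            ("MD10_Tha_L_8_3", 65.2),
            ("FA90_SPL_R_5_4", -23.9),
            ("FA90_STG_R_6_1", 98.2),
            ("MD10_Amyg_L_2_1", -35.9),
            ("MD10_Tha_L_8_8", 72.8),
            ("MD90_IPL_L_6_2", -18.0),
            ("FA90_VM_Put_R", 35.0),
            ("FA90_MFG_L_7_6", -38.1),
        ],
    ),
    "PIGD": (
        1.2,
        [
            ("MD90_INS_R_6_5", 1.5),
            ("FA10_MTG_R_4_3", 210.7),
            ("FA90_MTG_R_4_3", -49.9),
            ("FA90_MFG_R_7_2", -26.0),
            ("MD90_PrG_R_6_2", 4.1),
            ("FA50_ITG_R_7_2", 28.4),
            ("FA90_MTG_R_4_4", -13.7),
            ("FA90_PoG_L_4_3", 9.3),
            ("MD10_Amyg_R_2_1", -5.5),
            ("MD90_MVOcC_L_5_3", 3.7),
            ("FA10_ITG_L_7_6", 44.6),
        ],
    ),
    "MHY": (
        6.0,
        [
            ("MD50_MFG_L_7_5", -2.8),
            ("FA90_IPL_R_6_4", -6.7),
            ("FA50_NAC_L", 9.5),
            ("FA90_SPL_L_5_3", -3.8),
            ("FA90_Tha_R_8_4", -10.5),
            ("MD10_IFG_R_6_4", -4.9),
            ("FA50_ITG_R_7_2", 6.1),
            ("FA10_ITG_L_7_6", 18.6),
            ("MD10_PrG_L_6_4", 2.0),
            ("MD50_Amyg_L_2_1", -0.6),
            ("FA90_MFG_L_7_6", -2.6),
        ],
    ),
    "LEDD": (
        450.9,
        [
            ("FA90_STG_R_6_1", 2833.7),
            ("MD50_Amyg_R_2_2", -571.6),
            ("MD50_CG_R_7_6", 325.4),
            ("MD90_PhG_L_6_3", -369.4),
            ("FA10_VM_Put_R", -2074.1),
            ("FA50_OrG_R_6_2", 2949.2),
            ("MD10_PrG_L_6_4", 1487.9),
            ("MD10_PoG_L_4_3", -1568.8),
            ("FA90_PCL_R_2_1", -1112.0),
            ("MD50_PoG_R_4_3", 421.3),
            ("FA10_SPL_R_5_4", 5248.2),
        ],
    ),
}


def bundled_reference_models() -> dict[str, SeverityModel]:
    """The four bundled reference models, keyed by clinical scale."""
    out = {}
    for target, (intercept, terms) in _REFERENCE_TERMS.items():
        out[target] = SeverityModel(
            target=target,
            intercept=intercept,
            terms=list(terms),
            cap=11,
            training_n=53,
            provenance="bundled-reference",
        )
    return out
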