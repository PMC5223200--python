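"""Bundled reference datasets.

Published mean-NFI fold-change tables from a rat study of cerebral-cortex
mitochondrial glycoprotein glycopatterns, comparing a sporadic Alzheimer's
disease model (SAD vs its control SAD-C) and a cerebral-ischemia model
(MCAO occlusion for 16 h / 48 h, M16 and M48, vs control MC).  The raw
fluorescence scans are not public; these printed ratio columns are the
recomputable inputs for significance counts and cross-model overlap.
"""

from __future__ import annotations

SAD_CONTRAST = ("SAD", "SAD-C")
M16_CONTRAST = ("M16", "MC")
M48_CONTRAST = ("M48", "MC")

#: SAD/SAD-C mean-NFI ratios of the lectins the study listed as significant.
SAD_RATIOS: dict[str, float] = {
    "PSA": 2.35,
    "WFA": 0.61,
    "PTL-I": 0.22,
    "AAL": 0.42,
    "PTL-II": 0.61,
    "SBA": 0.57,
    "UEA-I": 0.53,
    "PHA-E + L": 0.34,
    "SNA": 0.62,
}

#: (M16/MC, M48/MC) mean-NFI ratio pairs of the lectins listed as
#: significant at either occlusion timepoint.
MCAO_RATIOS: dict[str, tuple[float, float]] = {
    "ECA": (1.99, 2.20),
    "WFA": (2.54, 2.17),
    "PTL-I": (2.66, 1.74),
    "LCA": (2.24, 2.37),
    "VVA": (1.93, 1.75),
    "GNA": (1.94, 2.67),
    "PHA-E + L": (1.68, 1.94),
    "DBA": (1.39, 1.58),
    "PTL-II": (1.35, 1.84),
    "NPA": (1.43, 1.69),
    "SNA": (1.47, 1.60),
    "SJA": (0.40, 0.33),
    "GLS-I": (0.58, 0.77),
    "STL": (0.46, 0.54),
    "ConA": (0.45, 0.45),
    "BPL": (0.55, 0.52),
    "PHA-E": (0.74, 0.64),
    "LEL": (0.70, 0.53),
}


def sad_ratio_table() -> dict[str, float]:
    """SAD-model ratio column (copy)."""
    return dict(SAD_RATIOS)


def mcao_ratio_tables() -> dict[tuple[str, str], dict[str, float]]:
    """MCAO-model ratio columns keyed by contrast (copies)."""
    return {
        M16_CONTRAST: {lec: pair[0] for lec, pair in MCAO_RATIOS.items()},
        M48_CONTRAST: {lec: pair[1] for lec, pair in MCAO_RATIOS.items()},
    }
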