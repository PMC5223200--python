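"""Differential glycan calling and cross-model comparison.

A lectin is called up-regulated when its model/control mean-NFI ratio is
>= 1.5 and down-regulated when it is <= 0.67 (both bounds inclusive,
configurable).  A two-sample pooled-variance Student's t-test on the block
NFI vectors can additionally gate calls; the gate direction is switchable
(``lt``: p < alpha, ``gt``: p > alpha, ``off``: fold change only) because
published fold-change tables are frequently produced without a p filter.
No multiple-testing correction is applied by default; Benjamini-Hochberg
is available as an option.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from glycolect.array_core import LectinAnnotation, Panel
from glycolect.errors import UndefinedRatioError
from glycolect.quantify import GroupProfile

__all__ = [
    "DifferentialCall",
    "CrossModelResult",
    "t_test",
    "classify_ratio",
    "call_lectin",
    "call_table",
    "calls_from_ratios",
    "compare_models",
    "collapse_directions",
    "motif_summary",
    "benjamini_hochberg",
    "UP_THRESHOLD",
    "DOWN_THRESHOLD",
    "MONOSACCHARIDE_TOKENS",
]

UP_THRESHOLD = 1.5
DOWN_THRESHOLD = 0.67

#: Canonical monosaccharide tokens, longest-match first so that "GalNAc"
#: is never double-counted as "Gal" plus a suffix.
MONOSACCHARIDE_TOKENS = ("GalNAc", "GlcNAc", "Gal", "Glc", "Man", "Fuc", "Sia")
_TOKEN_RE = re.compile("|".join(MONOSACCHARIDE_TOKENS))


@dataclass(frozen=True)
class DifferentialCall:
    """One lectin's fold change, p-value and direction for one contrast."""

    lectin: str
    contrast: tuple[str, str]  # (model group, control group)
    ratio: float
    p_value: Optional[float]
    direction: str  # "up" | "down" | "unchanged" | "na"
    specificity: str = ""

    @property
    def significant(self) -> bool:
        return self.direction in ("up", "down")


@dataclass(frozen=True)
class CrossModelResult:
    """Overlap of differential calls between two disease models."""

    direction_a: Mapping[str, str]
    direction_b: Mapping[str, str]
    shared_lectins: tuple[str, ...]
    opposite_lectins: tuple[str, ...]
    motif_summary: tuple[tuple[str, int], ...]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t-test (two-sided).

    Returns ``(t, p)`` with ``n1 + n2 - 2`` degrees of freedom.  Degenerate
    zero-variance input yields ``t=0, p=1`` for equal means and ``p=0``
    (with a warning) for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = x.mean() - y.mean()
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df = n1 + n2 - 2
    pooled_var = ss / df
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0", stacklevel=2)
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return float(t), p


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance alternative (opt-in)."""
    res = _stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def classify_ratio(ratio: float, up: float = UP_THRESHOLD,
                   down: float = DOWN_THRESHOLD) -> str:
    """Fold-change-only direction: inclusive thresholds on both sides."""
    if not math.isfinite(ratio) or ratio <= 0:
        return "na"
    if ratio >= up:
        return "up"
    if ratio <= down:
        return "down"
    return "unchanged"


def _gate(p_value: Optional[float], p_gate: str, alpha: float) -> bool:
    if p_gate == "off":
        return True
    if p_value is None:
        raise ValueError("p-gate requested but no p-value available")
    if p_gate == "lt":
        return p_value < alpha
    if p_gate == "gt":
        return p_value > alpha
    raise ValueError(f"p_gate must be 'lt', 'gt' or 'off', got {p_gate!r}")


def call_lectin(
    model: GroupProfile,
    control: GroupProfile,
    lectin: str,
    *,
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
    p_gate: str = "lt",
    alpha: float = 0.05,
    specificity: str = "",
    welch: bool = False,
) -> DifferentialCall:
    """Call one lectin for the contrast ``model`` vs ``control``."""
    if lectin not in model.mean_nfi or lectin not in control.mean_nfi:
        raise KeyError(f"lectin {lectin!r} missing from a group profile")
    mean_c = control.mean_nfi[lectin]
    if mean_c == 0:
        raise UndefinedRatioError(
            f"{lectin}: control group {control.group_id!r} mean NFI is zero"
        )
    ratio = model.mean_nfi[lectin] / mean_c
    test = welch_t_test if welch else t_test
    _, p = test(model.blocks_for(lectin), control.blocks_for(lectin))
    direction = classify_ratio(ratio, up, down)
    if direction in ("up", "down") and not _gate(p, p_gate, alpha):
        direction = "unchanged"
    return DifferentialCall(
        lectin, (model.group_id, control.group_id), ratio, p, direction, specificity
    )


def call_table(
    profiles: Mapping[str, GroupProfile],
    contrasts: Sequence[tuple[str, str]],
    panel: Panel,
    *,
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
    p_gate: str = "lt",
    alpha: float = 0.05,
    fdr: str = "none",
    welch: bool = False,
) -> list[DifferentialCall]:
    """One call per panel lectin per contrast, in stable panel order.

    Per-lectin failures (missing lectin, zero control mean) propagate as
    ``direction='na'`` rows rather than aborting the table.  ``fdr='bh'``
    replaces p-values with Benjamini-Hochberg adjusted ones per contrast
    before gating.
    """
    for model_id, control_id in contrasts:
        for gid in (model_id, control_id):
            if gid not in profiles:
                raise KeyError(f"contrast references unknown group {gid!r}")
    if fdr not in ("none", "bh"):
        raise ValueError(f"fdr must be 'none' or 'bh', got {fdr!r}")

    calls: list[DifferentialCall] = []
    for model_id, control_id in contrasts:
        model, control = profiles[model_id], profiles[control_id]
        contrast_calls: list[DifferentialCall] = []
        for lec in panel.names:
            spec = panel.get(lec).specificity
            try:
                contrast_calls.append(
                    call_lectin(
                        model, control, lec,
                        up=up, down=down, p_gate="off", alpha=alpha,
                        specificity=spec, welch=welch,
                    )
                )
            except (KeyError, UndefinedRatioError):
                contrast_calls.append(
                    DifferentialCall(lec, (model_id, control_id),
                                     float("nan"), None, "na", spec)
                )
        if fdr == "bh":
            idx = [i for i, c in enumerate(contrast_calls) if c.p_value is not None]
            adj = benjamini_hochberg([contrast_calls[i].p_value for i in idx])
            for i, p_adj in zip(idx, adj):
                contrast_calls[i] = replace(contrast_calls[i], p_value=float(p_adj))
        # apply the gate after any adjustment
        for c in contrast_calls:
            if c.significant and not _gate(c.p_value, p_gate, alpha):
                c = replace(c, direction="unchanged")
            calls.append(c)
    return calls


def calls_from_ratios(
    ratios: Mapping[str, float],
    contrast: tuple[str, str],
    panel: Optional[Panel] = None,
    *,
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
) -> list[DifferentialCall]:
    """Build fold-change-only calls from a published ratio column.

    Used to re-derive significance counts and cross-model overlaps from
    printed ratio tables when raw fluorescence data are unavailable; the
    p-gate is necessarily off.
    """
    calls = []
    order = [n for n in (panel.names if panel is not None else ratios) if n in ratios]
    for lec in order:
        spec = panel.get(lec).specificity if panel is not None else ""
        calls.append(
            DifferentialCall(lec, contrast, float(ratios[lec]), None,
                             classify_ratio(ratios[lec], up, down), spec)
        )
    return calls


# ---------------------------------------------------------------------------
# Cross-model comparison
# ---------------------------------------------------------------------------

def collapse_directions(calls: Sequence[DifferentialCall]) -> dict[str, str]:
    """Per-lectin direction across contrasts/timepoints of one model.

    A lectin counts as up (down) if called up (down) in *any* contrast;
    conflicting up+down calls collapse to ``"mixed"``.
    """
    per_lectin: dict[str, set[str]] = {}
    for c in calls:
        per_lectin.setdefault(c.lectin, set()).add(c.direction)
    out = {}
    for lec, dirs in per_lectin.items():
        if "up" in dirs and "down" in dirs:
            out[lec] = "mixed"
        elif "up" in dirs:
            out[lec] = "up"
        elif "down" in dirs:
            out[lec] = "down"
        else:
            out[lec] = "unchanged"
    return out


def compare_models(
    calls_a: Sequence[DifferentialCall],
    calls_b: Sequence[DifferentialCall],
    panel: Optional[Panel] = None,
) -> CrossModelResult:
    """Shared and opposite-direction lectins between two models.

    ``shared`` = significant in both models; ``opposite`` = shared with
    strictly opposite up/down directions.  Either side may hold several
    contrasts (timepoints); membership is "significant at any timepoint".
    """
    if not calls_a or not calls_b:
        raise ValueError("both call lists must be nonempty")
    dir_a = collapse_directions(calls_a)
    dir_b = collapse_directions(calls_b)
    if not set(dir_a) & set(dir_b):
        raise ValueError("call lists share no lectins; disjoint panels?")

    if panel is not None:
        order = [n for n in panel.names if n in dir_a and n in dir_b]
    else:
        order = [n for n in dir_a if n in dir_b]

    sig = ("up", "down", "mixed")
    shared = tuple(l for l in order if dir_a[l] in sig and dir_b[l] in sig)
    opposite = tuple(l for l in shared if {dir_a[l], dir_b[l]} == {"up", "down"})

    spec_by_lectin: dict[str, str] = {}
    for c in list(calls_a) + list(calls_b):
        if c.specificity:
            spec_by_lectin.setdefault(c.lectin, c.specificity)
    annotations = [
        LectinAnnotation(l, spec_by_lectin.get(l, "")) for l in opposite
    ]
    motifs = motif_summary(annotations) if annotations else ()
    return CrossModelResult(dir_a, dir_b, shared, opposite, tuple(motifs))


def motif_summary(lectins: Sequence[LectinAnnotation]) -> list[tuple[str, int]]:
    """Count how many lectins mention each monosaccharide token.

    Longest-match tokenization of the specificity strings; returns
    ``(token, n_lectins)`` pairs sorted by descending count (ties in
    canonical token order).  Empty specificity strings contribute nothing.
    """
    if not lectins:
        raise ValueError("motif_summary requires at least one lectin")
    counts = {tok: 0 for tok in MONOSACCHARIDE_TOKENS}
    for lec in lectins:
        for tok in set(_TOKEN_RE.findall(lec.specificity)):
            counts[tok] += 1
    present = [(tok, n) for tok, n in counts.items() if n > 0]
    rank = {tok: i for i, tok in enumerate(MONOSACCHARIDE_TOKENS)}
    present.sort(key=lambda kv: (-kv[1], rank[kv[0]]))
    return present
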