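"""Standardized mean differences for bleached-vs-healthy fish comparisons.

Each comparison supplies group summaries (mean, SD, n) for a fish response —
species richness, abundance, recruitment, or a family-specific abundance —
on bleached (treatment) versus healthy (control) reefs.  The effect size is
Hedges' d, the small-sample-corrected standardized mean difference:

    s_p² = ((n_t − 1) s_t² + (n_c − 1) s_c²) / (n_t + n_c − 2)
    d    = J · (m_t − m_c) / s_p,    J = 1 − 3 / (4 (n_t + n_c − 2) − 1)
    var  = (n_t + n_c) / (n_t n_c) + d² / (2 (n_t + n_c))

Effects are pooled per response class with DerSimonian–Laird random-effects
weighting (between-study variance τ² estimated from Cochran's Q, truncated
at zero); a fixed-effect option sets τ² = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonRecord",
    "EffectSize",
    "PooledEffect",
    "hedges_d",
    "pool_random_effects",
    "summarize_by_class",
    "read_comparisons_csv",
]

RESPONSE_CLASSES = ("richness", "abundance", "recruitment", "family_abundance")


@dataclass(frozen=True)
class ComparisonRecord:
    """One bleached-vs-healthy group comparison extracted from a study."""

    study_id: str
    response_class: str
    mean_treat: float
    sd_treat: float
    n_treat: int
    mean_ctrl: float
    sd_ctrl: float
    n_ctrl: int
    family: str | None = None

    def __post_init__(self) -> None:
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response class {self.response_class!r}")
        if self.sd_treat < 0 or self.sd_ctrl < 0:
            raise ValueError("SDs must be non-negative")
        if self.n_treat < 2 or self.n_ctrl < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class EffectSize:
    d: float
    variance: float
    record_ref: str


@dataclass(frozen=True)
class PooledEffect:
    response_class: str
    family: str | None
    d: float
    se: float
    tau2: float
    k: int


def hedges_d(rec: ComparisonRecord) -> EffectSize:
    """Hedges' d and its sampling variance for one comparison.

    Raises
    ------
    ValueError
        If the pooled SD is zero (the effect is undefined).
    """
    nt, nc = rec.n_treat, rec.n_ctrl
    df = nt + nc - 2
    s_pooled2 = ((nt - 1) * rec.sd_treat**2 + (nc - 1) * rec.sd_ctrl**2) / df
    if s_pooled2 <= 0:
        raise ValueError(
            f"{rec.study_id}: zero pooled SD, standardized difference undefined"
        )
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = J * (rec.mean_treat - rec.mean_ctrl) / np.sqrt(s_pooled2)
    variance = (nt + nc) / (nt * nc) + d**2 / (2.0 * (nt + nc))
    return EffectSize(d=float(d), variance=float(variance), record_ref=rec.study_id)


def pool_random_effects(
    effects: Sequence[EffectSize], method: str = "random"
) -> tuple[float, float, float]:
    """DerSimonian–Laird pooled effect: returns ``(pooled_d, se, tau2)``.

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effect weights
    w = 1/variance; pooling weights are 1/(variance + τ²).
    ``method="fixed"`` forces τ² = 0.
    """
    if not effects:
        raise ValueError("no effects to pool")
    d = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    w = 1.0 / v
    k = len(d)
    if k == 1:
        return float(d[0]), float(np.sqrt(v[0])), 0.0
    d_fixed = float((w * d).sum() / w.sum())
    if method == "fixed":
        tau2 = 0.0
    else:
        q = float((w * (d - d_fixed) ** 2).sum())
        c = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float((w_star * d).sum() / w_star.sum())
    se = float(np.sqrt(1.0 / w_star.sum()))
    return pooled, se, tau2


def summarize_by_class(
    records: Iterable[ComparisonRecord], method: str = "random"
) -> pd.DataFrame:
    """Pooled effect per response class (and per family within family_abundance).

    Comparisons whose effect is undefined (zero pooled SD) are dropped with a
    warning; a class with no usable comparisons is omitted.
    """
    import warnings

    groups: dict[tuple[str, str | None], list[EffectSize]] = {}
    for rec in records:
        key = (
            rec.response_class,
            rec.family if rec.response_class == "family_abundance" else None,
        )
        try:
            eff = hedges_d(rec)
        except ValueError as exc:
            warnings.warn(f"dropping degenerate comparison: {exc}", stacklevel=2)
            continue
        groups.setdefault(key, []).append(eff)
    rows = []
    for (cls, family), effs in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
        pooled, se, tau2 = pool_random_effects(effs, method=method)
        rows.append(
            PooledEffect(
                response_class=cls, family=family,
                d=pooled, se=se, tau2=tau2, k=len(effs),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def read_comparisons_csv(path: str | Path) -> list[ComparisonRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        fam = getattr(row, "family", None)
        if isinstance(fam, float) and np.isnan(fam):
            fam = None
        records.append(
            ComparisonRecord(
                study_id=str(row.study_id),
                response_class=str(row.response_class),
                mean_treat=float(row.mean_treat),
                sd_treat=float(row.sd_treat),
                n_treat=int(row.n_treat),
                mean_ctrl=float(row.mean_ctrl),
                sd_ctrl=float(row.sd_ctrl),
                n_ctrl=int(row.n_ctrl),
                family=fam,
            )
        )
    return records
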