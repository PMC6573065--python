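"""Calling chromatin-independent Mediator interactors from AP-MS tables.

The experimental design behind these rules: the complex is affinity-purified
four times — from untreated nuclear extract, from extract treated with the
nuclease benzonase, from extract treated with ethidium bromide (EtBr), and an
independent benzonase-treated replicate — alongside one mock purification per
experiment. A protein is called an interactor only if it is specifically
enriched over the paired control in every purification (Mascot identification
score and emPAI abundance rules), is not a cytoskeletal/cytoplasmic
contaminant, is detected in all four bait purifications, and does not drop
two-fold or more in emPAI under either chromatin-disrupting treatment —
i.e. the interaction does not rely on a DNA/chromatin bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

__all__ = [
    "ROLES",
    "MEDIATOR_ROLES",
    "CONTROL_OF",
    "ApmsRow",
    "FilterConfig",
    "InteractorCall",
    "passes_inclusion",
    "chromatin_independent",
    "call_interactors",
    "subtract_core_subunits",
    "edge_weight_category",
    "endogenous_overlap",
    "rows_from_table",
    "calls_to_table",
    "edge_list",
]

#: purification roles: four bait purifications and one control per experiment
ROLES: Tuple[str, ...] = (
    "untreated",
    "benzonase",
    "etbr",
    "benzonase_rep2",
    "control_exp1",
    "control_exp2",
)

MEDIATOR_ROLES: Tuple[str, ...] = ("untreated", "benzonase", "etbr", "benzonase_rep2")

#: experiment-1 control serves the untreated/benzonase/EtBr purifications,
#: the experiment-2 control serves the independent benzonase replicate
CONTROL_OF: Dict[str, str] = {
    "untreated": "control_exp1",
    "benzonase": "control_exp1",
    "etbr": "control_exp1",
    "benzonase_rep2": "control_exp2",
}


@dataclass(frozen=True)
class ApmsRow:
    """Per-protein Mascot and emPAI scores across all purifications.

    A score of 0 encodes "not detected".
    """

    protein_id: str
    mascot: Mapping[str, float]
    empai: Mapping[str, float]
    is_core_mediator: bool = False
    is_cyto: bool = False
    is_known_interactor: bool = False

    def __post_init__(self) -> None:
        for role in ROLES:
            if role not in self.mascot or role not in self.empai:
                raise ValueError(f"{self.protein_id}: missing role {role!r}")
        if any(v < 0 for v in self.mascot.values()) or any(
            v < 0 for v in self.empai.values()
        ):
            raise ValueError(f"{self.protein_id}: negative score")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the interactor-inclusion rules."""

    mascot_min: float = 50.0
    empai_fold_min: float = 5.0
    mascot_fold_min: float = 3.0
    treatment_drop_fold: float = 2.0
    require_all_purifications: bool = True

    def __post_init__(self) -> None:
        for name in ("mascot_min", "empai_fold_min", "mascot_fold_min", "treatment_drop_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class InteractorCall:
    protein_id: str
    passed: bool
    failure_reasons: Tuple[str, ...]
    mean_empai: float
    edge_category: int

    def __post_init__(self) -> None:
        if self.passed != (len(self.failure_reasons) == 0):
            raise ValueError("passed must equal 'no failure reasons'")
        if self.mean_empai < 0:
            raise ValueError("mean_empai must be >= 0")


def _fold_ok(sample: float, control: float, fold: float) -> bool:
    """sample/control >= fold; a zero control with a detected sample counts
    as infinite enrichment."""
    if control == 0:
        return sample > 0
    return sample >= fold * control


def passes_inclusion(
    row: ApmsRow,
    sample_role: str,
    control_role: str,
    cfg: FilterConfig = FilterConfig(),
) -> Tuple[bool, List[str]]:
    """Apply the per-purification inclusion rules.

    Rules: Mascot score of at least ``mascot_min`` in the bait sample; at
    least ``empai_fold_min``-fold emPAI enrichment and ``mascot_fold_min``-fold
    Mascot enrichment over the paired control; not annotated as a
    cytoskeletal/cytoplasmic protein.
    """
    for role in (sample_role, control_role):
        if role not in ROLES:
            raise KeyError(f"unknown role {role!r}")
    reasons: List[str] = []
    if row.mascot[sample_role] < cfg.mascot_min:
        reasons.append("mascot_min")
    if not _fold_ok(row.empai[sample_role], row.empai[control_role], cfg.empai_fold_min):
        reasons.append("empai_fold")
    if not _fold_ok(row.mascot[sample_role], row.mascot[control_role], cfg.mascot_fold_min):
        reasons.append("mascot_fold")
    if row.is_cyto:
        reasons.append("cyto")
    return (not reasons, reasons)


def chromatin_independent(
    empai_untreated: float,
    empai_treated: float,
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """True unless the treated purification is two-fold lower or more in emPAI.

    A protein undetected in the untreated purification cannot show a drop
    (returns True); one detected untreated but lost under treatment is a
    chromatin-dependent binder (returns False).
    """
    if empai_untreated < 0 or empai_treated < 0:
        raise ValueError("emPAI values must be >= 0")
    if empai_untreated == 0:
        return True
    if empai_treated == 0:
        return False
    # drop iff untreated/treated >= fold; compare multiplicatively to avoid
    # float-division artefacts at the exact two-fold boundary
    return empai_untreated < cfg.treatment_drop_fold * empai_treated


def call_interactors(
    rows: Iterable[ApmsRow], cfg: FilterConfig = FilterConfig()
) -> List[InteractorCall]:
    """Evaluate the full rule conjunction for every protein.

    A protein passes iff the inclusion rules hold for each of the four bait
    purifications against its paired control, its emPAI is robust to both
    benzonase and EtBr treatment, and it is detected (emPAI > 0) in all four
    bait purifications. Output is sorted by mean emPAI descending.
    """
    calls: List[InteractorCall] = []
    for row in rows:
        reasons: List[str] = []
        for role in MEDIATOR_ROLES:
            ok, why = passes_inclusion(row, role, CONTROL_OF[role], cfg)
            for r in why:
                if r not in reasons:
                    reasons.append(r)
        if not chromatin_independent(
            row.empai["untreated"], row.empai["benzonase"], cfg
        ) or not chromatin_independent(row.empai["untreated"], row.empai["etbr"], cfg):
            reasons.append("treatment_drop")
        if cfg.require_all_purifications and any(
            row.empai[role] == 0 for role in MEDIATOR_ROLES
        ):
            reasons.append("presence")
        mean_empai = sum(row.empai[r] for r in MEDIATOR_ROLES) / len(MEDIATOR_ROLES)
        calls.append(
            InteractorCall(
                protein_id=row.protein_id,
                passed=not reasons,
                failure_reasons=tuple(reasons),
                mean_empai=mean_empai,
                edge_category=edge_weight_category(mean_empai),
            )
        )
    calls.sort(key=lambda c: (-c.mean_empai, c.protein_id))
    return calls


def subtract_core_subunits(
    calls: Sequence[InteractorCall], core_ids: Set[str]
) -> List[InteractorCall]:
    """Drop calls whose protein is an annotated core subunit of the complex."""
    return [c for c in calls if c.protein_id not in core_ids]


def edge_weight_category(mean_empai: float) -> int:
    """Map mean emPAI to the 4 network edge-thickness categories.

    > 1.5 thickest (4); (0.75, 1.5] (3); (0.25, 0.75] (2); <= 0.25 thinnest (1).
    """
    if mean_empai < 0:
        raise ValueError("mean_empai must be >= 0")
    if mean_empai > 1.5:
        return 4
    if mean_empai > 0.75:
        return 3
    if mean_empai > 0.25:
        return 2
    return 1


def endogenous_overlap(
    flag_interactors: Set[str], endogenous_calls: Set[str]
) -> Tuple[int, List[str]]:
    """Intersection of the tagged-bait interactor list with an endogenous-IP
    list, in deterministic (sorted) order."""
    shared = sorted(set(flag_interactors) & set(endogenous_calls))
    return len(shared), shared


# ---------------------------------------------------------------------------
# table adapters


def rows_from_table(df: pd.DataFrame) -> List[ApmsRow]:
    """Build ApmsRow records from an 'apms'-schema DataFrame."""
    rows = []
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        rows.append(
            ApmsRow(
                protein_id=d["protein_id"],
                mascot={r: float(d[f"mascot_{r}"]) for r in ROLES},
                empai={r: float(d[f"empai_{r}"]) for r in ROLES},
                is_core_mediator=bool(d.get("is_core_mediator", False)),
                is_cyto=bool(d.get("is_cyto", False)),
                is_known_interactor=bool(d.get("is_known_interactor", False)),
            )
        )
    return rows


def calls_to_table(calls: Sequence[InteractorCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "mean_empai": [c.mean_empai for c in calls],
            "edge_category": [c.edge_category for c in calls],
            "passed": [c.passed for c in calls],
            "reasons": [";".join(c.failure_reasons) for c in calls],
        }
    )


def edge_list(calls: Sequence[InteractorCall], source: str = "MED-complex") -> pd.DataFrame:
    """Edge table (bait-complex -> interactor) for network tools."""
    passing = [c for c in calls if c.passed]
    return pd.DataFrame(
        {
            "source": [source] * len(passing),
            "target": [c.protein_id for c in passing],
            "weight_category": [c.edge_category for c in passing],
        }
    )
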