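"""Relative qPCR quantification by the 2^-ddCt method.

Each record carries the target gene's and the housekeeping reference's
threshold cycles. dCt = Ct_target - Ct_reference per record; ddCt is the
difference of group-mean dCt between treated and control; relative
expression is 2^-ddCt. Swapping the groups inverts the fold change exactly,
and adding a constant to every Ct (target and reference alike) leaves the
result unchanged. Per-replicate fold changes with mean and SD are also
provided for summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["QpcrRecord", "fold_change_ddct", "summarize_qpcr"]


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR well: target and housekeeping threshold cycles."""

    sample_id: str
    condition: str  # "treated" or "control"
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, value in (("ct_target", self.ct_target),
                            ("ct_reference", self.ct_reference)):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{name} must be positive and finite, got {value}"
                )

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def _dcts(records: Iterable[QpcrRecord], label: str) -> np.ndarray:
    values = np.array([r.dct for r in records], float)
    if values.size == 0:
        raise ValueError(f"{label} record list is empty")
    return values


def fold_change_ddct(
    treated: Sequence[QpcrRecord], control: Sequence[QpcrRecord]
) -> float:
    """Relative expression 2^-ddCt of treated vs. control."""
    ddct = _dcts(treated, "treated").mean() - _dcts(control, "control").mean()
    return float(2.0 ** (-ddct))


def summarize_qpcr(
    treated: Sequence[QpcrRecord], control: Sequence[QpcrRecord]
) -> dict:
    """Group fold change plus per-replicate folds (mean +/- SD).

    Per-replicate folds reference each treated record's dCt to the control
    group's mean dCt.
    """
    t = _dcts(treated, "treated")
    c = _dcts(control, "control")
    per_rep = 2.0 ** (-(t - c.mean()))
    return {
        "fold_change": float(2.0 ** (-(t.mean() - c.mean()))),
        "replicate_folds": [float(v) for v in per_rep],
        "mean": float(per_rep.mean()),
        "sd": float(per_rep.std(ddof=1)) if per_rep.size > 1 else 0.0,
        "n_treated": int(t.size),
        "n_control": int(c.size),
    }
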