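"""Group-comparison statistics for the assay readouts.

Groups are summarized as mean +/- SD. Two groups are compared with an
unpaired two-sided Student's t-test (equal variances by default; Welch
behind a flag); three or more with one-way ANOVA followed by Tukey HSD
all-pairs post hoc (Dunnett-style many-to-one comparison against a named
control behind a flag).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidInputError
from .types import ComparisonResult, GroupSummary

__all__ = ["summarize_groups", "compare_groups"]


def _split_groups(data: pd.DataFrame) -> dict[str, np.ndarray]:
    if not {"group_label", "value"}.issubset(data.columns):
        raise InvalidInputError("data needs 'group_label' and 'value' columns")
    if len(data) == 0:
        raise InvalidInputError("empty data table")
    return {
        str(label): grp["value"].to_numpy(dtype=float)
        for label, grp in data.groupby("group_label", sort=True)
    }


def summarize_groups(data: pd.DataFrame) -> list[GroupSummary]:
    """Per-group n, mean and sample SD (n-1 denominator; SD = 0 for n = 1)."""
    out = []
    for label, vals in _split_groups(data).items():
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(GroupSummary(label, int(len(vals)), float(np.mean(vals)), sd))
    return out


def compare_groups(
    data: pd.DataFrame,
    welch: bool = False,
    posthoc: str = "tukey",
    control_label: str | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Student's t-test for two groups; one-way ANOVA + post hoc for more.

    Parameters
    ----------
    posthoc : {'tukey', 'dunnett'}
        All-pairs Tukey HSD (default), or many-to-one Dunnett comparisons
        against ``control_label``.
    """
    groups = _split_groups(data)
    for label, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {label!r} has {len(vals)} value(s); need at least 2"
            )
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups to compare")

    labels = list(groups)
    if len(groups) == 2:
        a, b = groups[labels[0]], groups[labels[1]]
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        name = "welch_t" if welch else "student_t"
        return ComparisonResult(name, float(t), float(p))

    f, p = sps.f_oneway(*groups.values())
    if posthoc == "tukey":
        res = sps.tukey_hsd(*groups.values())
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rows.append(
                    {
                        "group_a": labels[i],
                        "group_b": labels[j],
                        "adjusted_p": float(res.pvalue[i, j]),
                    }
                )
        pairwise = pd.DataFrame(rows)
    elif posthoc == "dunnett":
        if control_label is None or control_label not in groups:
            raise InvalidInputError("dunnett post hoc needs a valid control_label")
        others = [l for l in labels if l != control_label]
        res = sps.dunnett(*(groups[l] for l in others), control=groups[control_label])
        pairwise = pd.DataFrame(
            {
                "group_a": others,
                "group_b": control_label,
                "adjusted_p": [float(pv) for pv in res.pvalue],
            }
        )
    else:
        raise InvalidInputError(f"unknown posthoc {posthoc!r}")
    return ComparisonResult("one_way_anova", float(f), float(p), pairwise=pairwise)
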