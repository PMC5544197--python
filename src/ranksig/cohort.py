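"""HOMA-IR arithmetic and extreme-group cohort selection.

Selection keeps subjects inside a BMI window, takes the n lowest and n
highest HOMA-IR subjects, then runs a greedy swap pass (candidates
restricted to the bottom/top thirds of the HOMA-IR distribution) that
minimizes the summed standardized group differences of the matching
variables. The published cohorts were matched without a stated algorithm;
this greedy reconstruction is deterministic given the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ranksig.io import ClinicalTable

__all__ = ["GroupSelection", "homa_ir", "homa_fold_change", "select_extreme_groups"]

HOMA_DENOMINATOR = 22.5


def homa_ir(fasting_glucose_mmol_l: float, fasting_insulin_mU_l: float) -> float:
    """HOMA-IR = fasting glucose (mmol/l) x fasting insulin (mU/l) / 22.5."""
    g = float(fasting_glucose_mmol_l)
    i = float(fasting_insulin_mU_l)
    if g <= 0 or i <= 0:
        raise ValueError(f"glucose and insulin must be > 0, got {g}, {i}")
    return g * i / HOMA_DENOMINATOR


def homa_fold_change(low_values: Sequence[float], high_values: Sequence[float]) -> float:
    """Fold difference of group mean HOMA-IR: mean(high) / mean(low)."""
    low = np.asarray(low_values, dtype=np.float64)
    high = np.asarray(high_values, dtype=np.float64)
    if low.size == 0 or high.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(high.mean() / low.mean())


@dataclass
class GroupSelection:
    low_group: list[str]
    high_group: list[str]
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.low_group) & set(self.high_group):
            raise ValueError("low and high groups overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "low_group": self.low_group,
                    "high_group": self.high_group,
                    "criteria": self.criteria,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _with_homa(frame: pd.DataFrame) -> pd.DataFrame:
    f = frame.copy()
    if "homa_ir" not in f.columns:
        f["homa_ir"] = [homa_ir(g, i) for g, i in zip(f["glucose"], f["insulin"])]
    return f


def _encode(frame: pd.DataFrame, var: str) -> np.ndarray:
    if var == "sex":
        return (frame["sex"].astype(str).str.upper() == "M").to_numpy(dtype=float)
    return frame[var].to_numpy(dtype=float)


def _balance(frame: pd.DataFrame, low: list[str], high: list[str],
             match_vars: Sequence[str], sds: dict[str, float]) -> float:
    """Sum over matching variables of |mean diff| / window SD."""
    lo = frame[frame["subject_id"].isin(low)]
    hi = frame[frame["subject_id"].isin(high)]
    total = 0.0
    for var in match_vars:
        d = abs(_encode(lo, var).mean() - _encode(hi, var).mean())
        total += d / sds[var]
    return total


def select_extreme_groups(
    table: ClinicalTable,
    bmi_low: float | None,
    bmi_high: float | None,
    n_per_group: int,
    match_vars: Sequence[str] = ("age", "sex", "bmi"),
    exact_sex: bool = False,
    max_iter: int = 200,
) -> GroupSelection:
    """Extreme HOMA-IR groups inside an exclusive BMI window, greedily matched.

    ``bmi_low``/``bmi_high`` are exclusive bounds (``None`` disables one
    side): the lean cohort uses ``bmi_high=25.0`` (excluding BMI >= 25.0)
    and the heavy cohort ``bmi_low=25.0`` (requiring BMI > 25.0). With
    ``exact_sex`` the per-sex counts of the two groups must stay equal
    during swapping. Deterministic and invariant to input row order.
    """
    frame = _with_homa(table.frame).sort_values("subject_id").reset_index(drop=True)
    if bmi_low is not None:
        frame = frame[frame["bmi"] > bmi_low]
    if bmi_high is not None:
        frame = frame[frame["bmi"] < bmi_high]
    if len(frame) < 2 * n_per_group:
        raise ValueError(
            f"only {len(frame)} subjects inside BMI window, need {2 * n_per_group}"
        )
    frame = frame.sort_values(["homa_ir", "subject_id"]).reset_index(drop=True)
    ids = frame["subject_id"].tolist()
    third = max(n_per_group, len(frame) // 3)
    pool_low = ids[:third]
    pool_high = ids[-third:]
    low = ids[:n_per_group]
    high = ids[-n_per_group:]

    sds: dict[str, float] = {}
    for var in match_vars:
        sd = float(np.std(_encode(frame, var), ddof=1))
        sds[var] = sd if sd > 0 else 1.0

    sex_of = dict(zip(frame["subject_id"], frame["sex"].astype(str).str.upper()))

    def males(group: list[str]) -> int:
        return sum(1 for s in group if sex_of[s] == "M")

    if exact_sex:
        # repair pass: equalize male counts by same-group opposite-sex swaps,
        # then restrict the greedy pass to same-sex swaps
        for _ in range(2 * n_per_group):
            diff = males(low) - males(high)
            if diff == 0:
                break
            side, group, pool = (
                ("low", low, pool_low) if diff > 0 else ("high", high, pool_high)
            )
            surplus = "M"
            used = set(low) | set(high)
            options = [
                (cand, member)
                for member in group
                if sex_of[member] == surplus
                for cand in pool
                if cand not in used and sex_of[cand] != surplus
            ]
            if not options:
                # shrink the other group's majority instead
                side, group, pool = (
                    ("high", high, pool_high) if diff > 0 else ("low", low, pool_low)
                )
                surplus = "F"
                options = [
                    (cand, member)
                    for member in group
                    if sex_of[member] == surplus
                    for cand in pool
                    if cand not in used and sex_of[cand] != surplus
                ]
            if not options:
                raise ValueError("exact sex matching infeasible with the candidate pools")
            best_opt = min(
                options,
                key=lambda cm: _balance(
                    frame,
                    [cm[0] if x == cm[1] else x for x in low] if side == "low" else low,
                    [cm[0] if x == cm[1] else x for x in high] if side == "high" else high,
                    match_vars,
                    sds,
                ),
            )
            cand, member = best_opt
            if side == "low":
                low = [cand if x == member else x for x in low]
            else:
                high = [cand if x == member else x for x in high]

    def admissible_swap(member: str, cand: str) -> bool:
        return not exact_sex or sex_of[member] == sex_of[cand]

    score = _balance(frame, low, high, match_vars, sds)
    for _ in range(max_iter):
        best = None
        for side, group, pool in (("low", low, pool_low), ("high", high, pool_high)):
            used = set(low) | set(high)
            for member in group:
                for cand in pool:
                    if cand in used:
                        continue
                    if not admissible_swap(member, cand):
                        continue
                    trial = [cand if x == member else x for x in group]
                    lo, hi = (trial, high) if side == "low" else (low, trial)
                    s = _balance(frame, lo, hi, match_vars, sds)
                    if s < score - 1e-12 and (best is None or s < best[0] - 1e-12):
                        best = (s, side, member, cand)
        if best is None:
            break
        score, side, member, cand = best
        if side == "low":
            low = [cand if x == member else x for x in low]
        else:
            high = [cand if x == member else x for x in high]

    homa = dict(zip(frame["subject_id"], frame["homa_ir"]))
    low = sorted(low, key=lambda s: (homa[s], s))
    high = sorted(high, key=lambda s: (homa[s], s))
    criteria = {
        "bmi_window": [bmi_low, bmi_high],
        "n_per_group": n_per_group,
        "match_vars": list(match_vars),
        "exact_sex": exact_sex,
        "balance_score": float(score),
        "homa_fold_change": homa_fold_change(
            [homa[s] for s in low], [homa[s] for s in high]
        ),
    }
    return GroupSelection(low, high, criteria)
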