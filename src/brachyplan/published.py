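"""Packaged printed-table values and their recomputation.

``load_tables`` returns the per-cell values of the study's result tables
(per-seed deviations, per-case CI/HI/DVH percentages, per-method
positioning errors) exactly as printed.  ``reproduce_published_tables``
recomputes every aggregate cell (row averages, grand means, sds, and the
CI t-test p-value) from the per-cell values through the package's own
statistics routines and compares each against the printed aggregate at its
printed precision.  The per-axis/total-error consistency of the traditional
method's row (the vector-sum identity) and the seed activity unit
conversion are checked the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .dosimetry import mean_sd, two_sample_ttest
from .geometry import euclidean_error
from .tg43 import activity_to_bq

__all__ = ["load_tables", "CheckResult", "reproduce_published_tables"]


def load_tables() -> dict:
    ref = resources.files("brachyplan.data").joinpath("published_tables.json")
    with ref.open() as f:
        return json.load(f)


@dataclass(frozen=True)
class CheckResult:
    table: str
    cell: str
    computed: float
    printed: float
    decimals: int

    @property
    def passed(self) -> bool:
        # consistent with the printed rounding: within half of the last digit
        return abs(self.computed - self.printed) <= 0.5 * 10.0 ** -self.decimals + 1e-12


def _check(out: list, table: str, cell: str, computed: float, printed: float,
           decimals: int) -> None:
    out.append(CheckResult(table, cell, float(computed), float(printed), decimals))


def reproduce_published_tables(fixture: dict | None = None) -> list[CheckResult]:
    """Recompute all printed aggregates from printed per-cell values.

    Returns one CheckResult per aggregate cell; ``all(c.passed ...)`` is the
    acceptance condition.  Informational cells the source itself cannot
    support (the non-CI p-values, see the package docs) are not included.
    """
    fx = fixture if fixture is not None else load_tables()
    checks: list[CheckResult] = []

    # Table 1: the TPM row's total error is the vector sum of its per-axis means
    tpm = fx["table1"]["tpm"]
    axis_means = [tpm["x_error_mm"][0], tpm["y_error_mm"][0], tpm["z_error_mm"][0]]
    total = euclidean_error(axis_means, [0.0, 0.0, 0.0])
    _check(checks, "table1", "tpm_total_error_mm", total,
           tpm["total_error_mm"][0], 2)

    # seed activity conversion
    seed = fx["seed"]
    _check(checks, "seed", "activity_bq", activity_to_bq(seed["activity_mci"]),
           seed["activity_bq"], 0)

    # Table 2: per-case Ave +/- sd and the grand Mean +/- sd
    t2 = fx["table2"]
    row_means = []
    for case, devs in sorted(t2["deviations_mm"].items()):
        m, sd = mean_sd(devs)
        row_means.append(m)
        _check(checks, "table2", f"ave_d_case{case}_mean", m,
               t2["ave_d_mm"][case][0], 2)
        _check(checks, "table2", f"ave_d_case{case}_sd", sd,
               t2["ave_d_mm"][case][1], 2)
    gm, gsd = mean_sd(row_means)
    _check(checks, "table2", "mean_d_mean", gm, t2["mean_d_mm"][0], 2)
    _check(checks, "table2", "mean_d_sd", gsd, t2["mean_d_mm"][1], 2)

    # Table 3: Ave row for CI/HI pre+post (3 decimals) and DVH columns (ints)
    t3 = fx["table3"]
    for col in ("ci_pre", "ci_post", "hi_pre", "hi_post"):
        m, sd = mean_sd(t3[col])
        _check(checks, "table3", f"{col}_mean", m, t3["ave_printed"][col][0], 3)
        _check(checks, "table3", f"{col}_sd", sd, t3["ave_printed"][col][1], 3)
    for col in ("d100", "d90", "v100", "v90"):
        m_pre, _ = mean_sd(t3["dvh_pct_pre"][col])
        m_post, _ = mean_sd(t3["dvh_pct_post"][col])
        _check(checks, "table3", f"{col}_pre_mean", m_pre,
               t3["ave_printed"][col][0], 0)
        _check(checks, "table3", f"{col}_post_mean", m_post,
               t3["ave_printed"][col][1], 0)

    # Table 3: the CI p-value (the only printed p the data reproduce)
    tt = two_sample_ttest(t3["ci_pre"], t3["ci_post"])
    _check(checks, "table3", "ci_p", tt.p, t3["p_printed"]["ci"], 3)
    return checks


def checks_to_dataframe(checks: list[CheckResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"table": c.table, "cell": c.cell,
          "computed": round(c.computed, c.decimals), "printed": c.printed,
          "passed": c.passed} for c in checks]
    )
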