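"""Test-retest repeatability statistics for double-baseline tissue volumes.

Three complementary precision metrics over paired replicate measurements
``(x_i1, x_i2)`` of the same quantity:

* **wCV** — within-subject coefficient of variation,
  ``100 * sqrt( mean_i[ (x_i1-x_i2)^2 / (2 m_i^2) ] )`` with ``m_i`` the pair
  mean; the squared-relative-difference estimator.
* **ICC** — one-way random-effects intraclass correlation for two
  interchangeable replicates, ``(MSB - MSW) / (MSB + MSW)``.
* **Asymmetric limits of agreement** — computed on the log scale, where
  test-retest error is additive: ``sigma_w,log`` is the within-subject SD of
  log measurements, the repeatability coefficient is
  ``RC_log = 1.96 * sqrt(2) * sigma_w,log``, and the percent limits
  ``lower = 100 (exp(-RC_log) - 1)``, ``upper = 100 (exp(+RC_log) - 1)``
  are reciprocal-symmetric: ``(1 + upper/100)(1 + lower/100) = 1``.

A change between two visits larger than the limits is, with 95% confidence,
real rather than measurement noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RC_MULTIPLIER = 1.96 * np.sqrt(2.0)  # 95% repeatability coefficient


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must have shape (n, 2)")
    return arr


def wcv(pairs) -> float:
    """Within-subject coefficient of variation as a percentage.

    Requires at least two pairs of strictly positive volumes.
    """
    arr = _as_pairs(pairs)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(arr <= 0):
        raise ValueError("volumes must be strictly positive")
    d2 = (arr[:, 0] - arr[:, 1]) ** 2
    m2 = arr.mean(axis=1) ** 2
    return float(100.0 * np.sqrt(np.mean(d2 / (2.0 * m2))))


def icc_testretest(pairs) -> float:
    """One-way random-effects ICC(1,1) for k = 2 replicates.

    ``(MSB - MSW) / (MSB + MSW)``; NaN when the total variance is zero.
    """
    arr = _as_pairs(pairs)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs for ICC")
    k = 2
    subj_means = arr.mean(axis=1)
    grand = arr.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((arr - subj_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return float((msb - msw) / denom)


def sigma_w_log(pairs) -> float:
    """Within-subject SD of log measurements: ``sqrt(sum (ln x1 - ln x2)^2 / 2n)``."""
    arr = _as_pairs(pairs)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(arr <= 0):
        raise ValueError("volumes must be strictly positive")
    dlog = np.log(arr[:, 0]) - np.log(arr[:, 1])
    return float(np.sqrt(np.sum(dlog**2) / (2.0 * arr.shape[0])))


def asymmetric_loa(pairs) -> tuple[float, float]:
    """Asymmetric 95% limits of agreement (lower %, upper %) on the log scale."""
    s = sigma_w_log(pairs)
    rc = RC_MULTIPLIER * s
    return (float(100.0 * (np.exp(-rc) - 1.0)), float(100.0 * (np.exp(rc) - 1.0)))


@dataclass
class RepeatabilityResult:
    """Repeatability of one tissue class within one stratum."""

    tissue: str
    stratum: str
    n: int
    wcv_pct: float
    sigma_w_log: float
    icc: float
    loa_lower_pct: float
    loa_upper_pct: float
    rc_log: float

    def __post_init__(self) -> None:
        # reciprocal symmetry of the log-scale limits
        prod = (1.0 + self.loa_upper_pct / 100.0) * (1.0 + self.loa_lower_pct / 100.0)
        assert abs(prod - 1.0) < 1e-9, "asymmetric LOA must be reciprocal-symmetric"

    def as_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "stratum": self.stratum,
            "n": self.n,
            "wcv_pct": self.wcv_pct,
            "sigma_w_log": self.sigma_w_log,
            "icc": self.icc,
            "loa_lower_pct": self.loa_lower_pct,
            "loa_upper_pct": self.loa_upper_pct,
            "rc_log": self.rc_log,
        }


def extract_pairs(
    table: pd.DataFrame, tissue: str, patients: list[str] | None = None
) -> np.ndarray:
    """(n, 2) baseline1/baseline2 volumes for one tissue, complete pairs only."""
    sub = table[table["tissue"] == tissue]
    if patients is not None:
        sub = sub[sub["patient"].isin(patients)]
    wide = sub.pivot(index="patient", columns="visit", values="volume_ml")
    if "baseline1" not in wide or "baseline2" not in wide:
        return np.empty((0, 2))
    wide = wide.dropna(subset=["baseline1", "baseline2"])
    return wide[["baseline1", "baseline2"]].to_numpy()


def stratified_repeatability(
    table: pd.DataFrame, strata: str | None = None
) -> list[RepeatabilityResult]:
    """wCV/ICC/LOA per tissue class, optionally split by a grouping column.

    *strata* names a column of the volume table (e.g. ``"gender"``); ``None``
    computes a single pooled stratum per tissue.  Strata with fewer than two
    complete pairs are skipped with a warning.
    """
    results: list[RepeatabilityResult] = []
    tissues = sorted(table["tissue"].unique())
    if strata is None:
        groups = [("all", table)]
    else:
        groups = [(str(g), sub) for g, sub in table.groupby(strata)]
    for tissue in tissues:
        for label, sub in groups:
            pairs = extract_pairs(sub, tissue)
            if pairs.shape[0] < 2:
                warnings.warn(
                    f"stratum {label!r} for tissue {tissue!r} has "
                    f"{pairs.shape[0]} complete pairs; skipped",
                    stacklevel=2,
                )
                continue
            s = sigma_w_log(pairs)
            lo, up = asymmetric_loa(pairs)
            icc = icc_testretest(pairs) if pairs.shape[0] >= 3 else float("nan")
            results.append(
                RepeatabilityResult(
                    tissue=tissue,
                    stratum=label,
                    n=pairs.shape[0],
                    wcv_pct=wcv(pairs),
                    sigma_w_log=s,
                    icc=icc,
                    loa_lower_pct=lo,
                    loa_upper_pct=up,
                    rc_log=RC_MULTIPLIER * s,
                )
            )
    return results


def repeatability_frame(results: list[RepeatabilityResult]) -> pd.DataFrame:
    """Tabular summary of stratified repeatability results."""
    return pd.DataFrame([r.as_dict() for r in results])
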