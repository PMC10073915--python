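"""Sexual size dimorphism (SSD) and two-sample Z-tests.

SSD is expressed as the male share of combined sex means:
100 * mean(male weight) / (mean(male) + mean(female)), so 50% means
monomorphic body size and values above 50% mean males are heavier.
Breed comparisons use a Z-test on the difference of SSD ratios with a
delta-method variance, so individual weight spread and sample size
both enter the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class SSDResult:
    breed: str
    ssd_percent: float  # 100 * mean_m / (mean_m + mean_f)
    n_m: int
    n_f: int


class ZTestResult(NamedTuple):
    z: float
    p: float
    flag: str = ""


def _sex_weights(weights: pd.DataFrame, breed: str, sex: str) -> np.ndarray:
    w = weights.loc[(weights["breed"] == breed) & (weights["sex"] == sex), "weight_g"]
    return w.to_numpy(float)


def ssd(weights: pd.DataFrame, breed: str) -> SSDResult:
    """SSD percentage for one breed from a breed/sex/weight_g table."""
    m = _sex_weights(weights, breed, "M")
    f = _sex_weights(weights, breed, "F")
    if m.size == 0 or f.size == 0:
        raise ValidationError(f"{breed}: both sexes required for SSD")
    pct = 100.0 * m.mean() / (m.mean() + f.mean())
    return SSDResult(breed=breed, ssd_percent=pct, n_m=m.size, n_f=f.size)


def z_test_means(groupA, groupB) -> ZTestResult:
    """Two-sample Z-test on means with per-group variances.

    Z = (mean_A - mean_B) / sqrt(s2_A/n_A + s2_B/n_B), two-sided p from
    the standard normal. Degenerate zero-variance inputs give p = 1 for
    equal means, p = 0 flagged ``degenerate`` otherwise.
    """
    a = np.asarray(groupA, float)
    b = np.asarray(groupB, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need n >= 2 per group")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return ZTestResult(0.0, 1.0)
        return ZTestResult(math.copysign(math.inf, diff), 0.0, "degenerate")
    z = diff / math.sqrt(se2)
    return ZTestResult(z, 2.0 * stats.norm.sf(abs(z)))


def _ssd_ratio_and_var(m: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Delta-method mean and variance of R = mu_m / (mu_m + mu_f).

    dR/dmu_m = mu_f / T^2 and dR/dmu_f = -mu_m / T^2 with T the total,
    so Var(R) ~ (mu_f^2 s2_m/n_m + mu_m^2 s2_f/n_f) / T^4.
    """
    mu_m, mu_f = m.mean(), f.mean()
    total = mu_m + mu_f
    var = (
        mu_f**2 * m.var(ddof=1) / m.size + mu_m**2 * f.var(ddof=1) / f.size
    ) / total**4
    return mu_m / total, var


def ssd_compare(weightsA: pd.DataFrame, weightsB: pd.DataFrame) -> ZTestResult:
    """Z-test on the difference of two breeds' SSD ratios (delta method).

    Each argument is a weight table for a single breed with both sexes.
    Antisymmetric in breed order: swapping arguments flips Z's sign.
    """
    parts = []
    for w in (weightsA, weightsB):
        breeds = w["breed"].unique()
        if len(breeds) != 1:
            raise ValidationError("each weight table must cover exactly one breed")
        m = _sex_weights(w, breeds[0], "M")
        f = _sex_weights(w, breeds[0], "F")
        if m.size < 2 or f.size < 2:
            raise ValidationError(f"{breeds[0]}: need >= 2 weights per sex")
        parts.append(_ssd_ratio_and_var(m, f))
    (ra, va), (rb, vb) = parts
    se2 = va + vb
    diff = ra - rb
    if se2 == 0:
        if diff == 0:
            return ZTestResult(0.0, 1.0)
        return ZTestResult(math.copysign(math.inf, diff), 0.0, "degenerate")
    z = diff / math.sqrt(se2)
    return ZTestResult(z, 2.0 * stats.norm.sf(abs(z)))


def z_test_proportions(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion Z-test, two-sided.

    Used e.g. to compare the male-biased share of sex-biased genes
    between two breeds.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se2 = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if se2 == 0:
        return ZTestResult(0.0, 1.0) if p1 == p2 else ZTestResult(math.inf, 0.0, "degenerate")
    z = (p1 - p2) / math.sqrt(se2)
    return ZTestResult(z, 2.0 * stats.norm.sf(abs(z)))


def ssd_table(weights: pd.DataFrame) -> pd.DataFrame:
    """SSD per breed plus all pairwise breed Z-tests, star-coded at 0.05."""
    rows = [ssd(weights, b).__dict__ for b in weights["breed"].unique()]
    return pd.DataFrame(rows)


def pairwise_ssd_tests(weights: pd.DataFrame) -> pd.DataFrame:
    breeds = list(weights["breed"].unique())
    rows = []
    for i, a in enumerate(breeds):
        for b in breeds[i + 1 :]:
            res = ssd_compare(
                weights[weights["breed"] == a], weights[weights["breed"] == b]
            )
            stars = (
                "***" if res.p < 0.001 else "**" if res.p < 0.01 else "*" if res.p < 0.05 else ""
            )
            rows.append({"breed_a": a, "breed_b": b, "z": res.z, "p": res.p, "sig": stars})
    return pd.DataFrame(rows)
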