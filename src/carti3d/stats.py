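"""Group comparisons on thickness measurement tables.

Two tests mirror the study design: one-way ANOVA with Tukey's HSD post hoc
across the naive / contralateral / operated groups, and two-tailed paired
Student's t-tests for matched comparisons (contralateral vs operated limb of
the same animal, or the same sample measured by two modalities).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import InputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    #: Tukey-adjusted p value per unordered group pair
    pairwise_p: dict[tuple[str, str], float]


def one_way_anova_tukey(groups: dict[str, list[float]]) -> AnovaResult:
    """Classical one-way ANOVA followed by Tukey's HSD multiple comparisons.

    ``groups`` maps group name to its per-sample values. Unbalanced designs
    use the Tukey-Kramer adjustment (studentized-range distribution with the
    harmonic pair size), which is what :func:`scipy.stats.tukey_hsd`
    implements. All p values lie in [0, 1].
    """
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise InputError(f"group '{n}' has fewer than 2 values")

    means = [a.mean() for a in arrays]
    within_var = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within_var == 0:
        if np.allclose(means, means[0]):
            f, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero within-group variance with unequal means: "
                "reporting the limiting F = inf, p = 0",
                stacklevel=2,
            )
            f, p = float("inf"), 0.0
        pairwise = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                equal = np.isclose(means[i], means[j])
                pairwise[(names[i], names[j])] = 1.0 if equal else 0.0
        return AnovaResult(f, p, pairwise)

    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = {
        (names[i], names[j]): float(np.clip(hsd.pvalue[i, j], 0.0, 1.0))
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    log.info("ANOVA: F = %.4g, p = %.4g over %s", f, p, names)
    return AnovaResult(float(f), float(np.clip(p, 0.0, 1.0)), pairwise)


def paired_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-tailed paired Student's t-test; returns ``(t, p)``.

    Pairs must be aligned by sample. Zero-variance differences are handled
    as limiting cases with a warning: all-zero differences give
    ``(0.0, 1.0)``, constant nonzero differences give ``(±inf, 0.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"paired test needs equal lengths, got {a.size} and {b.size}")
    if a.size < 2:
        raise InputError("paired test needs at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            warnings.warn(
                "identical pairs: t = 0, p = 1 (degenerate case)", stacklevel=2
            )
            return 0.0, 1.0
        warnings.warn(
            "zero-variance nonzero differences: reporting the limiting "
            "t = +/-inf, p = 0",
            stacklevel=2,
        )
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(np.clip(p, 0.0, 1.0))
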