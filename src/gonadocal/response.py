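"""Stimulus-responsiveness classification and the field's statistical conventions.

A cell is *responsive* when its stimulation-session synchrony coefficient
strictly exceeds the 80th percentile (linear-interpolation definition) of
the basal-session coefficients of its own population in the same fish.
Coefficients come either from the reference-ROI vector (default) or from
each cell's mean off-diagonal all-pairs coefficient; the same mode is used
for basal and stimulation sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DffMatrix
from .synchrony import CorrelationParams, CorrelationResult, max_crosscorr, reference_vector

__all__ = [
    "ResponseParams",
    "ResponseSummary",
    "session_coefficients",
    "classify_responsive",
    "compare_pre_post",
    "compare_populations",
]


@dataclass(frozen=True)
class ResponseParams:
    percentile: float = 80.0
    coefficient_mode: str = "reference_vector"  # or 'all_pairs_mean_per_cell'

    def __post_init__(self):
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.coefficient_mode not in ("reference_vector", "all_pairs_mean_per_cell"):
            raise ValueError(f"unknown coefficient_mode {self.coefficient_mode!r}")


@dataclass
class ResponseSummary:
    """Per-cell coefficients and responsiveness, per-population fractions (%)."""

    per_cell: pd.DataFrame  # cell_id, population, basal_coeff, stim_coeff, threshold, responsive
    fraction_responsive_pct: dict[str, float]
    threshold_by_population: dict[str, float]
    params: ResponseParams


def session_coefficients(
    dff: DffMatrix,
    params: ResponseParams,
    corr_params: CorrelationParams = CorrelationParams(),
) -> dict[str, float]:
    """Per-cell synchrony coefficient for one session, per population."""
    out: dict[str, float] = {}
    for pop in dff.populations():
        cells = dff.cells_of(pop)
        if len(cells) < 2:
            out.update({c: float("nan") for c in cells})
            continue
        if params.coefficient_mode == "reference_vector":
            _, coeffs = reference_vector(dff, "auto", corr_params, population=pop)
            out.update(coeffs)
        else:
            sub = _population_submatrix(dff, pop)
            result = max_crosscorr(sub, corr_params)
            out.update(result.per_cell_mean(pop))
    return out


def _population_submatrix(dff: DffMatrix, population: str) -> DffMatrix:
    from dataclasses import replace

    cells = dff.cells_of(population)
    idx = [dff.cell_ids.index(c) for c in cells]
    return replace(
        dff,
        values=dff.values[:, idx],
        cell_ids=cells,
        population_of={c: population for c in cells},
        f0_per_cell=dff.f0_per_cell[idx],
    )


def classify_responsive(
    basal_coeffs: dict[str, float],
    stim_coeffs: dict[str, float],
    population_of: dict[str, str],
    params: ResponseParams = ResponseParams(),
) -> ResponseSummary:
    """Percentile-rule classification of stimulus-responsive cells.

    ``basal_coeffs`` and ``stim_coeffs`` map cell id -> coefficient for the
    basal and stimulation sessions of the same fish (same cells).  The
    threshold is computed per population from the basal values; a cell is
    responsive iff its stimulation coefficient strictly exceeds it.  Cells
    with a missing coefficient in either session are excluded from both
    numerator and denominator.
    """
    cells = [c for c in basal_coeffs if c in stim_coeffs]
    if not cells:
        raise ValueError("basal and stimulation sessions share no cells")
    pops: dict[str, None] = {}
    for c in cells:
        pops.setdefault(population_of[c], None)

    thresholds: dict[str, float] = {}
    fractions: dict[str, float] = {}
    rows = []
    for pop in pops:
        pop_cells = [c for c in cells if population_of[c] == pop]
        basal_vals = np.array([basal_coeffs[c] for c in pop_cells], dtype=float)
        valid_basal = basal_vals[~np.isnan(basal_vals)]
        if len(valid_basal) == 0:
            raise ValueError(f"no valid basal coefficients for population {pop}")
        threshold = float(np.percentile(valid_basal, params.percentile))  # linear interp
        thresholds[pop] = threshold
        n_valid = n_resp = 0
        for c in pop_cells:
            b, s = basal_coeffs[c], stim_coeffs[c]
            usable = not (np.isnan(b) or np.isnan(s))
            responsive = bool(usable and s > threshold)
            if usable:
                n_valid += 1
                n_resp += responsive
            rows.append(
                {
                    "cell_id": c,
                    "population": pop,
                    "basal_coeff": b,
                    "stim_coeff": s,
                    "threshold": threshold,
                    "responsive": responsive if usable else np.nan,
                }
            )
        fractions[pop] = 100.0 * n_resp / n_valid if n_valid else float("nan")
    return ResponseSummary(
        per_cell=pd.DataFrame(rows),
        fraction_responsive_pct=fractions,
        threshold_by_population=thresholds,
        params=params,
    )


def compare_pre_post(pre, post, alternative: str = "greater"):
    """Paired one-sided Wilcoxon signed-rank test (post vs pre).

    Exact null distribution for n <= 25 (no ties/zeros), as scipy provides.
    Returns ``(statistic, p_value, n)``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    n = len(pre)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = post - pre
    if np.all(diffs == 0):
        raise ValueError("all-zero differences: the paired test is undefined")
    method = "exact" if n <= 25 else "auto"
    try:
        res = stats.wilcoxon(post, pre, alternative=alternative, method=method)
    except ValueError:
        # ties or zeros make the exact distribution unavailable
        res = stats.wilcoxon(post, pre, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue), n


def compare_populations(groups: dict[str, np.ndarray], design: str = "auto") -> pd.DataFrame:
    """Two-tailed unpaired t (two groups) or one-way ANOVA + Tukey-Kramer.

    Returns a tidy test table with statistic, df and p per comparison.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for lab, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    if design == "auto":
        design = "two_groups" if len(arrays) == 2 else "one_way"
    if design == "two_groups":
        if len(arrays) != 2:
            raise ValueError("two_groups design requires exactly two groups")
        df = len(arrays[0]) + len(arrays[1]) - 2
        if arrays[0].var() == 0 and arrays[1].var() == 0:
            # degenerate but unambiguous: identical constants -> no effect,
            # different constants -> separation beyond any threshold
            same = arrays[0].mean() == arrays[1].mean()
            sign = np.sign(arrays[0].mean() - arrays[1].mean())
            return pd.DataFrame(
                [
                    {
                        "test": "t_unpaired_two_tailed",
                        "comparison": f"{labels[0]} vs {labels[1]}",
                        "statistic": 0.0 if same else float(sign * np.inf),
                        "df": df,
                        "p_value": 1.0 if same else 0.0,
                    }
                ]
            )
        t = stats.ttest_ind(arrays[0], arrays[1])
        return pd.DataFrame(
            [
                {
                    "test": "t_unpaired_two_tailed",
                    "comparison": f"{labels[0]} vs {labels[1]}",
                    "statistic": float(t.statistic),
                    "df": df,
                    "p_value": float(t.pvalue),
                }
            ]
        )
    if design == "one_way":
        f = stats.f_oneway(*arrays)
        k, n = len(arrays), sum(map(len, arrays))
        rows = [
            {
                "test": "one_way_anova",
                "comparison": "omnibus",
                "statistic": float(f.statistic),
                "df": f"{k - 1},{n - k}",
                "p_value": float(f.pvalue),
            }
        ]
        tukey = stats.tukey_hsd(*arrays)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "test": "tukey_kramer",
                        "comparison": f"{labels[i]} vs {labels[j]}",
                        "statistic": float(tukey.statistic[i, j]),
                        "df": f"{k},{n - k}",
                        "p_value": float(tukey.pvalue[i, j]),
                    }
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown design {design!r}")
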