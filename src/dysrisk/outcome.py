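"""Reference-quantile construction of the binary low-richness outcome.

The dysbiosis-risk outcome is defined against the healthy reference group:
a sample is "positive" (at risk, low richness) when its Chao1 richness falls
strictly below a chosen quantile — by default the 25th percentile — of the
reference group's richness distribution.  ``scan_quantiles`` cross-tabulates
each candidate quantile's binarization against the CD/HC group label, under
both conditioning conventions, and picks the most discriminating one by
Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OutcomeDefinition, ValidationError


def reference_quantile(values, q: float, method: str = "linear") -> float:
    """Quantile of the reference group's richness (type-7 linear interpolation
    by default, i.e. h = (n-1)q + 1)."""
    v = np.asarray(values, dtype=float)
    if not 0 < q < 1:
        raise ValidationError(f"quantile must lie in (0,1); got {q}")
    if v.size < 4 or not np.all(np.isfinite(v)):
        raise ValidationError(
            f"need at least 4 finite reference values; got {v.size}"
        )
    return float(np.quantile(v, q, method=method))


def binarize(values, cutoff: float) -> np.ndarray:
    """1 = low richness (value strictly below cutoff); ties at the cutoff are
    negative."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite richness values")
    return (v < cutoff).astype(np.int8)


def define_outcome(
    richness: pd.Series,
    groups: pd.Series,
    *,
    reference_group: str = "HC",
    q: float = 0.25,
    method: str = "linear",
) -> tuple[pd.Series, OutcomeDefinition]:
    """Binary outcome for every sample from the reference group's quantile."""
    groups = groups.reindex(richness.index)
    ref = richness[groups == reference_group]
    if ref.empty:
        raise ValidationError(f"no samples in reference group {reference_group!r}")
    cutoff = reference_quantile(ref.to_numpy(), q, method=method)
    outcome = pd.Series(
        binarize(richness.to_numpy(), cutoff), index=richness.index, name="low_richness"
    )
    definition = OutcomeDefinition(
        reference_group=reference_group, quantile=q,
        cutoff_value=cutoff, quantile_method=method,
    )
    return outcome, definition


@dataclass
class QuantileScan:
    table: pd.DataFrame        # one row per (quantile, condition)
    best_quantile: float
    best_row: pd.Series


def _sens_spec(outcome: np.ndarray, condition: np.ndarray) -> tuple[float, float]:
    pos = condition == 1
    sens = float(outcome[pos].mean()) if pos.any() else np.nan
    spec = float((1 - outcome[~pos]).mean()) if (~pos).any() else np.nan
    return sens, spec


def scan_quantiles(
    richness: pd.Series,
    groups: pd.Series,
    quantiles=(0.25, 0.5, 0.75),
    *,
    reference_group: str = "HC",
    condition_group: str = "CD",
    method: str = "linear",
) -> QuantileScan:
    """Scan candidate reference-group quantiles for group discrimination.

    For each quantile, binarize richness at the reference group's quantile
    and cross-tabulate "low richness" against the group label under BOTH
    conditioning conventions (condition of interest = ``condition_group`` and
    = ``reference_group``), reporting sensitivity, specificity and Youden's
    J for each.  The best quantile maximizes J under the configured
    orientation (condition = ``condition_group``).
    """
    groups = groups.reindex(richness.index)
    labels = set(groups.dropna().unique())
    if len(labels) < 2:
        raise ValidationError(f"need two groups; found {sorted(map(str, labels))}")
    ref = richness[groups == reference_group].to_numpy()
    rows = []
    for q in quantiles:
        cutoff = reference_quantile(ref, q, method=method)
        out = binarize(richness.to_numpy(), cutoff)
        for cond in (condition_group, reference_group):
            sens, spec = _sens_spec(out, (groups == cond).astype(int).to_numpy())
            rows.append({
                "quantile": q, "cutoff": cutoff, "condition": cond,
                "sensitivity": sens, "specificity": spec,
                "youden_j": sens + spec - 1.0,
            })
    table = pd.DataFrame(rows)
    configured = table[table["condition"] == condition_group]
    best = configured.loc[configured["youden_j"].idxmax()]
    return QuantileScan(table=table, best_quantile=float(best["quantile"]), best_row=best)
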