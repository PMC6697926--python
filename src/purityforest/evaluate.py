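"""Independent purity scores and evaluation machinery.

Includes the LUMP score (leukocyte-unmethylation purity proxy: the mean beta
over a panel of CpGs hypomethylated in immune cells, conventionally divided
by 0.85 and capped at 1), cross-method agreement statistics (Pearson r, MSE,
median absolute difference), pairwise correlation matrices and per-group
purity quantile tables used to derive entity-specific low-purity cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BetaMatrix, PurityTable, ValidationError

__all__ = [
    "EvaluationReport",
    "QuantileTable",
    "lump_score",
    "evaluate_predictions",
    "pairwise_correlations",
    "purity_quantiles_by_group",
    "abs_difference_summary",
]

DEFAULT_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)
LUMP_SCALE = 0.85


@dataclass(frozen=True)
class EvaluationReport:
    """Agreement between two purity tables on their sample intersection."""

    pearson_r: float  # NaN when either vector has zero variance
    mse: float
    median_abs_diff: float
    n: int
    pair: tuple
    zero_variance: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": ["/".join(self.pair)] * 3,
                "metric": ["pearson_r", "mse", "median_abs_diff"],
                "value": [self.pearson_r, self.mse, self.median_abs_diff],
                "n": [self.n] * 3,
            }
        )


@dataclass(frozen=True)
class QuantileTable:
    """Per-group empirical purity quantiles (linear interpolation)."""

    quantile_probs: tuple
    values: pd.DataFrame  # index: group, columns: quantile probs
    n_per_group: pd.Series
    small_groups: tuple = ()  # groups with n < 3, flagged not dropped

    def to_frame(self) -> pd.DataFrame:
        frame = self.values.copy()
        frame.insert(0, "n", self.n_per_group)
        return frame.rename_axis("group").reset_index()


def lump_score(
    m: BetaMatrix,
    panel,
    scale: float = LUMP_SCALE,
    cap: bool = True,
) -> tuple:
    """LUMP-style purity proxy from a panel of immune-hypomethylated CpGs.

    Per sample: mean beta over the panel probes present in the matrix,
    divided by ``scale`` and (with ``cap`` on) truncated at 1.  Low scores
    indicate immune infiltration.  Returns the score table (source ``LUMP``)
    plus a per-sample count of panel probes that entered the mean.

    With ``cap`` off the score must remain a valid purity, so pair it with
    ``scale=1`` (the raw-mean variant); a sub-1 scale without the cap can
    push scores past 1 and is rejected by the purity-table invariant.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    panel = list(dict.fromkeys(panel))
    present = [p for p in panel if p in set(m.probe_ids)]
    if not present:
        raise ValidationError("no panel probe present in the beta matrix")
    sub = m.values.loc[present]
    counts = sub.notna().sum(axis=0)
    if (counts == 0).any():
        sid = counts.index[counts == 0][0]
        raise ValidationError(f"sample {sid!r} has no usable panel probe")
    score = sub.mean(axis=0, skipna=True) / scale
    if cap:
        score = score.clip(upper=1.0)
    table = PurityTable(purity=pd.Series(score, name="purity"), source="LUMP")
    counts.name = "panel_probes_used"
    return table, counts


def _intersect(a: PurityTable, b: PurityTable) -> tuple:
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    return a.purity.loc[shared].to_numpy(), b.purity.loc[shared].to_numpy(), shared


def evaluate_predictions(a: PurityTable, b: PurityTable) -> EvaluationReport:
    """Pearson r, MSE and median absolute difference on the shared samples.

    With fewer than 3 shared samples the comparison is refused; a zero-
    variance vector leaves r undefined (NaN, flagged) while MSE and the
    median absolute difference are still reported.
    """
    va, vb, shared = _intersect(a, b)
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared samples, got {len(shared)}")
    zero_var = np.ptp(va) == 0.0 or np.ptp(vb) == 0.0
    if zero_var:
        r = float("nan")
    else:
        r = float(sps.pearsonr(va, vb).statistic)
    diff = va - vb
    return EvaluationReport(
        pearson_r=r,
        mse=float(np.mean(diff**2)),
        median_abs_diff=float(np.median(np.abs(diff))),
        n=len(shared),
        pair=(a.source, b.source),
        zero_variance=zero_var,
    )


def pairwise_correlations(tables, names=None) -> pd.DataFrame:
    """Symmetric Pearson-r matrix across purity tables.

    Each cell is computed on that pair's own sample intersection; pairs with
    fewer than 3 shared samples (or zero variance) are flagged as NaN.
    """
    tables = list(tables)
    if names is None:
        names = []
        for t in tables:
            name = t.source
            while name in names:  # disambiguate repeated sources
                name += "_"
            names.append(name)
    k = len(tables)
    out = pd.DataFrame(np.eye(k), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            va, vb, shared = _intersect(tables[i], tables[j])
            if len(shared) < 3 or np.ptp(va) == 0.0 or np.ptp(vb) == 0.0:
                r = float("nan")
            else:
                r = float(sps.pearsonr(va, vb).statistic)
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def purity_quantiles_by_group(p: PurityTable, probs=DEFAULT_QUANTILES) -> QuantileTable:
    """Per-group empirical quantiles of purity (linear interpolation between
    order statistics), the machinery behind entity-wise low-purity cut-offs."""
    if p.group is None:
        raise ValidationError("purity table has no group labels")
    probs = tuple(probs)
    if any(not 0.0 < q < 1.0 for q in probs) or list(probs) != sorted(probs):
        raise ValidationError("quantile probs must be sorted and inside (0, 1)")
    rows, ns, small = {}, {}, []
    for group, values in p.purity.groupby(p.group):
        arr = values.to_numpy()
        rows[group] = np.quantile(arr, probs, method="linear")
        ns[group] = len(arr)
        if len(arr) < 3:
            small.append(group)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(probs)).sort_index()
    return QuantileTable(
        quantile_probs=probs,
        values=values,
        n_per_group=pd.Series(ns).sort_index(),
        small_groups=tuple(sorted(small)),
    )


def abs_difference_summary(a: PurityTable, b: PurityTable, bins: int = 20) -> dict:
    """Distribution summary of |a - b| on the shared samples (median, mean,
    histogram over [0, 1])."""
    va, vb, shared = _intersect(a, b)
    if not shared:
        raise ValidationError("no shared samples")
    diff = np.abs(va - vb)
    counts, edges = np.histogram(diff, bins=bins, range=(0.0, 1.0))
    return {
        "median": float(np.median(diff)),
        "mean": float(np.mean(diff)),
        "n": len(shared),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
        "pair": (a.source, b.source),
    }
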