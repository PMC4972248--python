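"""Salient-feature selection by correlation interval intersected with significance.

From the full feature set F (M features), three steps distil a small salient
subset used for classification:

1. ``U`` — features whose Pearson correlation with at least ``M_L`` other
   features falls inside the low-correlation interval [-delta, delta]
   (computed on both groups pooled).
2. ``Q`` — features whose two-group Welch t-test (two-tailed, unequal
   variance) achieves p < alpha (default 0.05, no multiplicity correction).
3. ``phi = U ∩ Q`` — the salient set.

Because U only grows with delta, phi is nested along a delta grid; sweeping
delta therefore induces an *importance order* on the features of Q: the
smaller the delta at which a feature first enters phi, the more important it
is.  The sweep also tabulates cross-validated prediction accuracy as a
function of salient-set size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import FeatureTable

DEFAULT_ALPHA = 0.05
DEFAULT_ML = 100
DEFAULT_DELTA_GRID = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


@dataclass
class SelectionResult:
    """Outputs of the salient-feature selection for one table."""

    delta: float
    M_L: int
    alpha: float
    U: list[str]
    Q: list[str]
    phi: list[str]
    p_values: pd.Series
    importance_order: list[str] | None = None
    entry_delta: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (set(self.phi) <= set(self.U) and set(self.phi) <= set(self.Q)):
            raise ValueError("phi must be a subset of both U and Q")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "delta": self.delta, "M_L": self.M_L, "alpha": self.alpha,
            "U": self.U, "Q": self.Q, "phi": self.phi,
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "importance_order": self.importance_order,
            "entry_delta": self.entry_delta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(delta=d["delta"], M_L=d["M_L"], alpha=d["alpha"],
                   U=d["U"], Q=d["Q"], phi=d["phi"],
                   p_values=pd.Series(d["p_values"]),
                   importance_order=d.get("importance_order"),
                   entry_delta=d.get("entry_delta"))


# --- correlation ----------------------------------------------------------

def correlation_matrix(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlations over all subjects, both groups pooled.

    Zero-variance features yield undefined correlations; these entries are
    set to 0 (diagonal stays 1) with a warning, so downstream counting
    treats such features as uncorrelated with everything.
    """
    X = table.data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 subjects, got {X.shape[0]}")
    sd = X.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            "zero-variance features; their correlations are set to 0: "
            + ", ".join(table.feature_ids[i] for i in degenerate),
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    ids = table.feature_ids
    return pd.DataFrame(corr, index=ids, columns=ids)


def low_correlation_counts(corr: pd.DataFrame, delta: float) -> pd.Series:
    """Per feature: how many *other* features have correlation in [-delta, delta]."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    A = np.abs(corr.to_numpy(dtype=float))
    counts = (A <= delta).sum(axis=1) - (np.diag(A) <= delta)
    return pd.Series(counts.astype(int), index=corr.index)


def low_correlation_set(corr: pd.DataFrame, delta: float, M_L: int) -> list[str]:
    """``U``: features with low correlation with at least ``M_L`` others."""
    M = corr.shape[0]
    if not 1 <= M_L <= M - 1:
        raise ValueError(f"M_L must be in [1, {M - 1}], got {M_L}")
    counts = low_correlation_counts(corr, delta)
    return [f for f in corr.index if counts[f] >= M_L]


# --- significance ---------------------------------------------------------

def welch_p_values(table: FeatureTable) -> pd.Series:
    """Two-tailed Welch (unequal-variance) t-test p-value per feature.

    If both groups have zero variance on a feature, the convention t = 0 is
    used when the group means agree (p = 1); distinct constant means give
    p = 0.
    """
    g = table.groups.to_numpy()
    X0 = table.data.to_numpy(dtype=float)[g == 0]
    X1 = table.data.to_numpy(dtype=float)[g == 1]
    if X0.shape[0] < 2 or X1.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(X0, X1, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    if np.isnan(p).any():  # zero variance in both groups
        mean_diff = X0.mean(axis=0) - X1.mean(axis=0)
        p = np.where(np.isnan(p), np.where(mean_diff == 0, 1.0, 0.0), p)
    return pd.Series(p, index=table.feature_ids, name="p")


def significance_set(table: FeatureTable, alpha: float = DEFAULT_ALPHA,
                     bh_correct: bool = False) -> tuple[list[str], pd.Series]:
    """``Q``: features separating the groups at strict p < alpha.

    ``bh_correct`` switches to Benjamini-Hochberg adjusted p-values; the
    default (off) matches standard uncorrected per-feature screening.
    """
    p = welch_p_values(table)
    if bh_correct:
        p = pd.Series(stats.false_discovery_control(p.to_numpy(), method="bh"),
                      index=p.index, name="p_bh")
    Q = [f for f in table.feature_ids if p[f] < alpha]
    return Q, p


def salient_features(U: list[str], Q: list[str],
                     catalog: list[str] | None = None) -> list[str]:
    """``phi = U ∩ Q``, ordered by catalog (or U-list) index."""
    order = {f: i for i, f in enumerate(catalog if catalog is not None else U)}
    phi = set(U) & set(Q)
    return sorted(phi, key=lambda f: order.get(f, len(order)))


def select_salient(table: FeatureTable, delta: float, M_L: int = DEFAULT_ML,
                   alpha: float = DEFAULT_ALPHA) -> SelectionResult:
    """One-shot selection at fixed delta: U, Q, and phi = U ∩ Q."""
    corr = correlation_matrix(table)
    U = low_correlation_set(corr, delta, M_L)
    Q, p = significance_set(table, alpha)
    phi = salient_features(U, Q, table.feature_ids)
    return SelectionResult(delta=delta, M_L=M_L, alpha=alpha,
                           U=U, Q=Q, phi=phi, p_values=p)


# --- delta sweep ----------------------------------------------------------

def delta_sweep(table: FeatureTable, M_L: int = DEFAULT_ML,
                grid: np.ndarray | None = None,
                alpha: float = DEFAULT_ALPHA,
                cv_config=None,
                set_sizes: list[int] | None = None):
    """Sweep delta over a grid; rank features by the delta at which they
    first enter phi.

    Returns ``(result, accuracy_by_size)``.  ``result.importance_order``
    ranks all M features: members of Q ascending by entry delta (ties broken
    by p-value then catalog order), followed by non-members of Q ascending
    by p-value then catalog order.  ``result.delta`` is the grid value whose
    phi achieves the best cross-validated accuracy (when ``cv_config`` is
    given; otherwise the largest grid value).

    When ``cv_config`` and ``set_sizes`` are provided, prediction accuracy /
    TP / FP are tabulated for the top-k features of the importance order at
    each requested size k.
    """
    from .prediction import repeated_leave_n_out  # deferred: avoids cycle

    if grid is None:
        grid = DEFAULT_DELTA_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty delta grid")
    grid = np.sort(grid)
    corr = correlation_matrix(table)
    Q, p = significance_set(table, alpha)
    ids = table.feature_ids
    cat_index = {f: i for i, f in enumerate(ids)}

    entry: dict[str, float] = {}
    phis: dict[float, list[str]] = {}
    A = np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(A, np.inf)  # self never counts
    Qset = set(Q)
    for d in grid:
        counts = (A <= d).sum(axis=1)
        U_mask = counts >= M_L
        phi = [f for i, f in enumerate(ids) if U_mask[i] and f in Qset]
        phis[float(d)] = phi
        for f in phi:
            entry.setdefault(f, float(d))

    in_q = sorted(Qset, key=lambda f: (entry.get(f, np.inf), p[f], cat_index[f]))
    rest = sorted((f for f in ids if f not in Qset),
                  key=lambda f: (p[f], cat_index[f]))
    importance = in_q + rest

    accuracy_rows = []
    best_delta = float(grid[-1])
    if cv_config is not None:
        # evaluate only the distinct nested phi sets (at most |Q| + 1)
        seen: dict[frozenset, float] = {}
        for d in grid:
            key = frozenset(phis[float(d)])
            if key and key not in seen:
                cv = repeated_leave_n_out(table, phis[float(d)], cv_config)
                seen[key] = cv.accuracy
        if seen:
            best_acc = max(seen.values())
            for d in grid:  # smallest delta attaining the best accuracy
                key = frozenset(phis[float(d)])
                if key in seen and seen[key] == best_acc:
                    best_delta = float(d)
                    break
        if set_sizes:
            for k in set_sizes:
                feats = importance[:k]
                cv = repeated_leave_n_out(table, feats, cv_config)
                accuracy_rows.append({"n_features": k, "accuracy": cv.accuracy,
                                      "tp": cv.tp, "fp": cv.fp})

    U_best = low_correlation_set(corr, best_delta, M_L)
    result = SelectionResult(
        delta=best_delta, M_L=M_L, alpha=alpha,
        U=U_best, Q=sorted(Qset, key=cat_index.get),
        phi=salient_features(U_best, Q, ids),
        p_values=p, importance_order=importance, entry_delta=entry,
    )
    accuracy_by_size = pd.DataFrame(accuracy_rows,
                                    columns=["n_features", "accuracy", "tp", "fp"])
    return result, accuracy_by_size


def p_value_histogram(p_values, bins=20) -> np.ndarray:
    """Histogram counts of per-feature p-values over [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    counts, _ = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return counts
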