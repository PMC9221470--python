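"""Fast correlation-based filter (FCBF) feature selection.

FCBF scores each candidate feature by its symmetrical uncertainty (SU) with
the class, SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)), keeps those above a
relevance threshold, and then removes redundant features: scanning the
survivors in decreasing relevance order, a feature q is dropped when an
already-retained, more relevant feature p satisfies SU(p, q) >= SU(q, class)
(p "predominates" q).  The number of selected features therefore emerges
from the data rather than being fixed in advance.

Features enter discretized to three levels: an already z-normalized value
maps to -1 below -0.5, to 0 on [-0.5, 0.5] (closed interval), and to +1
above 0.5.  Entropies use base 2; SU is base-invariant but the base is fixed
for reproducibility.  Selection is applied to the radiomic features only —
clinical covariates always enter the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def discretize(values: np.ndarray) -> np.ndarray:
    """Map z-normalized values to {-1, 0, +1} at thresholds +-0.5."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("discretize expects finite (already imputed) input")
    out = np.zeros(values.shape, dtype=np.int8)
    out[values < -0.5] = -1
    out[values > 0.5] = 1
    return out


def _entropy_from_counts(counts: np.ndarray, n: float) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(x, y) in [0, 1]; 0 when either variable is constant."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must have equal, positive length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    n = float(x.size)
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    hx = _entropy_from_counts(np.bincount(xi), n)
    hy = _entropy_from_counts(np.bincount(yi), n)
    hxy = _entropy_from_counts(joint, n)
    if hx + hy == 0.0:
        return 0.0
    mi = hx + hy - hxy
    return max(0.0, 2.0 * mi / (hx + hy))


# ---------------------------------------------------------------------------
# vectorized SU helpers (ternary feature columns vs binary class / feature)
# ---------------------------------------------------------------------------


def _su_columns_class(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SU of each ternary column of X (n x m, values in {-1,0,1}) with the
    binary class vector y."""
    n, m = X.shape
    yb = (np.asarray(y) > 0).astype(np.int64)
    codes = (X.astype(np.int64) + 1) * 2 + yb[:, None]  # 0..5
    flat = codes + 6 * np.arange(m)[None, :]
    joint = np.bincount(flat.ravel(), minlength=6 * m).reshape(m, 6).astype(float)
    xc = joint.reshape(m, 3, 2).sum(axis=2)
    yc = joint.reshape(m, 3, 2).sum(axis=1)
    hx = _entropy_rows(xc, n)
    hy = _entropy_rows(yc, n)
    hxy = _entropy_rows(joint, n)
    denom = hx + hy
    with np.errstate(invalid="ignore", divide="ignore"):
        su = 2.0 * (hx + hy - hxy) / denom
    su[denom == 0] = 0.0
    return np.clip(su, 0.0, 1.0)


def _su_columns_pair(x: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """SU of one ternary vector x with each ternary column of Q."""
    n, m = Q.shape
    codes = (Q.astype(np.int64) + 1) * 3 + (x.astype(np.int64) + 1)[:, None]  # 0..8
    flat = codes + 9 * np.arange(m)[None, :]
    joint = np.bincount(flat.ravel(), minlength=9 * m).reshape(m, 9).astype(float)
    qc = joint.reshape(m, 3, 3).sum(axis=2)
    xc = joint.reshape(m, 3, 3).sum(axis=1)
    hq = _entropy_rows(qc, n)
    hx = _entropy_rows(xc, n)
    hqx = _entropy_rows(joint, n)
    denom = hq + hx
    with np.errstate(invalid="ignore", divide="ignore"):
        su = 2.0 * (hq + hx - hqx) / denom
    su[denom == 0] = 0.0
    return np.clip(su, 0.0, 1.0)


def _entropy_rows(counts: np.ndarray, n: float) -> np.ndarray:
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=1)


@dataclass
class SelectionResult:
    """FCBF outcome: the retained features in decreasing relevance order,
    the SU-to-class of every candidate, and which predominant feature
    removed which redundant one."""

    selected: list[str]
    su_to_class: dict[str, float]
    removal_log: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "su_to_class": {k: float(v) for k, v in self.su_to_class.items()},
            "removed": [list(pair) for pair in self.removal_log],
        }


def fcbf(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    delta: float = 0.0,
) -> SelectionResult:
    """Run FCBF on a discretized feature matrix.

    X : (n, m) matrix with values in {-1, 0, 1}; y : binary labels.
    delta : relevance threshold; only features with SU(f, class) > delta
    are candidates.  Relevance ties are broken by feature name so the scan
    order (and hence the selection) is deterministic.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a 2-D matrix with at least one feature")
    m = X.shape[1]
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(m)]
    if len(names) != m:
        raise ValueError("feature_names length mismatch")

    su_class = _su_columns_class(X, np.asarray(y))
    su_map = {names[j]: float(su_class[j]) for j in range(m)}
    cand = [j for j in range(m) if su_class[j] > delta]
    # decreasing relevance, ties by name
    cand.sort(key=lambda j: (-su_class[j], names[j]))

    selected: list[int] = []
    removal: list[tuple[str, str]] = []
    remaining = cand
    while remaining:
        p = remaining[0]
        selected.append(p)
        rest = remaining[1:]
        if not rest:
            break
        pair_su = _su_columns_pair(X[:, p], X[:, rest])
        keep = []
        for k, q in enumerate(rest):
            # predominance at exact equality removes q; the epsilon makes the
            # comparison robust to floating-point noise in tied entropies
            if pair_su[k] >= su_class[q] - 1e-12:
                removal.append((names[p], names[q]))
            else:
                keep.append(q)
        remaining = keep
    return SelectionResult(
        selected=[names[j] for j in selected],
        su_to_class=su_map,
        removal_log=removal,
    )
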