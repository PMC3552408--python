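"""Environmental distance: correlation filtering, rotated PCA, factor-score distances.

Sites are characterized by numeric environment variables (climate, soil,
elevation).  Highly inter-correlated variables are removed first (pairs
with Pearson-correlation p below a threshold, default 0.001, pruned by a
greedy rule), the survivors are ordinated by PCA on the correlation matrix
with varimax rotation, and environmental distance between sites is the
Euclidean distance between their rotated factor scores.  Climate-only,
soil-only and composite matrices are built from the same input by variable
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .core import DistanceMatrix, SiteEnvironment, ValidationError, environment_frame

__all__ = ["FilterReport", "OrdinationResult", "filter_correlated", "ordinate", "env_distance"]


@dataclass
class FilterReport:
    """Outcome of the correlated-variable filter."""

    kept: list[str]
    dropped: list[dict] = field(default_factory=list)  # {variable, reason, r, p}
    threshold_p: float = 0.001


@dataclass
class OrdinationResult:
    """Rotated PCA of site environment variables.

    ``scores`` (sites × components) are the rotated factor scores used for
    environmental distance; ``loadings`` are variables × components;
    ``explained_variance_pct`` is the retained share of total variance.
    """

    site_labels: list[str]
    variables: list[str]
    n_components: int
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_pct: float
    rotation: str


# ---------------------------------------------------------------------------
# correlation filter
# ---------------------------------------------------------------------------


def filter_correlated(
    sites: list[SiteEnvironment],
    variables: list[str] | None = None,
    p_threshold: float = 0.001,
) -> FilterReport:
    """Greedy removal of variables involved in highly significant correlations.

    At each step the variable participating in the most pairs with
    Pearson-correlation p < ``p_threshold`` is dropped (ties broken by the
    larger mean |r| over its offending pairs, then alphabetically); the
    procedure stops when no offending pair remains.  Constant variables are
    dropped first with reason "zero variance".  Needs >= 4 sites so the
    correlation p-value is computable.
    """
    frame = environment_frame(sites)
    variables = list(variables) if variables is not None else list(frame.columns)
    if len(sites) < 4:
        raise ValidationError("need >= 4 sites for correlation p-values")
    dropped: list[dict] = []
    active: list[str] = []
    for v in variables:
        if v not in frame.columns:
            raise ValidationError(f"variable {v!r} not present")
        if float(np.ptp(frame[v].to_numpy())) == 0.0:
            dropped.append({"variable": v, "reason": "zero variance", "r": None, "p": None})
        else:
            active.append(v)

    def offending_pairs(vs: list[str]) -> dict[tuple[str, str], tuple[float, float]]:
        out = {}
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                r, p = stats.pearsonr(frame[vs[i]], frame[vs[j]])
                if p < p_threshold:
                    out[(vs[i], vs[j])] = (float(r), float(p))
        return out

    while True:
        pairs = offending_pairs(active)
        if not pairs:
            break
        counts: dict[str, list[float]] = {v: [] for v in active}
        for (a, b), (r, _) in pairs.items():
            counts[a].append(abs(r))
            counts[b].append(abs(r))
        # most offending pairs; ties -> larger mean |r|; then alphabetical
        victim = sorted(
            (v for v in active if counts[v]),
            key=lambda v: (-len(counts[v]), -float(np.mean(counts[v])), v),
        )[0]
        partner_pairs = [(k, v) for k, v in pairs.items() if victim in k]
        (a, b), (r, p) = max(partner_pairs, key=lambda kv: abs(kv[1][0]))
        other = b if a == victim else a
        dropped.append({"variable": victim, "reason": f"correlated-with {other}",
                        "r": r, "p": p})
        active.remove(victim)
    return FilterReport(kept=active, dropped=dropped, threshold_p=p_threshold)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation matrix (Kaiser-normalized)."""
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    h = np.sqrt((loadings**2).sum(axis=1))
    h[h == 0] = 1.0
    A = loadings / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ T
        u, s, vt = np.linalg.svd(A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p))
        T = u @ vt
        d_new = s.sum()
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    return T


def ordinate(
    sites: list[SiteEnvironment],
    variables: list[str],
    rotation: str = "varimax",
    retain: str | int = "kaiser",
) -> OrdinationResult:
    """PCA on the correlation matrix of standardized variables, with rotation.

    Components are retained by the Kaiser rule (eigenvalue > 1) or a fixed
    count (``retain="fixed:k"`` or an int).  Varimax rotation
    (Kaiser-normalized, tol 1e-8, <= 1000 iterations) is applied to the
    loadings, and scores are rotated consistently, so communalities and
    Euclidean score distances over all retained components are preserved.
    """
    frame = environment_frame(sites)
    for v in variables:
        if v not in frame.columns:
            raise ValidationError(f"variable {v!r} not present")
    X = frame[list(variables)].to_numpy(dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [variables[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant variables cannot be ordinated: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]

    if retain == "kaiser":
        k = max(1, int((eigval > 1.0).sum()))
    else:
        if isinstance(retain, str):
            if not retain.startswith("fixed:"):
                raise ValidationError(f"unknown retention rule {retain!r}")
            k = int(retain.split(":", 1)[1])
        else:
            k = int(retain)
        if k < 1:
            raise ValidationError("must retain >= 1 component")
    if k >= n:
        raise ValidationError(f"retained components ({k}) must be < number of sites ({n})")
    k = min(k, p)

    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    scores = Z @ eigvec[:, :k]
    if rotation == "varimax" and k > 1:
        T = _varimax(loadings)
        loadings = loadings @ T
        scores = scores @ T
    elif rotation not in ("varimax", "none"):
        raise ValidationError(f"unknown rotation {rotation!r}")
    explained = float(eigval[:k].sum() / eigval.sum() * 100.0)
    return OrdinationResult(
        site_labels=list(frame.index),
        variables=list(variables),
        n_components=k,
        loadings=loadings,
        scores=scores,
        explained_variance_pct=explained,
        rotation=rotation,
    )


def env_distance(ordination: OrdinationResult) -> DistanceMatrix:
    """Pairwise Euclidean distance between rotated factor scores."""
    values = squareform(pdist(ordination.scores, metric="euclidean"))
    return DistanceMatrix(ordination.site_labels, values, kind="environmental")
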