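"""Mantel permutation tests between labelled distance matrices.

The Mantel statistic r is the Pearson correlation of the upper-triangle
entries of two distance matrices over the same labels.  Because matrix
entries sharing a row are not independent, significance comes from the
permutation null: rows and columns of one matrix are permuted
simultaneously (a relabeling of its objects — the only valid Mantel null)
and r is recomputed.  The p-value uses the +1 convention,
p = (#{extreme} + 1)/(n_perm + 1), so it is never zero and never below
1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DistanceMatrix, ValidationError

__all__ = ["MantelResult", "mantel"]

TAILS = ("two", "upper", "lower")


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    tail: str


def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10_000,
    tail: str = "two",
    seed: int | None = None,
    chunk: int = 4096,
) -> MantelResult:
    """Mantel test between two distance matrices over the same labels.

    ``b`` is reordered to ``a``'s label order first.  Requires n >= 4 and
    non-constant triangles.  Reproducible given ``seed``.
    """
    if tail not in TAILS:
        raise ValidationError(f"unknown tail {tail!r}")
    if a.n < 4:
        raise ValidationError("need >= 4 objects for a Mantel test")
    if set(a.labels) != set(b.labels):
        missing = sorted(set(a.labels) ^ set(b.labels))
        raise ValidationError(f"label sets differ: unshared labels {missing}")
    b = b.reorder(a.labels)
    x = _triangle(a.values)
    y = _triangle(b.values)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError("zero-variance triangle: Mantel r undefined")

    xc = x - x.mean()
    xnorm = np.linalg.norm(xc)
    yc = y - y.mean()
    r_obs = float(xc @ yc / (xnorm * np.linalg.norm(yc)))

    n = a.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    B = b.values
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # batch of random permutations via argsort of uniforms
        perm = np.argsort(rng.random((m, n)), axis=1)
        bp = B[perm[:, :, None], perm[:, None, :]]  # (m, n, n)
        yp = bp[:, iu[0], iu[1]]  # (m, n_pairs)
        ypc = yp - yp.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(ypc, axis=1) * xnorm
        r_perm = (ypc @ xc) / denom
        if tail == "two":
            count += int((np.abs(r_perm) >= abs(r_obs) - 1e-15).sum())
        elif tail == "upper":
            count += int((r_perm >= r_obs - 1e-15).sum())
        else:
            count += int((r_perm <= r_obs + 1e-15).sum())
        done += m
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed, tail=tail)
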