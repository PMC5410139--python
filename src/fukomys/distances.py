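"""Pairwise and group-mean genetic distances.

Implements uncorrected p distances and the Tamura–Nei (TN93) distance with
an optional gamma rate-heterogeneity correction (shape ``alpha``; the study
value for cyt b is 1.4964).  Missing data are handled by pairwise deletion:
a site enters a comparison only when both rows carry an unambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, BASES
from .errors import SaturationError, UndefinedDistanceError

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PairwiseCounts:
    """Sufficient statistics of one sequence pair for the TN93 estimator.

    ``P1`` is the proportion of compared sites showing an A<->G difference,
    ``P2`` the C<->T proportion, ``Q`` the transversion proportion, and
    ``base_freqs`` the (A, C, G, T) frequencies used by the estimator.
    """

    n_compared: int
    P1: float
    P2: float
    Q: float
    base_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if not (0 <= self.P1 <= 1 and 0 <= self.P2 <= 1 and 0 <= self.Q <= 1):
            raise ValueError("P1, P2, Q must lie in [0, 1]")
        if self.P1 + self.P2 + self.Q > 1 + 1e-12:
            raise ValueError("P1 + P2 + Q must not exceed 1")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with its model tag."""

    labels: list[str]
    matrix: np.ndarray
    model: str  # "p" | "tn93" | "tn93_gamma"
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        header = f"# model={self.model}"
        if self.alpha is not None:
            header += f" alpha={self.alpha}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def _comparable_mask(a: Alignment, i: int, j: int) -> np.ndarray:
    ri, rj = a.matrix[i], a.matrix[j]
    ok_i = np.isin(ri, list(BASES))
    ok_j = np.isin(rj, list(BASES))
    return ok_i & ok_j


def count_substitutions(a: Alignment, i: int, j: int) -> int:
    """Number of sites where both rows are unambiguous and differ."""
    if i == j:
        raise IndexError("i and j must differ")
    mask = _comparable_mask(a, i, j)
    return int(np.sum(a.matrix[i][mask] != a.matrix[j][mask]))


def n_compared(a: Alignment, i: int, j: int) -> int:
    return int(np.sum(_comparable_mask(a, i, j)))


def p_distance(a: Alignment, i: int, j: int) -> float:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    nc = n_compared(a, i, j)
    if nc == 0:
        raise UndefinedDistanceError(
            f"no comparable sites between rows {i} and {j}"
        )
    return count_substitutions(a, i, j) / nc

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def pairwise_counts(
    a: Alignment, i: int, j: int, freqs: str = "pair"
) -> PairwiseCounts:
    """Compute TN93 sufficient statistics for one row pair.

    ``freqs="pair"`` pools empirical base frequencies over the two rows at
    comparable sites (the distance-literature default); ``freqs="alignment"``
    uses alignment-wide frequencies over all unambiguous characters.
    """
    mask = _comparable_mask(a, i, j)
    nc = int(mask.sum())
    if nc == 0:
        raise UndefinedDistanceError(
            f"no comparable sites between rows {i} and {j}"
        )
    ri = a.matrix[i][mask]
    rj = a.matrix[j][mask]
    diff = ri != rj
    pair_sets = [frozenset((x, y)) for x, y in zip(ri[diff], rj[diff])]
    n_ag = sum(1 for s in pair_sets if s == frozenset("AG"))
    n_ct = sum(1 for s in pair_sets if s == frozenset("CT"))
    n_tv = len(pair_sets) - n_ag - n_ct
    if freqs == "pair":
        pool = np.concatenate([ri, rj])
    elif freqs == "alignment":
        flat = a.matrix.ravel()
        pool = flat[np.isin(flat, list(BASES))]
    else:
        raise ValueError("freqs must be 'pair' or 'alignment'")
    counts = np.array([np.sum(pool == b) for b in BASES], dtype=float)
    return PairwiseCounts(
        n_compared=nc,
        P1=n_ag / nc,
        P2=n_ct / nc,
        Q=n_tv / nc,
        base_freqs=counts / counts.sum(),
    )


def tn93_gamma_distance(counts: PairwiseCounts, alpha: float | None) -> float:
    """Tamura–Nei distance, optionally gamma-corrected.

    With ``alpha=None`` (or ``inf``) the plain TN93 estimator is returned;
    otherwise each ``-ln(w)`` term is replaced by ``alpha * (w**(-1/alpha) - 1)``,
    the standard gamma-rates form.  Raises :class:`SaturationError` when a
    log/power argument is non-positive (sequences too diverged to correct).
    """
    pa, pc, pg, pt = counts.base_freqs
    pr = pa + pg
    py = pc + pt
    if min(pa, pc, pg, pt) <= 0:
        raise SaturationError("zero base frequency; TN93 distance undefined")
    k1 = 2 * pa * pg / pr
    k2 = 2 * pc * pt / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    w1 = 1 - counts.P1 / k1 - counts.Q / (2 * pr)
    w2 = 1 - counts.P2 / k2 - counts.Q / (2 * py)
    w3 = 1 - counts.Q / (2 * pr * py)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError(
            f"TN93 not estimable (w1={w1:.4g}, w2={w2:.4g}, w3={w3:.4g}); "
            "divergence at or beyond saturation"
        )
    if alpha is None or np.isinf(alpha):
        def corr(w: float) -> float:
            return -np.log(w)
    else:
        if alpha <= 0:
            raise ValueError("alpha must be positive")

        def corr(w: float) -> float:
            return alpha * (w ** (-1.0 / alpha) - 1.0)

    d = k1 * corr(w1) + k2 * corr(w2) + k3 * corr(w3)
    return float(d)


def pairwise_distance_matrix(
    a: Alignment,
    model: str = "p",
    alpha: float | None = None,
    freqs: str = "pair",
) -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` in {"p", "tn93", "tn93_gamma"}."""
    if model not in {"p", "tn93", "tn93_gamma"}:
        raise ValueError(f"unknown distance model {model!r}")
    if model == "tn93_gamma" and alpha is None:
        raise ValueError("tn93_gamma requires alpha")
    n = a.n
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p":
                d = p_distance(a, i, j)
            else:
                cts = pairwise_counts(a, i, j, freqs=freqs)
                d = tn93_gamma_distance(
                    cts, alpha if model == "tn93_gamma" else None
                )
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(
        labels=list(a.ids),
        matrix=mat,
        model=model,
        alpha=alpha if model == "tn93_gamma" else None,
    )


def group_mean_distances(
    dm: DistanceMatrix, grouping: dict[str, str]
) -> DistanceMatrix:
    """Arithmetic mean of pairwise distances between (and within) groups.

    Between-group entries average all cross pairs; within-group entries
    average distinct pairs.  A singleton group's within-group mean is
    undefined and reported as NaN.
    """
    missing = [lab for lab in dm.labels if lab not in grouping]
    if missing:
        raise KeyError(f"labels without a group assignment: {missing}")
    groups: list[str] = []
    for lab in dm.labels:
        g = grouping[lab]
        if g not in groups:
            groups.append(g)
    idx = {g: [i for i, lab in enumerate(dm.labels) if grouping[lab] == g] for g in groups}
    k = len(groups)
    out = np.full((k, k), np.nan)
    for gi in range(k):
        for gj in range(gi, k):
            rows, cols = idx[groups[gi]], idx[groups[gj]]
            if gi == gj:
                pairs = [
                    dm.matrix[r, c]
                    for a_, r in enumerate(rows)
                    for c in rows[a_ + 1:]
                ]
                out[gi, gj] = np.mean(pairs) if pairs else np.nan
            else:
                vals = dm.matrix[np.ix_(rows, cols)]
                out[gi, gj] = out[gj, gi] = float(vals.mean())
    return DistanceMatrix(labels=groups, matrix=out, model=dm.model, alpha=dm.alpha)
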