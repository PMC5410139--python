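"""Dispersal-extinction-cladogenesis (DEC) likelihood engine.

Geographic ranges are subsets of a small set of areas (the study uses seven:
SZ, SL, WK, EK, MTJ, ER, WA).  Anagenetic evolution along branches is a
continuous-time Markov chain: a range gains area ``a`` at rate
``d * sum_b m[b->a]`` over occupied areas ``b`` (``m`` an epoch-specific
dispersal multiplier matrix) and loses an occupied area at rate ``e``; the
empty range is absorbing (global extinction; the likelihood is NOT
conditioned on survival).  At cladogenesis a range of k>=2 areas divides by
subset sympatry (one daughter a single occupied area, the other the full
range) or vicariance (one daughter a single area, the other the remainder),
all permitted ordered scenarios equally weighted; a single-area range is
inherited identically by both daughters.

Epoch-stratified models tile the root-to-present time axis with dispersal
multiplier matrices; branch transition matrices are products of per-segment
matrix exponentials ordered oldest to youngest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

import dendropy

from .errors import ConfigError, ImpossibleDataError
from .trees import assert_ultrametric, node_ages

STUDY_AREAS = ("SZ", "SL", "WK", "EK", "MTJ", "ER", "WA")
#: Adjacent-area composites defining the study's constrained range set (M1).
M1_COMPOSITES = (
    ("WA", "EK", "WK"),
    ("ER", "MTJ", "EK"),
    ("MTJ", "EK", "WK", "SZ"),
    ("EK", "WK", "SZ", "SL"),
    ("WK", "SZ", "SL"),
    ("SZ", "SL"),
)


@dataclass
class Epoch:
    """One time slice of a stratified model.

    ``start`` is the young bound and ``end`` the old bound (Mya,
    start < end).  ``multipliers`` is an n_areas x n_areas 0/1 (or [0,1])
    matrix, rows = source area, columns = target area; the diagonal is
    ignored.
    """

    start: float
    end: float
    multipliers: np.ndarray

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if self.end <= self.start:
            raise ConfigError("epoch end (older) must exceed start (younger)")


@dataclass
class DECModelSpec:
    """Areas, allowed ranges, epochs and root prior of one DEC model."""

    areas: tuple[str, ...] = STUDY_AREAS
    allowed_ranges: list[frozenset[str]] | None = None  # None -> all non-empty
    epochs: list[Epoch] = field(default_factory=list)
    root_prior: str = "uniform"  # uniform over allowed non-empty ranges

    def __post_init__(self) -> None:
        self.areas = tuple(self.areas)
        if len(set(self.areas)) != len(self.areas):
            raise ConfigError("area codes must be unique")
        if len(self.areas) > 16:
            raise ConfigError("at most 16 areas supported")
        if self.allowed_ranges is not None:
            bad = [r for r in self.allowed_ranges if not set(r) <= set(self.areas)]
            if bad:
                raise ConfigError(f"allowed ranges outside the area set: {bad}")
            self.allowed_ranges = sorted(
                {frozenset(r) for r in self.allowed_ranges} - {frozenset()},
                key=lambda r: (len(r), sorted(self.areas.index(a) for a in r)),
            )
        if self.epochs:
            bounds = sorted((ep.start, ep.end) for ep in self.epochs)
            for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
                if abs(e1 - s2) > 1e-9:
                    raise ConfigError(
                        f"epochs must tile time without gaps/overlaps: "
                        f"{e1} vs {s2}"
                    )

    @classmethod
    def m0(cls, areas: tuple[str, ...] = STUDY_AREAS) -> "DECModelSpec":
        return cls(areas=areas, allowed_ranges=None)

    @classmethod
    def m1(cls, areas: tuple[str, ...] = STUDY_AREAS) -> "DECModelSpec":
        """Ranges restricted to subsets of the six adjacent-area composites."""
        allowed: set[frozenset[str]] = set()
        for comp in M1_COMPOSITES:
            members = list(comp)
            for mask in range(1, 2 ** len(members)):
                allowed.add(
                    frozenset(m for i, m in enumerate(members) if mask >> i & 1)
                )
        return cls(areas=areas, allowed_ranges=sorted(
            allowed, key=lambda r: (len(r), sorted(areas.index(a) for a in r))
        ))

    @classmethod
    def from_json(cls, path) -> "DECModelSpec":
        with open(path) as fh:
            cfg = json.load(fh)
        known = {"areas", "allowed_ranges", "max_size", "epochs", "root_prior"}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown DEC config keys: {sorted(unknown)}")
        areas = tuple(cfg["areas"])
        allowed = None
        if cfg.get("allowed_ranges"):
            allowed = [frozenset(r) for r in cfg["allowed_ranges"]]
        elif cfg.get("max_size"):
            k = int(cfg["max_size"])
            allowed = [
                frozenset(a for i, a in enumerate(areas) if mask >> i & 1)
                for mask in range(1, 2 ** len(areas))
                if bin(mask).count("1") <= k
            ]
        epochs = [
            Epoch(ep["start"], ep["end"], np.array(ep["matrix"], dtype=float))
            for ep in cfg.get("epochs", [])
        ]
        return cls(
            areas=areas,
            allowed_ranges=allowed,
            epochs=epochs,
            root_prior=cfg.get("root_prior", "uniform"),
        )


def build_state_space(spec: DECModelSpec) -> list[frozenset[str]]:
    """Ordered range states: the empty range first, then allowed non-empty
    ranges by (size, area order)."""
    if spec.allowed_ranges is None:
        nonempty = [
            frozenset(a for i, a in enumerate(spec.areas) if mask >> i & 1)
            for mask in range(1, 2 ** len(spec.areas))
        ]
        nonempty.sort(
            key=lambda r: (len(r), sorted(spec.areas.index(a) for a in r))
        )
    else:
        nonempty = list(spec.allowed_ranges)
    return [frozenset()] + nonempty


def build_q(
    spec: DECModelSpec,
    d: float,
    e: float,
    epoch: Epoch | None = None,
) -> np.ndarray:
    """Anagenetic rate matrix over the state space.

    Expansion r -> r+{a} at rate ``d * sum_{b in r} m[b, a]`` (only into
    states in the allowed set); contraction r -> r-{a} at rate ``e``.  The
    empty range is absorbing.
    """
    if d < 0 or e < 0:
        raise ConfigError("rates d and e must be non-negative")
    states = build_state_space(spec)
    index = {s: i for i, s in enumerate(states)}
    n_areas = len(spec.areas)
    m = (
        epoch.multipliers
        if epoch is not None
        else np.ones((n_areas, n_areas))
    )
    ai = {a: i for i, a in enumerate(spec.areas)}
    q = np.zeros((len(states), len(states)))
    for s, r in enumerate(states):
        if not r:
            continue
        for a in spec.areas:
            if a in r:
                target = r - {a}
                if target in index:
                    q[s, index[target]] += e
            else:
                target = r | {a}
                if target in index:
                    rate = d * sum(m[ai[b], ai[a]] for b in r)
                    q[s, index[target]] += rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _segments(
    spec: DECModelSpec, child_age: float, parent_age: float
) -> list[tuple[float, Epoch | None]]:
    """Branch time slices (duration, epoch), ordered oldest -> youngest."""
    if parent_age <= child_age:
        raise ConfigError("parent_age must exceed child_age")
    if not spec.epochs:
        return [(parent_age - child_age, None)]
    eps = sorted(spec.epochs, key=lambda ep: -ep.start)  # oldest first
    oldest = max(ep.end for ep in eps)
    youngest = min(ep.start for ep in eps)
    if parent_age > oldest + 1e-9 or child_age < youngest - 1e-9:
        raise ConfigError(
            f"branch [{child_age}, {parent_age}] outside epoch cover "
            f"[{youngest}, {oldest}]"
        )
    out = []
    for ep in eps:
        lo = max(child_age, ep.start)
        hi = min(parent_age, ep.end)
        if hi - lo > 1e-12:
            out.append((hi - lo, ep))
    return out


class _BranchEngine:
    """Caches per-epoch rate matrices and their propagators for one (d, e).

    Each epoch's Q is eigendecomposed once so a branch segment's transition
    matrix is two dense multiplies; ill-conditioned decompositions fall back
    to scaling-and-squaring ``expm``.
    """

    def __init__(self, spec: DECModelSpec, d: float, e: float):
        self.spec = spec
        self._eig: dict[int, tuple | None] = {}
        self._q: dict[int, np.ndarray] = {}
        self._cache: dict[tuple[int, float], np.ndarray] = {}
        for key, epoch in self._epoch_items():
            q = build_q(spec, d, e, epoch)
            self._q[key] = q
            try:
                w, v = np.linalg.eig(q)
                vinv = np.linalg.inv(v)
                err = np.abs(np.real((v * w) @ vinv) - q).max()
                scale = max(np.abs(q).max(), 1.0)
                self._eig[key] = (w, v, vinv) if err < 1e-10 * scale else None
            except np.linalg.LinAlgError:
                self._eig[key] = None

    def _epoch_items(self):
        if not self.spec.epochs:
            return [(0, None)]
        return list(enumerate(self.spec.epochs, start=1))

    def _epoch_key(self, epoch: Epoch | None) -> int:
        if epoch is None:
            return 0
        return self.spec.epochs.index(epoch) + 1

    def segment_p(self, epoch: Epoch | None, dt: float) -> np.ndarray:
        key = (self._epoch_key(epoch), round(dt, 12))
        if key not in self._cache:
            eig = self._eig[key[0]]
            if eig is None:
                p = expm(self._q[key[0]] * dt)
            else:
                w, v, vinv = eig
                p = (v * np.exp(w * dt)) @ vinv
                p = np.real(p)
                np.clip(p, 0.0, None, out=p)
            self._cache[key] = p
        return self._cache[key]

    def branch_p(self, child_age: float, parent_age: float) -> np.ndarray:
        p = None
        for dt, epoch in _segments(self.spec, child_age, parent_age):
            seg = self.segment_p(epoch, dt)
            p = seg if p is None else p @ seg
        return p


def branch_probability(
    spec: DECModelSpec,
    d: float,
    e: float,
    child_age: float,
    parent_age: float,
) -> np.ndarray:
    """Transition probability matrix along one branch.

    Rows index the state at the old (parent) end, columns at the young
    (child) end; the product over epoch segments is taken oldest first.
    """
    return _BranchEngine(spec, d, e).branch_p(child_age, parent_age)


def cladogenesis_splits(
    r: frozenset[str], spec: DECModelSpec | None = None
) -> list[tuple[frozenset[str], frozenset[str], float]]:
    """Equally weighted ordered daughter-range scenarios for a splitting range.

    If a model spec is given, scenarios whose daughters fall outside the
    allowed range set are dropped and the weights renormalized.
    """
    if not r:
        raise ConfigError("the empty range cannot undergo cladogenesis")
    if len(r) == 1:
        return [(r, r, 1.0)]
    scenarios: set[tuple[frozenset, frozenset]] = set()
    for a in r:
        single = frozenset({a})
        rest = r - single
        scenarios.add((single, rest))   # vicariance
        scenarios.add((rest, single))
        scenarios.add((single, r))      # subset sympatry
        scenarios.add((r, single))
    if spec is not None and spec.allowed_ranges is not None:
        allowed = set(spec.allowed_ranges)
        scenarios = {
            (l, rr) for l, rr in scenarios if l in allowed and rr in allowed
        }
        if not scenarios:
            raise ConfigError(
                f"no resolvable cladogenetic split for allowed range {sorted(r)}"
            )
    ordered = sorted(
        scenarios, key=lambda s: (tuple(sorted(s[0])), tuple(sorted(s[1])))
    )
    w = 1.0 / len(ordered)
    return [(l, rr, w) for l, rr in ordered]


def _root_prior_vector(spec: DECModelSpec, states) -> np.ndarray:
    prior = np.zeros(len(states))
    nonempty = [i for i, s in enumerate(states) if s]
    prior[nonempty] = 1.0 / len(nonempty)
    return prior


def _prepare(chronogram, tip_ranges, spec):
    states = build_state_space(spec)
    index = {s: i for i, s in enumerate(states)}
    assert_ultrametric(chronogram, tol=1e-4)
    ages = node_ages(chronogram)
    for taxon, r in tip_ranges.items():
        if frozenset(r) not in index:
            raise ConfigError(
                f"tip {taxon!r} has range {sorted(r)} outside the allowed set"
            )
    labels = {lf.taxon.label for lf in chronogram.leaf_node_iter()}
    missing = labels - set(tip_ranges)
    if missing:
        raise ConfigError(f"tips without a range: {sorted(missing)}")
    return states, index, ages


def _node_partials(chronogram, tip_ranges, spec, d, e, states, index, ages):
    """Post-order conditional likelihoods and per-branch transition matrices."""
    engine = _BranchEngine(spec, d, e)
    partials: dict = {}
    branch_p: dict = {}
    for node in chronogram.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(len(states))
            v[index[frozenset(tip_ranges[node.taxon.label])]] = 1.0
            partials[node] = v
            continue
        msgs = []
        for child in node.child_nodes():
            p = engine.branch_p(
                child_age=max(ages[child], 0.0), parent_age=ages[node]
            )
            branch_p[child] = p
            msgs.append(p @ partials[child])
        parent_idx, left_idx, right_idx, weights = _split_table(
            spec, states, index
        )
        v = np.zeros(len(states))
        np.add.at(
            v, parent_idx, weights * msgs[0][left_idx] * msgs[1][right_idx]
        )
        partials[node] = v
    return partials, branch_p


def _split_table(spec, states, index):
    """Flat index arrays of all cladogenesis scenarios (cached on the spec)."""
    cache = getattr(spec, "_split_cache", None)
    if cache is None:
        pi, li, ri, wi = [], [], [], []
        for i, s in enumerate(states):
            if not s:
                continue
            for l, r, w in cladogenesis_splits(s, spec):
                pi.append(i)
                li.append(index[l])
                ri.append(index[r])
                wi.append(w)
        cache = (
            np.array(pi), np.array(li), np.array(ri), np.array(wi, dtype=float)
        )
        object.__setattr__(spec, "_split_cache", cache)
    return cache


@dataclass
class DECFitResult:
    loglik: float
    d: float
    e: float
    model_name: str = ""
    converged: bool = True
    n_restarts: int = 0

    def as_row(self) -> dict:
        return {
            "model": self.model_name,
            "lnL": self.loglik,
            "dispersal": self.d,
            "extinction": self.e,
        }


def dec_loglik(
    chronogram: dendropy.Tree,
    tip_ranges: dict[str, frozenset[str]],
    spec: DECModelSpec,
    d: float,
    e: float,
) -> float:
    """DEC log-likelihood of the observed tip ranges.

    Root states are weighted by a uniform prior over allowed non-empty
    ranges (the Lagrange default).
    """
    states, index, ages = _prepare(chronogram, tip_ranges, spec)
    partials, _ = _node_partials(
        chronogram, tip_ranges, spec, d, e, states, index, ages
    )
    prior = _root_prior_vector(spec, states)
    lik = float(prior @ partials[chronogram.seed_node])
    if lik <= 0:
        raise ImpossibleDataError(
            "constraints assign zero probability to the observed ranges "
            f"(first failing clade at root of {sorted(tip_ranges)[:3]}...)"
        )
    return float(np.log(lik))


def fit_dec(
    chronogram: dendropy.Tree,
    tip_ranges: dict[str, frozenset[str]],
    spec: DECModelSpec,
    model_name: str = "",
    seed: int = 0,
    n_restarts: int = 3,
) -> DECFitResult:
    """Maximize the DEC likelihood over (d, e) >= 0.

    Nelder–Mead on (log d, log e) from (log 0.01, log 0.01), with jittered
    restarts; the best optimum is kept.
    """
    from scipy.optimize import minimize

    states, index, ages = _prepare(chronogram, tip_ranges, spec)
    prior = _root_prior_vector(spec, states)

    def neg_loglik(x: np.ndarray) -> float:
        d, e = np.exp(np.clip(x, -25, 5))
        partials, _ = _node_partials(
            chronogram, tip_ranges, spec, d, e, states, index, ages
        )
        lik = float(prior @ partials[chronogram.seed_node])
        if lik <= 0 or not np.isfinite(lik):
            return 1e10
        return -np.log(lik)

    rng = np.random.default_rng(seed)
    start = np.log([0.01, 0.01])
    best = None
    converged = True
    for i in range(n_restarts):
        x0 = start if i == 0 else start + rng.normal(0, 1.0, size=2)
        res = minimize(
            neg_loglik, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        import warnings

        warnings.warn(
            f"DEC optimization did not fully converge: {best.message}"
        )
        converged = False
    d_hat, e_hat = np.exp(np.clip(best.x, -25, 5))
    return DECFitResult(
        loglik=-float(best.fun),
        d=float(d_hat),
        e=float(e_hat),
        model_name=model_name,
        converged=converged,
        n_restarts=n_restarts,
    )


def ancestral_ranges(
    fit: DECFitResult,
    chronogram: dendropy.Tree,
    tip_ranges: dict[str, frozenset[str]],
    spec: DECModelSpec,
    window: float = 2.0,
) -> dict:
    """Ranked split scenarios per internal node.

    For every internal node, every (range, left daughter, right daughter)
    scenario whose log-likelihood lies within ``window`` units of that
    node's best scenario is reported, ranked by log-likelihood (the
    conventional 2-unit confidence window).
    """
    d, e = fit.d, fit.e
    states, index, ages = _prepare(chronogram, tip_ranges, spec)
    partials, branch_p = _node_partials(
        chronogram, tip_ranges, spec, d, e, states, index, ages
    )
    prior = _root_prior_vector(spec, states)

    # outside ("above") likelihoods per node, at the node itself
    outside: dict = {chronogram.seed_node: prior.copy()}
    for node in chronogram.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        msgs = [branch_p[c] @ partials[c] for c in children]
        for ci, child in enumerate(children):
            sib_msg = msgs[1 - ci]
            start_vec = np.zeros(len(states))
            for i, s in enumerate(states):
                if not s or outside[node][i] == 0:
                    continue
                for l, rr, w in cladogenesis_splits(s, spec):
                    own, sib = (l, rr) if ci == 0 else (rr, l)
                    start_vec[index[own]] += (
                        outside[node][i] * w * sib_msg[index[sib]]
                    )
            outside[child] = branch_p[child].T @ start_vec

    results = {}
    for node in chronogram.preorder_internal_node_iter():
        children = node.child_nodes()
        msgs = [branch_p[c] @ partials[c] for c in children]
        scen = []
        for i, s in enumerate(states):
            if not s or outside[node][i] <= 0:
                continue
            for l, rr, w in cladogenesis_splits(s, spec):
                lik = outside[node][i] * w * msgs[0][index[l]] * msgs[1][index[rr]]
                if lik > 0:
                    scen.append((float(np.log(lik)), s, l, rr))
        scen.sort(key=lambda t: -t[0])
        if not scen:
            results[node] = []
            continue
        top = scen[0][0]
        results[node] = [
            {"lnl": lnl, "range": s, "left": l, "right": rr}
            for lnl, s, l, rr in scen
            if lnl >= top - window
        ]
    return results


def compare_models(results: list[DECFitResult]):
    """Tabulate fits and pairwise log-likelihood differences.

    Differences larger than 2 units (the conventional confidence window)
    are flagged.
    """
    import pandas as pd

    table = pd.DataFrame([r.as_row() for r in results])
    table["neg_lnL"] = -table["lnL"]
    diffs = []
    for i, a in enumerate(results):
        for b in results[i + 1:]:
            delta = a.loglik - b.loglik
            diffs.append(
                {
                    "model_a": a.model_name,
                    "model_b": b.model_name,
                    "delta_lnL": delta,
                    "decisive": abs(delta) > 2.0,
                }
            )
    return table, pd.DataFrame(diffs)
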