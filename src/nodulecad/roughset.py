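"""Rough-set feature-level fusion (attribute reduction).

A labeled feature table is min-max normalized, discretized into integer
codes, and viewed as a decision system: objects x condition attributes with
a binary decision.  Objects indistinguishable on an attribute subset P form
indiscernibility blocks; a block lies in the positive region POS_P(D) when
all its objects share one decision.  A *reduct* is a minimal attribute
subset whose positive region equals that of the full attribute set; the
*core* is the set of attributes indispensable to every reduct.

Because reducts are not unique, reduction is repeated with several seeds
(significance-guided backward elimination with seed-shuffled tie-breaking),
mirroring a five-repeat protocol.  The
downstream classifier consumes the continuous normalized values of the
retained attributes; discretization exists only to drive the reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_minmax(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column linear map to [0, 1]; constant columns map to 0."""
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        lo, hi = x.min(), x.max()
        out[col] = (x - lo) / (hi - lo) if hi > lo else x * 0.0
    return pd.DataFrame(out, index=table.index)


def _discretize_column(x: np.ndarray, bins: int, method: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(len(x), dtype=int)
    if method == "equal_width":
        codes = np.floor((x - lo) / (hi - lo) * bins).astype(int)
        return np.clip(codes, 0, bins - 1)
    if method == "equal_frequency":
        qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
        cuts = np.unique(qs)  # collapse tied quantiles
        return np.searchsorted(cuts, x, side="right")
    raise ValueError(f"unknown discretization method {method!r}")


def discretize(table: pd.DataFrame, bins: int = 2, method: str = "equal_width") -> pd.DataFrame:
    """Integer codes 0..bins-1 per column (ties may collapse bins)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if bins > len(table):
        raise ValueError(f"bins={bins} exceeds table size {len(table)}")
    codes = {
        col: _discretize_column(table[col].to_numpy(dtype=float), bins, method)
        for col in table.columns
    }
    return pd.DataFrame(codes, index=table.index)


# ---------------------------------------------------------------------------
# decision systems
# ---------------------------------------------------------------------------

@dataclass
class DecisionTable:
    """Discretized decision system: integer condition codes + binary decision."""

    codes: pd.DataFrame      # objects x condition attributes, integer codes
    decision: np.ndarray     # binary decision per object

    def __post_init__(self) -> None:
        self.decision = np.asarray(self.decision, dtype=int)
        if len(self.decision) != len(self.codes):
            raise ValueError("decision length does not match number of objects")
        if self.codes.isna().any().any():
            raise ValueError("decision table has missing cells")

    @property
    def attributes(self) -> Tuple[str, ...]:
        return tuple(self.codes.columns)

    @property
    def n_objects(self) -> int:
        return len(self.codes)


def build_decision_table(
    features: pd.DataFrame,
    labels: Sequence[int],
    bins: int = 2,
    method: str = "equal_width",
) -> DecisionTable:
    """Normalize + discretize a continuous feature table into a decision system."""
    return DecisionTable(
        codes=discretize(normalize_minmax(features), bins=bins, method=method),
        decision=np.asarray(labels, dtype=int),
    )


def indiscernibility_classes(dt: DecisionTable, P: Iterable[str]) -> List[np.ndarray]:
    """Partition of object indices into blocks identical on every attribute of P."""
    P = list(P)
    n = dt.n_objects
    if not P:
        return [np.arange(n)]
    sub = dt.codes[P].to_numpy()
    _, inverse = np.unique(sub, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    splits = np.flatnonzero(np.diff(inverse[order])) + 1
    return list(np.split(order, splits))


def approximations(dt: DecisionTable, P: Iterable[str], X: Set[int]) -> Tuple[Set[int], Set[int]]:
    """(lower, upper) P-approximations of the object subset X."""
    lower: Set[int] = set()
    upper: Set[int] = set()
    for block in indiscernibility_classes(dt, P):
        b = set(block.tolist())
        if b & X:
            upper |= b
            if b <= X:
                lower |= b
    return lower, upper


def positive_region(dt: DecisionTable, P: Iterable[str]) -> Tuple[FrozenSet[int], float]:
    """POS_P(D): objects in decision-pure blocks, and gamma = |POS|/|U|."""
    pos: List[int] = []
    d = dt.decision
    for block in indiscernibility_classes(dt, P):
        if np.all(d[block] == d[block[0]]):
            pos.extend(block.tolist())
    return frozenset(pos), len(pos) / dt.n_objects


def core(dt: DecisionTable) -> Tuple[str, ...]:
    """Attributes whose removal from C shrinks the positive region."""
    full_pos, _ = positive_region(dt, dt.attributes)
    result = []
    for a in dt.attributes:
        rest = [b for b in dt.attributes if b != a]
        pos, _ = positive_region(dt, rest)
        if pos != full_pos:
            result.append(a)
    return tuple(result)


@dataclass
class Reduct:
    """A minimal POS-preserving attribute subset with search provenance."""

    attributes: Tuple[str, ...]
    seed: int
    gamma: float

    def to_dict(self) -> dict:
        return {
            "attributes": list(self.attributes),
            "seed": int(self.seed),
            "gamma": float(self.gamma),
        }


def is_reduct(dt: DecisionTable, P: Sequence[str]) -> bool:
    """Exact check of the two reduct conditions (POS preservation, minimality)."""
    full_pos, _ = positive_region(dt, dt.attributes)
    pos, _ = positive_region(dt, P)
    if pos != full_pos:
        return False
    for a in P:
        rest = [b for b in P if b != a]
        sub_pos, _ = positive_region(dt, rest)
        if sub_pos == full_pos:
            return False
    return True


def find_reduct(dt: DecisionTable, seed: int = 0) -> Reduct:
    """Significance-guided backward elimination with seed-shuffled ties.

    Starting from the full attribute set, attributes are visited in order of
    increasing individual dependency degree gamma({a}) — so weakly
    informative attributes are offered up for elimination before strongly
    informative ones — and dropped whenever the positive region of the full
    set is preserved exactly.  Attributes whose significance agrees to two
    decimals are visited in a seed-dependent random order, which is what
    makes repeated runs land on different (equally valid) reducts.  Passes
    repeat until no attribute can be dropped, so the result is minimal.
    """
    rng = np.random.default_rng(seed)
    full_pos, _ = positive_region(dt, dt.attributes)
    kept = list(dt.attributes)
    significance = {a: positive_region(dt, [a])[1] for a in dt.attributes}
    shuffled = [dt.attributes[i] for i in rng.permutation(len(dt.attributes))]
    # stable sort: equal-significance attributes keep their shuffled order
    order = sorted(shuffled, key=lambda a: round(significance[a], 2))
    changed = True
    while changed:
        changed = False
        for a in order:
            if a not in kept:
                continue
            # the empty set is a legitimate reduct when POS_C is itself
            # reproducible without any attribute (e.g. constant decision)
            trial = [b for b in kept if b != a]
            pos, _ = positive_region(dt, trial)
            if pos == full_pos:
                kept = trial
                changed = True
    gamma = len(full_pos) / dt.n_objects
    # keep schema order, not search order
    kept_ordered = tuple(a for a in dt.attributes if a in kept)
    return Reduct(attributes=kept_ordered, seed=seed, gamma=gamma)


def enumerate_reducts(dt: DecisionTable) -> List[Tuple[str, ...]]:
    """Exhaustive reduct enumeration (oracle for small tables only)."""
    from itertools import combinations

    attrs = dt.attributes
    if len(attrs) > 16:
        raise ValueError("exhaustive enumeration is limited to <= 16 attributes")
    full_pos, _ = positive_region(dt, attrs)
    preserving: List[Tuple[str, ...]] = []
    for r in range(0, len(attrs) + 1):
        for sub in combinations(attrs, r):
            pos, _ = positive_region(dt, sub)
            if pos == full_pos:
                preserving.append(sub)
    reducts = [
        p for p in preserving
        if not any(set(q) < set(p) for q in preserving)
    ]
    return reducts


# ---------------------------------------------------------------------------
# fusion driver
# ---------------------------------------------------------------------------

@dataclass
class FusionResult:
    """Five-repeat reduction output: reducts plus projected continuous tables."""

    reducts: List[Reduct]
    projected: List[pd.DataFrame]  # normalized continuous values, reduct columns
    normalized: pd.DataFrame = field(repr=False, default=None)


def fuse(
    features: pd.DataFrame,
    labels: Sequence[int],
    bins: int = 2,
    method: str = "equal_width",
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> FusionResult:
    """Normalize, discretize, and reduce once per seed.

    Returns one reduct per seed and, for each, the *continuous* normalized
    feature table projected onto the reduct's columns (the classifier
    consumes continuous values; the integer codes only drive the search).
    """
    norm = normalize_minmax(features)
    dt = DecisionTable(
        codes=discretize(norm, bins=bins, method=method),
        decision=np.asarray(labels, dtype=int),
    )
    reducts = [find_reduct(dt, seed=s) for s in seeds]
    projected = [norm[list(r.attributes)] for r in reducts]
    return FusionResult(reducts=reducts, projected=projected, normalized=norm)


class RoughSetReducer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer performing rough-set attribute reduction.

    ``fit(X, y)`` normalizes and discretizes the training table, runs the
    seeded backward-elimination search, and stores the reduct.  ``transform``
    projects any table with the same columns onto the retained attributes
    (raw values are passed through; normalize separately if desired).

    Parameters
    ----------
    bins : discretization bins per attribute (default 2).
    method : 'equal_width' (default) or 'equal_frequency'.
    seed : search-order shuffle seed.

    Attributes
    ----------
    reduct_ : the fitted :class:`Reduct`.
    support_ : boolean mask over input columns.
    gamma_ : dependency degree of the full table.
    core_ : attributes indispensable in the training table.
    """

    def __init__(self, bins: int = 2, method: str = "equal_width", seed: int = 0,
                 compute_core: bool = False):
        self.bins = bins
        self.method = method
        self.seed = seed
        self.compute_core = compute_core

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        cols = getattr(self, "feature_names_in_", None)
        if cols is not None and len(cols) == X.shape[1]:
            return pd.DataFrame(X, columns=list(cols))
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        frame = self._as_frame(X)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        dt = build_decision_table(frame, y, bins=self.bins, method=self.method)
        self.reduct_ = find_reduct(dt, seed=self.seed)
        self.gamma_ = self.reduct_.gamma
        self.core_ = core(dt) if self.compute_core else None
        kept = set(self.reduct_.attributes)
        self.support_ = np.array([c in kept for c in frame.columns])
        return self

    def transform(self, X):
        frame = self._as_frame(X)
        if frame.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {frame.shape[1]}"
            )
        out = frame.loc[:, self.support_]
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.reduct_.attributes, dtype=object)
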