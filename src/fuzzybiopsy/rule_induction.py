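"""Automatic induction of the fuzzy rule base.

Rules are extracted from the labelled training cohort in four steps, run
separately for each outcome class:

1. cluster the class's patients into homogeneous subgroups with a 4x4
   self-organizing map (winner-take-most updates, neighbourhood 1 at the
   winner, 0.5 at lattice distance 1, 0 elsewhere; learning rate 0.4);
2. binarize every input variable into interval/category indicator items
   ("psa_density=medium", "pirads=4", ...), one active item per variable
   per patient;
3. mine each cluster's binary transaction matrix with FP-growth for
   frequent itemsets (the candidate rule antecedents);
4. count, over the FULL training cohort, how many positive- and
   negative-outcome patients satisfy each antecedent and keep only rules
   whose class ratio (predominance) clears a threshold.  The majority class
   becomes the rule's consequent.

The intervals of the default binarization scheme coincide with the supports
of the fuzzy membership functions, so a mined antecedent item translates
one-to-one into a fuzzy term (see :mod:`fuzzybiopsy.fis`).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import (CATEGORICAL_VARIABLES, FIS_VARIABLES, NEGATIVE, POSITIVE,
                     Cohort, CohortError, PatientRecord)

# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SOMConfig:
    """4x4 lattice with the winner/neighbour/outside update scheme.

    ``neighborhood(d)`` is 1 at the winning neuron, 0.5 at lattice distance
    1 and 0 beyond; ``lattice`` chooses how distance 1 is measured on the
    grid — Chebyshev (default; diagonals are neighbours) or Manhattan.
    """

    grid_rows: int = 4
    grid_cols: int = 4
    learning_rate: float = 0.4
    epochs: int = 50
    seed: int = 0
    lattice: str = "chebyshev"

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.lattice not in ("chebyshev", "manhattan"):
            raise ValueError(f"unknown lattice metric {self.lattice!r}")

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols

    def neighborhood(self, lattice_distance: int) -> float:
        if lattice_distance == 0:
            return 1.0
        if lattice_distance == 1:
            return 0.5
        return 0.0


@dataclass
class SOMGrid:
    """Trained lattice: one weight vector per neuron (row-major order)."""

    weights: np.ndarray  # (n_neurons, dim)
    config: SOMConfig

    def lattice_distances(self, winner: int) -> np.ndarray:
        """Integer lattice distance of every neuron from ``winner``."""
        rows, cols = self.config.grid_rows, self.config.grid_cols
        r, c = divmod(winner, cols)
        rr, cc = np.divmod(np.arange(rows * cols), cols)
        dr, dc = np.abs(rr - r), np.abs(cc - c)
        if self.config.lattice == "chebyshev":
            return np.maximum(dr, dc)
        return dr + dc


def _winner(weights: np.ndarray, x: np.ndarray) -> int:
    """Index of the nearest neuron (Euclidean); ties -> lowest index."""
    d2 = np.sum((weights - x) ** 2, axis=1)
    return int(np.argmin(d2))  # argmin returns the first minimum


def som_update(grid: SOMGrid, x: np.ndarray) -> int:
    """One presentation: find the winner, move it and its neighbours.

    w_new = w_old + phi(d) * eta * (x - w_old), with phi from the config.
    Returns the winning neuron index.
    """
    win = _winner(grid.weights, x)
    phi = np.array([grid.config.neighborhood(int(d))
                    for d in grid.lattice_distances(win)])
    grid.weights += (phi * grid.config.learning_rate)[:, None] \
        * (x - grid.weights)
    return win


def train_som(records: np.ndarray, config: SOMConfig) -> SOMGrid:
    """Train the map on encoded patient vectors (rows).

    Weights start uniform in [0, 1]; the presentation order is shuffled once
    from the seed and repeated for every epoch, so training is fully
    deterministic given the config.
    """
    X = np.asarray(records, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise CohortError("train_som needs a non-empty 2-D array of vectors")
    if not np.all(np.isfinite(X)):
        raise CohortError("non-finite values in SOM input")
    rng = np.random.default_rng(config.seed)
    grid = SOMGrid(rng.uniform(0.0, 1.0, (config.n_neurons, X.shape[1])),
                   config)
    order = rng.permutation(X.shape[0])
    for _ in range(config.epochs):
        for i in order:
            som_update(grid, X[i])
    return grid


def assign_clusters(grid: SOMGrid, records: np.ndarray) -> np.ndarray:
    """Map each encoded vector to its nearest neuron (ties -> lowest index)."""
    X = np.asarray(records, dtype=float)
    if X.shape[1] != grid.weights.shape[1]:
        raise CohortError(
            f"dimensionality mismatch: vectors have {X.shape[1]} "
            f"coordinates, grid expects {grid.weights.shape[1]}")
    return np.array([_winner(grid.weights, x) for x in X])


def encode_for_som(cohort: Cohort,
                   variables: Sequence[str] = FIS_VARIABLES,
                   bounds: Mapping[str, tuple[float, float]] | None = None
                   ) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Encode records for the Euclidean winner search.

    Numerics are min-max scaled to [0, 1] (bounds from the cohort unless
    given); categoricals are one-hot.  Returns the matrix and the numeric
    bounds used, so the same scaling can be reapplied.
    """
    bounds = dict(bounds) if bounds else {}
    cols = []
    for var in variables:
        if var in CATEGORICAL_VARIABLES:
            levels = sorted({r.value(var) for r in cohort})
            for lev in levels:
                cols.append(np.array([1.0 if r.value(var) == lev else 0.0
                                      for r in cohort]))
        else:
            vals = np.array([float(r.value(var)) for r in cohort])
            lo, hi = bounds.get(var, (vals.min(), vals.max()))
            bounds[var] = (float(lo), float(hi))
            span = hi - lo
            cols.append((vals - lo) / span if span > 0
                        else np.zeros(len(vals)))
    return np.column_stack(cols), bounds


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """Half-open numeric interval [lo, hi) carrying a linguistic label."""

    label: str
    lo: float
    hi: float

    def contains(self, x: float) -> bool:
        return self.lo <= x < self.hi


@dataclass(frozen=True)
class BinarizationScheme:
    """Per-variable interval or category lists defining the binary items.

    Each (variable, interval-or-category) pair names exactly one item; the
    intervals of a variable are disjoint and cover its observed range, so
    every patient activates exactly one item per variable.
    """

    numeric: Mapping[str, tuple[Interval, ...]]
    categorical: Mapping[str, tuple[str, ...]]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.numeric) + tuple(self.categorical)

    @property
    def items(self) -> tuple[str, ...]:
        """All item names, variable-major, deterministic order."""
        out = []
        for var, ivs in self.numeric.items():
            out.extend(f"{var}={iv.label}" for iv in ivs)
        for var, cats in self.categorical.items():
            out.extend(f"{var}={c}" for c in cats)
        return tuple(out)

    def item_for(self, record: PatientRecord, var: str) -> str:
        if var in self.numeric:
            x = float(record.value(var))
            for iv in self.numeric[var]:
                if iv.contains(x):
                    return f"{var}={iv.label}"
            raise CohortError(f"{var}={x} covered by no interval of the "
                              f"binarization scheme")
        value = str(record.value(var))
        if value not in self.categorical[var]:
            raise CohortError(f"{var}={value!r} not among scheme categories "
                              f"{self.categorical[var]}")
        return f"{var}={value}"


def default_binarization_scheme() -> BinarizationScheme:
    """Items aligned with the fuzzy membership-function supports.

    PSA-density breakpoints 0.10 and 0.15 ng/mL² are the cut-offs commonly
    used clinically for biopsy decisions; lesion counts collapse to
    1 / 2 / 3+; PI-RADS scores are individual items.
    """
    inf = math.inf
    return BinarizationScheme(
        numeric={
            "psa_density": (Interval("low", 0.0, 0.10),
                            Interval("medium", 0.10, 0.15),
                            Interval("high", 0.15, inf)),
            "n_lesions": (Interval("1", 1.0, 2.0),
                          Interval("2", 2.0, 3.0),
                          Interval("3+", 3.0, inf)),
        },
        categorical={
            "dre": ("negative", "positive"),
            "prior_biopsy": ("no", "yes"),
            "lesion_location": ("peripheral", "transitional_anterior"),
            "pirads": ("3", "4", "5"),
        },
    )


@dataclass
class TransactionMatrix:
    """Patients x binary items, exactly one 1 per (patient, variable)."""

    matrix: np.ndarray            # (n_patients, n_items) of 0/1
    items: tuple[str, ...]
    patient_ids: tuple[str, ...]

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def itemsets(self) -> list[frozenset[str]]:
        """Each row as the set of its active item names."""
        items = np.array(self.items)
        return [frozenset(items[row.astype(bool)]) for row in self.matrix]


def binarize(cohort: Cohort,
             scheme: BinarizationScheme | None = None) -> TransactionMatrix:
    """Turn records into the 0/1 transaction matrix of the scheme's items."""
    scheme = scheme or default_binarization_scheme()
    items = scheme.items
    index = {item: j for j, item in enumerate(items)}
    M = np.zeros((len(cohort), len(items)), dtype=np.int8)
    for i, rec in enumerate(cohort):
        for var in scheme.variables:
            M[i, index[scheme.item_for(rec, var)]] = 1
    return TransactionMatrix(M, items, tuple(r.patient_id for r in cohort))


# ---------------------------------------------------------------------------
# FP-growth
# ---------------------------------------------------------------------------


class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}
        self.link: _FPNode | None = None


class _FPTree:
    def __init__(self):
        self.root = _FPNode(None, None)
        self.header: dict[str, _FPNode] = {}   # item -> head of node link
        self.counts: dict[str, int] = defaultdict(int)

    def insert(self, transaction: Sequence[str], count: int = 1) -> None:
        node = self.root
        for item in transaction:
            child = node.children.get(item)
            if child is None:
                child = _FPNode(item, node)
                node.children[item] = child
                child.link = self.header.get(item)
                self.header[item] = child
            child.count += count
            self.counts[item] += count
            node = child

    def prefix_paths(self, item: str) -> list[tuple[list[str], int]]:
        paths = []
        node = self.header.get(item)
        while node is not None:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                paths.append((path[::-1], node.count))
            node = node.link
        return paths


def fp_growth(transactions: TransactionMatrix | Iterable[frozenset[str]],
              min_support: float) -> list[tuple[frozenset[str], int]]:
    """All itemsets with support >= ``min_support`` (a fraction), with counts.

    Classic FP-tree mining: transactions are reordered by global item
    frequency, compressed into a prefix tree, and frequent itemsets are
    grown recursively from conditional trees — no candidate generation.
    Output is sorted by support descending, then lexicographically, so runs
    are reproducible.  An empty matrix yields an empty list.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support {min_support} outside (0, 1]")
    if isinstance(transactions, TransactionMatrix):
        tx = transactions.itemsets()
    else:
        tx = [frozenset(t) for t in transactions]
    n = len(tx)
    if n == 0:
        return []
    # support >= fraction  <=>  count >= ceil(fraction * n), robust to fp error
    min_count = max(1, math.ceil(min_support * n - 1e-9))

    global_counts: dict[str, int] = defaultdict(int)
    for t in tx:
        for item in t:
            global_counts[item] += 1
    frequent = {i for i, c in global_counts.items() if c >= min_count}
    # frequency-descending order (ties lexicographic) stabilises the tree
    order = {item: (-global_counts[item], item) for item in frequent}

    tree = _FPTree()
    for t in tx:
        filtered = sorted((i for i in t if i in frequent),
                          key=order.__getitem__)
        if filtered:
            tree.insert(filtered)

    results: list[tuple[frozenset[str], int]] = []
    _mine(tree, frozenset(), min_count, results)
    results.sort(key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    return results


def _mine(tree: _FPTree, suffix: frozenset[str], min_count: int,
          out: list[tuple[frozenset[str], int]]) -> None:
    for item in sorted(tree.header):
        count = tree.counts[item]
        if count < min_count:
            continue
        itemset = suffix | {item}
        out.append((itemset, count))
        cond = _FPTree()
        for path, path_count in tree.prefix_paths(item):
            cond.insert(path, path_count)
        # prune conditionally infrequent items, rebuild once
        infrequent = {i for i, c in cond.counts.items() if c < min_count}
        if infrequent:
            pruned = _FPTree()
            for path, path_count in tree.prefix_paths(item):
                kept = [i for i in path if i not in infrequent]
                if kept:
                    pruned.insert(kept, path_count)
            cond = pruned
        if cond.header:
            _mine(cond, itemset, min_count, out)


def maximal_itemsets(frequent: Sequence[tuple[frozenset[str], int]]
                     ) -> list[tuple[frozenset[str], int]]:
    """Keep only itemsets that are not a strict subset of another one.

    A maximal frequent itemset is the most specific frequent description of
    a patient subgroup; its sub-itemsets match supersets of the same
    patients and carry no extra information as rule antecedents.
    """
    sets = [s for s, _ in frequent]
    out = []
    for s, c in frequent:
        if not any(s < other for other in sets):
            out.append((s, c))
    return out


# ---------------------------------------------------------------------------
# Predominance filtering and rule-base induction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateRule:
    """A mined antecedent with its class match counts over the full cohort."""

    antecedent: frozenset[str]
    n_match_pos: int
    n_match_neg: int
    predominance: float
    consequent: str
    provenance: tuple[str, int]   # (source class, cluster id)

    def __post_init__(self) -> None:
        if self.n_match_pos < 0 or self.n_match_neg < 0:
            raise ValueError("match counts must be non-negative")


def match_counts(antecedent: frozenset[str],
                 transactions: TransactionMatrix,
                 labels: Sequence[str]) -> tuple[int, int]:
    """(positive, negative) patient counts satisfying the antecedent."""
    idx = [transactions.items.index(item) for item in antecedent]
    hits = transactions.matrix[:, idx].all(axis=1)
    lab = np.asarray(labels)
    return (int(np.sum(hits & (lab == POSITIVE))),
            int(np.sum(hits & (lab == NEGATIVE))))


def score_predominance(antecedent: frozenset[str], n_pos: int, n_neg: int,
                       threshold: float,
                       provenance: tuple[str, int]) -> CandidateRule | None:
    """Keep the rule iff one class clearly predominates among its matches.

    predominance = max(n_pos, n_neg) / max(1, min(n_pos, n_neg)); the rule
    is kept when predominance >= threshold and at least one patient matches,
    with the majority class as consequent.
    """
    larger, smaller = max(n_pos, n_neg), min(n_pos, n_neg)
    if larger == 0:
        return None
    predominance = larger / max(1, smaller)
    if predominance < threshold:
        return None
    consequent = POSITIVE if n_pos > n_neg else NEGATIVE
    return CandidateRule(antecedent, n_pos, n_neg, predominance,
                         consequent, provenance)


@dataclass(frozen=True)
class InductionConfig:
    """Knobs of the four-step extraction (defaults are the shipped choices).

    ``min_support`` applies within each SOM cluster — a rule must describe a
    frequent pattern of some homogeneous patient subgroup; the predominance
    threshold then demands the pattern be strongly one-class over the whole
    training set.
    """

    som: SOMConfig = field(default_factory=SOMConfig)
    min_support: float = 0.25
    predominance_threshold: float = 2.0
    max_antecedent_size: int | None = None   # None = no cap
    candidate_itemsets: str = "maximal"      # "maximal" | "all"

    def __post_init__(self) -> None:
        if self.candidate_itemsets not in ("maximal", "all"):
            raise ValueError(
                f"candidate_itemsets must be 'maximal' or 'all', "
                f"got {self.candidate_itemsets!r}")


def induce_rule_base(train: Cohort,
                     config: InductionConfig | None = None,
                     scheme: BinarizationScheme | None = None
                     ) -> list[CandidateRule]:
    """Run the four extraction steps and return the kept, deduplicated rules.

    Rules mined from different clusters (or classes) with identical
    antecedents are merged — their match counts are computed on the full
    cohort and therefore coincide; the first provenance encountered is
    retained.  Fully reproducible given the SOM seed.
    """
    config = config or InductionConfig()
    scheme = scheme or default_binarization_scheme()
    labels = train.labels()
    classes = set(labels)
    if not {NEGATIVE, POSITIVE} <= classes:
        raise CohortError("training cohort must contain both outcome classes")

    full_tx = binarize(train, scheme)
    kept: dict[frozenset[str], CandidateRule] = {}
    for class_index, cls in enumerate((NEGATIVE, POSITIVE)):
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        class_cohort = train.subset(idx, f"{train.name}:{cls}")
        X, _ = encode_for_som(class_cohort)
        som_cfg = SOMConfig(
            grid_rows=config.som.grid_rows, grid_cols=config.som.grid_cols,
            learning_rate=config.som.learning_rate, epochs=config.som.epochs,
            seed=config.som.seed + class_index, lattice=config.som.lattice)
        if len(class_cohort) < som_cfg.n_neurons:
            import warnings
            warnings.warn(
                f"class {cls!r} has {len(class_cohort)} records, fewer than "
                f"the {som_cfg.n_neurons} map neurons; clustering degenerates "
                f"to fewer effective clusters", stacklevel=2)
        grid = train_som(X, som_cfg)
        assignment = assign_clusters(grid, X)
        for cluster_id in sorted(set(assignment)):
            members = [idx[j] for j in np.flatnonzero(assignment == cluster_id)]
            cluster_tx = binarize(train.subset(members), scheme)
            frequent = fp_growth(cluster_tx, config.min_support)
            if config.candidate_itemsets == "maximal":
                frequent = maximal_itemsets(frequent)
            for antecedent, _count in frequent:
                if (config.max_antecedent_size is not None
                        and len(antecedent) > config.max_antecedent_size):
                    continue
                if antecedent in kept:
                    continue
                n_pos, n_neg = match_counts(antecedent, full_tx, labels)
                rule = score_predominance(antecedent, n_pos, n_neg,
                                          config.predominance_threshold,
                                          (cls, int(cluster_id)))
                if rule is not None:
                    kept[antecedent] = rule
    return sorted(kept.values(),
                  key=lambda r: (-r.predominance,
                                 -(r.n_match_pos + r.n_match_neg),
                                 tuple(sorted(r.antecedent))))
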