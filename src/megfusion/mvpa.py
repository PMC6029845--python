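"""Time-resolved multivariate pattern analysis.

The decoding scheme follows the standard pseudo-trial design for MEG:
within each of `n_repetitions` repetitions, the trials of every condition
are randomly sub-averaged in groups of `group_size` into M pseudo-trials;
for each condition pair and time point a linear maximum-margin classifier
(SVM, cost C) is evaluated by M-fold leave-one-pseudo-trial-per-class-out
cross-validation on the channel pattern vectors; fold accuracies are
averaged within a repetition and then across repetitions. The resulting
condition x condition x time grid of pairwise decoding accuracies is the
time-resolved representational dissimilarity matrix (RDM) that all later
stages consume.

Fold structure: each of the M folds holds out one pseudo-trial of each
class (2 test vectors) and trains on the remaining 2(M-1), keeping the
training set balanced. A test vector landing exactly on the decision
boundary is counted as incorrect (conservative, deterministic tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "DecodingParams",
    "TimeResolvedRDM",
    "TemporalGeneralizationMap",
    "PairPartition",
    "subaverage_trials",
    "pairwise_decoding_timecourse",
    "temporal_generalization",
    "direct_category_decoding",
    "partition_mean",
    "categorical_division",
    "all_pairs",
]


@dataclass(frozen=True)
class DecodingParams:
    """Knobs of the decoding procedure.

    group_size: trials averaged per pseudo-trial (default 3).
    n_repetitions: random sub-averaging repetitions averaged over
        (default 100).
    svm_cost: SVM regularization C (default 1, fixed — not tuned).
    time_stride: decode every k-th sample of the epoch's native grid;
        1 decodes the full 1 ms grid.
    normalize: z-score each feature on the training set before fitting
        (off by default; raw patterns keep the decoder hand-checkable).
    """

    group_size: int = 3
    n_repetitions: int = 100
    svm_cost: float = 1.0
    seed: int = 0
    time_stride: int = 1
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.time_stride < 1:
            raise ValueError("time_stride must be >= 1")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclass
class TimeResolvedRDM:
    """Pairwise decoding accuracies (%): conditions x conditions x time.

    Each time slice is symmetric with an undefined (NaN) diagonal; values
    lie in [0, 100] with 50 the two-class chance level.
    """

    accuracy: np.ndarray
    condition_ids: np.ndarray
    time_axis: np.ndarray
    category_of: np.ndarray | None = None  # category index per condition

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        self.condition_ids = np.asarray(self.condition_ids)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        c = self.condition_ids.size
        if self.accuracy.shape != (c, c, self.time_axis.size):
            raise ValueError("accuracy must be (C, C, n_times)")

    @property
    def n_conditions(self) -> int:
        return self.condition_ids.size


@dataclass
class TemporalGeneralizationMap:
    """Train-time x test-time decoding accuracy (%), averaged over pairs."""

    accuracy: np.ndarray  # (n_times, n_times): rows train, columns test
    time_axis: np.ndarray
    pair_maps: dict[tuple[int, int], np.ndarray] | None = None


@dataclass(frozen=True)
class PairPartition:
    """Disjoint split of all unordered condition pairs into three sets."""

    within_a: frozenset
    within_b: frozenset
    between: frozenset
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        sets = (self.within_a, self.within_b, self.between)
        total = sum(len(s) for s in sets)
        union = self.within_a | self.within_b | self.between
        if len(union) != total:
            raise ValueError("partition sets must be disjoint")

    @property
    def within(self) -> frozenset:
        return self.within_a | self.within_b

    @classmethod
    def from_categories(
        cls,
        category_of: np.ndarray,
        name_a: str = "A",
        name_b: str = "B",
    ) -> "PairPartition":
        """Build the within/within/between split from a two-level labeling."""
        cat = np.asarray(category_of)
        levels = np.unique(cat)
        if levels.size != 2:
            raise ValueError("exactly two categories required")
        wa, wb, bw = set(), set(), set()
        for i, j in combinations(range(cat.size), 2):
            if cat[i] == cat[j]:
                (wa if cat[i] == levels[0] else wb).add((i, j))
            else:
                bw.add((i, j))
        return cls(
            within_a=frozenset(wa),
            within_b=frozenset(wb),
            between=frozenset(bw),
            name_a=name_a,
            name_b=name_b,
        )

    def validate_for(self, n_conditions: int) -> None:
        expected = n_conditions * (n_conditions - 1) // 2
        union = self.within | self.between
        if len(union) != expected:
            raise ValueError(
                f"partition covers {len(union)} pairs, expected {expected}"
            )
        for i, j in union:
            if not (0 <= i < j < n_conditions):
                raise ValueError(f"invalid condition pair ({i}, {j})")


def all_pairs(n_conditions: int) -> list[tuple[int, int]]:
    """All unordered condition index pairs (i < j)."""
    return list(combinations(range(n_conditions), 2))


def subaverage_trials(
    trials: np.ndarray, group_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Average randomly assigned groups of `group_size` trials.

    Returns M = floor(n / group_size) pseudo-trials; each source trial is
    used at most once and the remainder trials are dropped for this draw
    (across repetitions the random assignment recycles all trials).
    """
    trials = np.asarray(trials)
    n = trials.shape[0]
    if n < group_size:
        raise ValueError(
            f"need at least group_size={group_size} trials, got {n}"
        )
    m = n // group_size
    perm = rng.permutation(n)[: m * group_size]
    groups = perm.reshape(m, group_size)
    return trials[groups].mean(axis=1)


def _split_by_condition(epochs) -> tuple[np.ndarray, list[np.ndarray]]:
    conds = np.unique(epochs.labels)
    return conds, [epochs.data[epochs.labels == c] for c in conds]


def _draw_pseudo_trials(
    by_cond: list[np.ndarray], group_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """One repetition's pseudo-trials per condition, axes (M, T, channels).

    Shared by the time-resolved and temporal-generalization decoders so
    that, for equal seeds, both consume the generator identically and
    produce identical fold assignments.
    """
    out = []
    for trials in by_cond:
        pseudo = subaverage_trials(trials, group_size, rng)  # (M, ch, T)
        out.append(np.ascontiguousarray(pseudo.transpose(0, 2, 1)))
    return out


def _new_svm(cost: float) -> SVC:
    return SVC(kernel="linear", C=cost)


def _normalize_train_test(xtr, xte):
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (xtr - mu) / sd, (xte - mu) / sd


def _fold_indices(m: int) -> list[tuple[np.ndarray, int]]:
    return [(np.delete(np.arange(m), k), k) for k in range(m)]


def _check_decodable(by_cond, params) -> None:
    if len(by_cond) < 2:
        raise ValueError("need at least 2 conditions to decode")
    for trials in by_cond:
        if trials.shape[0] // params.group_size < 2:
            raise ValueError(
                "M < 2 pseudo-trials: need at least 2*group_size="
                f"{2 * params.group_size} trials per condition for "
                "leave-one-out cross-validation"
            )


def pairwise_decoding_timecourse(epochs, params: DecodingParams) -> TimeResolvedRDM:
    """Decode every condition pair at every time point.

    Returns the time-resolved RDM with both triangles filled symmetrically
    and a NaN diagonal (no classification within condition). With unequal
    per-condition trial counts, each pair uses M = min of its two
    pseudo-trial counts so folds stay balanced.
    """
    conds, by_cond = _split_by_condition(epochs)
    _check_decodable(by_cond, params)
    t_idx = np.arange(0, epochs.n_times, params.time_stride)
    n_t = t_idx.size
    n_c = conds.size
    rng = np.random.default_rng(params.seed)
    acc_sum = np.zeros((n_c, n_c, n_t))
    pairs = all_pairs(n_c)

    for _ in range(params.n_repetitions):
        pseudos = _draw_pseudo_trials(by_cond, params.group_size, rng)
        for a, b in pairs:
            m = min(pseudos[a].shape[0], pseudos[b].shape[0])
            xa = pseudos[a][:m][:, t_idx, :]  # (M, n_t, ch)
            xb = pseudos[b][:m][:, t_idx, :]
            y = np.repeat([0, 1], m - 1)
            pair_acc = np.zeros(n_t)
            for train_idx, k in _fold_indices(m):
                xtr_a = xa[train_idx]
                xtr_b = xb[train_idx]
                for ti in range(n_t):
                    xtr = np.concatenate((xtr_a[:, ti], xtr_b[:, ti]))
                    xte = np.stack((xa[k, ti], xb[k, ti]))
                    if params.normalize:
                        xtr, xte = _normalize_train_test(xtr, xte)
                    clf = _new_svm(params.svm_cost)
                    clf.fit(xtr, y)
                    f = clf.decision_function(xte)
                    pair_acc[ti] += int(f[0] < 0) + int(f[1] > 0)
            pair_acc *= 100.0 / (2 * m)  # mean over folds and the 2 test vectors
            acc_sum[a, b] += pair_acc

    acc = acc_sum / params.n_repetitions
    acc = acc + acc.transpose(1, 0, 2)  # mirror the upper triangle
    ii = np.arange(n_c)
    acc[ii, ii, :] = np.nan
    cat = getattr(epochs, "category_of", None)
    return TimeResolvedRDM(
        accuracy=acc,
        condition_ids=conds,
        time_axis=epochs.time_axis[t_idx],
        category_of=cat,
    )


def temporal_generalization(
    epochs, params: DecodingParams, keep_pairs: bool = False
) -> TemporalGeneralizationMap:
    """Train at each time point, test at every time point.

    The classifier fit at train time t within a fold is evaluated at all
    test times t'; averaging over folds, repetitions and pairs proceeds
    exactly as in `pairwise_decoding_timecourse`, so for equal seeds the
    map's diagonal reproduces the time-resolved decoding.
    """
    conds, by_cond = _split_by_condition(epochs)
    _check_decodable(by_cond, params)
    t_idx = np.arange(0, epochs.n_times, params.time_stride)
    n_t = t_idx.size
    n_c = conds.size
    rng = np.random.default_rng(params.seed)
    pairs = all_pairs(n_c)
    sums = {pair: np.zeros((n_t, n_t)) for pair in pairs} if keep_pairs else None
    total = np.zeros((n_t, n_t))

    for _ in range(params.n_repetitions):
        pseudos = _draw_pseudo_trials(by_cond, params.group_size, rng)
        for a, b in pairs:
            m = min(pseudos[a].shape[0], pseudos[b].shape[0])
            xa = pseudos[a][:m][:, t_idx, :]
            xb = pseudos[b][:m][:, t_idx, :]
            y = np.repeat([0, 1], m - 1)
            pair_map = np.zeros((n_t, n_t))
            for train_idx, k in _fold_indices(m):
                xtr_a = xa[train_idx]
                xtr_b = xb[train_idx]
                # test vectors of this fold at every test time
                xte_all = np.concatenate((xa[k], xb[k]))  # (2*n_t, ch)
                for ti in range(n_t):
                    xtr = np.concatenate((xtr_a[:, ti], xtr_b[:, ti]))
                    xte = xte_all
                    if params.normalize:
                        xtr, xte = _normalize_train_test(xtr, xte_all)
                    clf = _new_svm(params.svm_cost)
                    clf.fit(xtr, y)
                    f = clf.decision_function(xte)
                    pair_map[ti] += (f[:n_t] < 0).astype(np.float64) + (
                        f[n_t:] > 0
                    )
            pair_map *= 100.0 / (2 * m)
            total += pair_map
            if keep_pairs:
                sums[(a, b)] += pair_map

    n_rep = params.n_repetitions
    grand = total / (n_rep * len(pairs))
    pair_maps = (
        {pair: s / n_rep for pair, s in sums.items()} if keep_pairs else None
    )
    return TemporalGeneralizationMap(
        accuracy=grand, time_axis=epochs.time_axis[t_idx], pair_maps=pair_maps
    )


def direct_category_decoding(
    epochs, category_of: np.ndarray, params: DecodingParams
) -> np.ndarray:
    """Train face-vs-object (category) classifiers directly.

    Cross-validation leaves out exemplar pairs — one exemplar of each
    category per fold, paired at random within each repetition — so test
    exemplars never appear in the training set and above-chance accuracy
    cannot come from exemplar identity. Returns the accuracy time series
    (%) on the (possibly strided) time grid.
    """
    conds, by_cond = _split_by_condition(epochs)
    _check_decodable(by_cond, params)
    cat = np.asarray(category_of)
    if cat.size != conds.size:
        raise ValueError("category_of must label every condition")
    levels = np.unique(cat)
    if levels.size != 2:
        raise ValueError("exactly two categories required")
    group_a = np.flatnonzero(cat == levels[0])
    group_b = np.flatnonzero(cat == levels[1])
    if min(group_a.size, group_b.size) < 2:
        raise ValueError(
            "each category needs at least 2 exemplars for "
            "leave-exemplar-pair-out cross-validation"
        )
    t_idx = np.arange(0, epochs.n_times, params.time_stride)
    n_t = t_idx.size
    rng = np.random.default_rng(params.seed)
    n_folds = min(group_a.size, group_b.size)
    acc_sum = np.zeros(n_t)

    for _ in range(params.n_repetitions):
        pseudos = _draw_pseudo_trials(by_cond, params.group_size, rng)
        pairing = list(
            zip(rng.permutation(group_a)[:n_folds], rng.permutation(group_b)[:n_folds])
        )
        rep_acc = np.zeros(n_t)
        rep_n = 0
        for ex_a, ex_b in pairing:
            train_conds = [c for c in range(conds.size) if c not in (ex_a, ex_b)]
            xtr_full = np.concatenate([pseudos[c][:, t_idx, :] for c in train_conds])
            ytr = np.concatenate(
                [
                    np.full(pseudos[c].shape[0], int(cat[c] == levels[1]))
                    for c in train_conds
                ]
            )
            xte_full = np.concatenate(
                (pseudos[ex_a][:, t_idx, :], pseudos[ex_b][:, t_idx, :])
            )
            yte = np.concatenate(
                (
                    np.zeros(pseudos[ex_a].shape[0], dtype=int),
                    np.ones(pseudos[ex_b].shape[0], dtype=int),
                )
            )
            sign = np.where(yte == 1, 1.0, -1.0)
            for ti in range(n_t):
                xtr = xtr_full[:, ti]
                xte = xte_full[:, ti]
                if params.normalize:
                    xtr, xte = _normalize_train_test(xtr, xte)
                clf = _new_svm(params.svm_cost)
                clf.fit(xtr, ytr)
                f = clf.decision_function(xte)
                rep_acc[ti] += np.sum(f * sign > 0)
            rep_n += yte.size
        acc_sum += rep_acc * (100.0 / rep_n)

    return acc_sum / params.n_repetitions


def partition_mean(rdm: TimeResolvedRDM, pairs) -> np.ndarray:
    """Unweighted mean accuracy over the listed unordered pairs, per time."""
    pair_list = sorted(pairs)
    if not pair_list:
        raise ValueError("pair set must be non-empty")
    n_c = rdm.n_conditions
    for i, j in pair_list:
        if not (0 <= i < n_c and 0 <= j < n_c and i != j):
            raise ValueError(f"invalid condition pair ({i}, {j})")
    rows = [rdm.accuracy[i, j, :] for i, j in pair_list]
    return np.mean(rows, axis=0)


def categorical_division(
    rdm: TimeResolvedRDM, partition: PairPartition
) -> np.ndarray:
    """Between-category minus pooled within-category mean accuracy.

    Positive values indicate category clustering: pairs straddling the
    category boundary decode better than pairs within a category. Within
    pairs of both categories are pooled with equal pair weight.
    """
    partition.validate_for(rdm.n_conditions)
    between = partition_mean(rdm, partition.between)
    within = partition_mean(rdm, partition.within)
    return between - within
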