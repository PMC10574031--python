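"""Integer-weight screening-score construction.

Searches item weights w_j in {0..4} maximizing the discrimination of the
binary low-richness outcome by the additive score s_i = sum_j w_j x_ij:
exhaustively when the item count permits full enumeration, otherwise by
seeded multi-restart coordinate ascent.  Zero-weight items are eliminated
("a yes that scores 0 carries no information"), and the integer score cutoff
is selected by Youden's J under the strict "positive iff score > t" rule.

Tie-breaking is deterministic everywhere: higher objective, then smaller
total weight (parsimony), then lexicographically smaller weight vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ItemWeights,
    MAX_WEIGHT,
    OutcomeDefinition,
    ResponseMatrix,
    ScreeningModel,
    ValidationError,
    scores_from_responses,
)

_EPS = 1e-12

score = scores_from_responses  # the scoring rule s_i = sum_j w_j x_ij


@dataclass
class OptimizerConfig:
    max_weight: int = MAX_WEIGHT
    objective: str = "auc"            # "auc" or "youden"
    search: str = "auto"              # "auto", "exhaustive", "coordinate_ascent"
    restarts: int = 25
    seed: int | None = 0
    exhaustive_item_limit: int = 7

    def __post_init__(self) -> None:
        if self.max_weight < 1:
            raise ValidationError("max_weight must be >= 1")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")
        if self.objective not in ("auc", "youden"):
            raise ValidationError(f"unknown objective {self.objective!r}")


@dataclass
class SearchTrace:
    n_evaluated: int = 0
    best_per_restart: list[float] = field(default_factory=list)
    restart_histories: list[list[float]] = field(default_factory=list)
    n_ties: int = 0
    degenerate_items: list[str] = field(default_factory=list)
    method: str = ""
    final_weights: dict[str, int] = field(default_factory=dict)


def _auc_rows(score_rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC of each row of a candidate-score matrix against binary y."""
    ranks = stats.rankdata(score_rows, axis=1)
    m = int(y.sum())
    n0 = len(y) - m
    return (ranks[:, y == 1].sum(axis=1) - m * (m + 1) / 2) / (m * n0)


def _youden_best(s: np.ndarray, y: np.ndarray) -> float:
    """Max over integer thresholds of sens + spec - 1 under "score > t"."""
    table = cutoff_table(s, y)
    return float(table["youden_j"].max())


def _objective_rows(score_rows: np.ndarray, y: np.ndarray, objective: str) -> np.ndarray:
    if objective == "auc":
        return _auc_rows(score_rows, y)
    return np.array([_youden_best(row, y) for row in score_rows])


def _validate(responses: ResponseMatrix, outcome) -> tuple[np.ndarray, np.ndarray]:
    if responses.has_missing:
        raise ValidationError("missing responses; drop to complete cases first")
    y = np.asarray(outcome, dtype=int)
    if len(y) != len(responses.sample_ids):
        raise ValidationError("outcome length does not match responses")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    return responses.responses.astype(np.int64), y


def _split_degenerate(x: np.ndarray, item_ids) -> tuple[list[int], list[str]]:
    """Indices of informative items; ids of constant (all-0/all-1) items."""
    active, degenerate = [], []
    for j, item in enumerate(item_ids):
        if x[:, j].min() == x[:, j].max():
            degenerate.append(item)
        else:
            active.append(j)
    return active, degenerate


def _better(cand: tuple[float, int, tuple], best: tuple[float, int, tuple] | None) -> bool:
    """Deterministic candidate ordering: objective desc, total weight asc,
    lexicographic asc."""
    if best is None:
        return True
    obj_c, tot_c, vec_c = cand
    obj_b, tot_b, vec_b = best
    if obj_c > obj_b + _EPS:
        return True
    if obj_c < obj_b - _EPS:
        return False
    return (tot_c, vec_c) < (tot_b, vec_b)


def exhaustive_search(
    responses: ResponseMatrix,
    outcome,
    config: OptimizerConfig | None = None,
) -> tuple[ItemWeights, SearchTrace]:
    """Globally optimal weights by full enumeration of (max_weight+1)^k grids."""
    config = config or OptimizerConfig()
    x, y = _validate(responses, outcome)
    active, degenerate = _split_degenerate(x, responses.item_ids)
    k = len(active)
    if k > config.exhaustive_item_limit:
        raise ValidationError(
            f"{k} informative items exceed the exhaustive limit "
            f"{config.exhaustive_item_limit}; use coordinate_ascent"
        )
    xa = x[:, active]
    values = np.arange(config.max_weight + 1)
    trace = SearchTrace(method="exhaustive", degenerate_items=degenerate)
    best: tuple[float, int, tuple] | None = None

    chunk: list[tuple] = []

    def flush(chunk_vecs: list[tuple]) -> None:
        nonlocal best
        if not chunk_vecs:
            return
        w = np.array(chunk_vecs)                     # (M, k)
        s = w @ xa.T                                 # (M, n)
        objs = _objective_rows(s, y, config.objective)
        trace.n_evaluated += len(chunk_vecs)
        for obj, vec in zip(objs, chunk_vecs):
            cand = (float(obj), int(sum(vec)), vec)
            if best is not None and abs(cand[0] - best[0]) <= _EPS:
                trace.n_ties += 1
            if _better(cand, best):
                best = cand

    for vec in itertools.product(values, repeat=k):
        chunk.append(vec)
        if len(chunk) >= 8192:
            flush(chunk)
            chunk = []
    flush(chunk)

    weights = dict.fromkeys(responses.item_ids, 0)
    for j, w in zip(active, best[2]):
        weights[responses.item_ids[j]] = int(w)
    trace.best_per_restart = [best[0]]
    trace.restart_histories = [[best[0]]]
    trace.final_weights = dict(weights)
    return ItemWeights(weights), trace


def coordinate_ascent(
    responses: ResponseMatrix,
    outcome,
    config: OptimizerConfig | None = None,
) -> tuple[ItemWeights, SearchTrace]:
    """Cyclic coordinate ascent over integer weights with random restarts.

    Each restart starts from a random integer weight vector and repeatedly
    sweeps the items, setting each w_j to its best value in {0..max_weight}
    holding the others fixed (ties resolved toward the smaller weight), until
    a full sweep makes no change.  The best restart wins under the same
    deterministic tie-breaking as the exhaustive search.
    """
    config = config or OptimizerConfig()
    x, y = _validate(responses, outcome)
    active, degenerate = _split_degenerate(x, responses.item_ids)
    if not active:
        raise ValidationError("no informative items")
    xa = x[:, active]
    k = len(active)
    values = np.arange(config.max_weight + 1)
    rng = np.random.default_rng(config.seed)
    trace = SearchTrace(method="coordinate_ascent", degenerate_items=degenerate)
    best: tuple[float, int, tuple] | None = None

    for _ in range(config.restarts):
        w = rng.integers(0, config.max_weight + 1, size=k)
        s = xa @ w
        obj = float(_objective_rows(s[None, :], y, config.objective)[0])
        trace.n_evaluated += 1
        history = [obj]
        changed = True
        while changed:
            changed = False
            # random cyclic order each sweep: escapes order-dependent traps
            for j in rng.permutation(k):
                base = s - w[j] * xa[:, j]
                cand_scores = base[None, :] + values[:, None] * xa[:, j][None, :]
                objs = _objective_rows(cand_scores, y, config.objective)
                trace.n_evaluated += len(values)
                # best value: objective desc, then smaller weight
                v_best = int(np.lexsort((values, -objs))[0])
                if objs[v_best] > obj + _EPS:
                    w[j] = v_best
                    s = base + v_best * xa[:, j]
                    obj = float(objs[v_best])
                    history.append(obj)
                    changed = True
        # parsimony pass: equal-objective weight reductions (deterministic,
        # cannot lower the objective), honoring the smaller-total tie-break
        changed = True
        while changed:
            changed = False
            for j in range(k):
                if w[j] == 0:
                    continue
                base = s - w[j] * xa[:, j]
                cand_scores = base[None, :] + values[:, None] * xa[:, j][None, :]
                objs = _objective_rows(cand_scores, y, config.objective)
                trace.n_evaluated += len(values)
                v_best = int(np.lexsort((values, -objs))[0])
                if v_best < w[j] and objs[v_best] >= obj - _EPS:
                    w[j] = v_best
                    s = base + v_best * xa[:, j]
                    obj = float(objs[v_best])
                    changed = True
        trace.best_per_restart.append(obj)
        trace.restart_histories.append(history)
        cand = (obj, int(w.sum()), tuple(int(v) for v in w))
        if best is not None and abs(cand[0] - best[0]) <= _EPS:
            trace.n_ties += 1
        if _better(cand, best):
            best = cand

    weights = dict.fromkeys(responses.item_ids, 0)
    for j, wv in zip(active, best[2]):
        weights[responses.item_ids[j]] = int(wv)
    trace.final_weights = dict(weights)
    return ItemWeights(weights), trace


def optimize_weights(
    responses: ResponseMatrix,
    outcome,
    config: OptimizerConfig | None = None,
) -> tuple[ItemWeights, SearchTrace]:
    """Dispatch to exhaustive enumeration or coordinate ascent ("auto")."""
    config = config or OptimizerConfig()
    if config.search == "exhaustive":
        return exhaustive_search(responses, outcome, config)
    if config.search == "coordinate_ascent":
        return coordinate_ascent(responses, outcome, config)
    if config.search != "auto":
        raise ValidationError(f"unknown search {config.search!r}")
    x, _ = _validate(responses, outcome)
    active, _ = _split_degenerate(x, responses.item_ids)
    if len(active) <= config.exhaustive_item_limit:
        return exhaustive_search(responses, outcome, config)
    return coordinate_ascent(responses, outcome, config)


def prune(weights: ItemWeights, item_order=None) -> list[str]:
    """Eliminate zero-weight items; return surviving items in canonical order."""
    survivors = weights.nonzero_items()
    if not survivors:
        raise ValidationError("no discriminating items: all weights are zero")
    if item_order is not None:
        order = {item: i for i, item in enumerate(item_order)}
        survivors = sorted(survivors, key=lambda it: order.get(it, len(order)))
    return survivors


def cutoff_table(scores, outcome) -> pd.DataFrame:
    """Sensitivity/specificity/Youden J at every achievable integer threshold
    under the strict rule "positive iff score > t"."""
    s = np.asarray(scores)
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    lo, hi = int(s.min()), int(s.max())
    rows = []
    for t in range(lo - 1, hi + 1):
        pred = s > t
        sens = float(pred[y == 1].mean())
        spec = float((~pred)[y == 0].mean())
        rows.append({"threshold": t, "sensitivity": sens, "specificity": spec,
                     "youden_j": sens + spec - 1.0})
    return pd.DataFrame(rows)


def select_cutoff(scores, outcome) -> tuple[int, pd.DataFrame, bool]:
    """Integer score cutoff maximizing Youden's J.

    Ties resolve toward higher specificity, then the smaller threshold.
    Returns (cutoff, full per-threshold table, degenerate flag); the flag is
    set when all scores are equal (J identically 0).
    """
    s = np.asarray(scores)
    table = cutoff_table(s, outcome)
    degenerate = bool(s.min() == s.max())
    ordered = table.sort_values(
        ["youden_j", "specificity", "threshold"],
        ascending=[False, False, True],
        kind="stable",
    )
    best = ordered.iloc[0]
    return int(best["threshold"]), table, degenerate


def build_model(
    responses: ResponseMatrix,
    outcome,
    config: OptimizerConfig | None = None,
    outcome_definition: OutcomeDefinition | None = None,
) -> tuple[ScreeningModel, SearchTrace, pd.DataFrame]:
    """Full construction: optimize weights, prune, select the score cutoff."""
    config = config or OptimizerConfig()
    weights, trace = optimize_weights(responses, outcome, config)
    survivors = prune(weights, item_order=responses.item_ids)
    pruned = ItemWeights({i: weights.weights[i] for i in survivors})
    scores = scores_from_responses(responses, weights)
    cutoff, table, _ = select_cutoff(scores.to_numpy(), outcome)
    model = ScreeningModel(
        weights=pruned, cutoff=cutoff, outcome_definition=outcome_definition
    )
    return model, trace, table
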