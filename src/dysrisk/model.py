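"""Domain types shared by every pipeline stage.

The containers are thin, validated wrappers around pandas/numpy objects:
``CountTable`` holds a samples x taxa integer abundance matrix with a
taxonomy map; ``ResponseMatrix`` holds binary questionnaire answers with an
explicit missing mask; ``ItemWeights`` holds the integer item weights of the
screening score; ``ScreeningModel`` packages surviving items, weights, the
score cutoff and the outcome definition; ``DiagnosticReport`` packages
confusion counts and derived diagnostic metrics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


MAX_WEIGHT = 4


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups}")


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    ``taxonomy`` maps taxon id -> semicolon-delimited lineage string (Silva /
    Greengenes style, down to at least phylum).  Taxa without a lineage are
    flagged in ``unclassified``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # (n_samples, n_taxa), integer dtype
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = np.modf(np.asarray(self.counts, dtype=float))[0]
            bad = np.argwhere(frac != 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"taxon {self.taxon_ids[j]!r}: {self.counts[i, j]}"
                )
            self.counts = self.counts.astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}: {self.counts[i, j]}"
            )

    @property
    def unclassified(self) -> list[str]:
        """Taxa with no taxonomy lineage."""
        return [t for t in self.taxon_ids if t not in self.taxonomy]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class SampleMetadata:
    """Sample -> group assignment over a declared two-level label set."""

    sample_ids: list[str]
    groups: list[str]
    levels: tuple[str, str] = ("CD", "HC")

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValidationError("sample_ids and groups differ in length")
        _check_unique(self.sample_ids, "sample")
        extra = sorted(set(self.groups) - set(self.levels))
        if extra:
            raise ValidationError(
                f"group labels {extra} outside declared levels {self.levels}"
            )

    def group_counts(self) -> dict[str, int]:
        return {lev: self.groups.count(lev) for lev in self.levels}

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.groups))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups})


@dataclass
class ResponseMatrix:
    """Binary questionnaire answers, 1 = "yes" (exposure to a harmful factor).

    Missing answers are explicit in ``missing`` (same shape boolean mask);
    the values under the mask are meaningless and must not be read.
    """

    sample_ids: list[str]
    item_ids: list[str]
    responses: np.ndarray  # (n_subjects, n_items) of {0,1}
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int8)
        shape = (len(self.sample_ids), len(self.item_ids))
        if self.responses.shape != shape:
            raise ValidationError(
                f"responses shape {self.responses.shape} != {shape}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.item_ids, "item")
        if self.missing is None:
            self.missing = np.zeros(shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != shape:
                raise ValidationError("missing mask shape mismatch")
        observed = self.responses[~self.missing]
        bad = ~np.isin(observed, (0, 1))
        if bad.any():
            raise ValidationError(
                f"responses must be 0/1; found {sorted(set(observed[bad].tolist()))}"
            )

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())

    def complete_cases(self) -> "ResponseMatrix":
        """Drop subjects with any missing answer."""
        keep = ~self.missing.any(axis=1)
        return ResponseMatrix(
            [s for s, k in zip(self.sample_ids, keep) if k],
            list(self.item_ids),
            self.responses[keep],
            self.missing[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.responses.astype(float), index=self.sample_ids, columns=self.item_ids
        )
        df[self.missing] = np.nan
        return df


@dataclass
class ItemWeights:
    """Integer weight in [0, MAX_WEIGHT] per questionnaire item."""

    weights: dict[str, int]

    def __post_init__(self) -> None:
        for item, w in self.weights.items():
            if not float(w).is_integer() or not 0 <= int(w) <= MAX_WEIGHT:
                raise ValidationError(
                    f"weight for {item!r} must be an integer in [0, {MAX_WEIGHT}]; got {w}"
                )
        self.weights = {item: int(w) for item, w in self.weights.items()}

    def vector(self, item_ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in item_ids if i not in self.weights]
        if missing:
            raise ValidationError(f"no weight for items {missing}")
        return np.array([self.weights[i] for i in item_ids], dtype=np.int64)

    @property
    def total(self) -> int:
        return sum(self.weights.values())

    def nonzero_items(self) -> list[str]:
        return [i for i, w in self.weights.items() if w > 0]


@dataclass
class OutcomeDefinition:
    """How the binary low-richness outcome was constructed."""

    reference_group: str
    quantile: float
    cutoff_value: float
    quantile_method: str = "linear"  # numpy name for the type-7 rule
    orientation: str = "below-cutoff = positive (low richness / dysbiosis risk)"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScreeningModel:
    """Final screening instrument: surviving weighted items plus score cutoff.

    A subject is flagged at risk when score > cutoff (strict).
    """

    weights: ItemWeights
    cutoff: int
    outcome_definition: OutcomeDefinition | None = None

    def __post_init__(self) -> None:
        zero = [i for i, w in self.weights.weights.items() if w == 0]
        if zero:
            raise ValidationError(f"screening model retains zero-weight items: {zero}")
        if not 0 <= self.cutoff <= self.weights.total:
            raise ValidationError(
                f"cutoff {self.cutoff} outside [0, {self.weights.total}]"
            )

    def to_dict(self) -> dict:
        return {
            "weights": dict(self.weights.weights),
            "cutoff": int(self.cutoff),
            "outcome_definition": (
                self.outcome_definition.to_dict() if self.outcome_definition else None
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreeningModel":
        od = d.get("outcome_definition")
        return cls(
            ItemWeights(dict(d["weights"])),
            int(d["cutoff"]),
            OutcomeDefinition(**od) if od else None,
        )

    @classmethod
    def from_json(cls, path) -> "ScreeningModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DiagnosticReport:
    """Confusion counts and derived diagnostic metrics.

    Ratios with a zero denominator are NaN with the offending metric listed in
    ``undefined`` — never silently 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: list[str] = field(default_factory=list)
    auc: float | None = None
    auc_ci95: tuple[float, float] | None = None
    auc_p: float | None = None
    pearson_r: float | None = None
    pearson_ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or not float(v).is_integer():
                raise ValidationError(f"{name} must be a non-negative integer; got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d.items()
            if v is not None
        }


def scores_from_responses(responses: ResponseMatrix, weights: ItemWeights,
                          *, complete_case: bool = False) -> pd.Series:
    """Per-subject integer screening score  s_i = sum_j w_j x_ij.

    Missing answers make the score undefined; by default they raise, with
    ``complete_case=True`` affected subjects are dropped instead.
    """
    if responses.has_missing:
        if not complete_case:
            idx = np.argwhere(responses.missing)[0]
            raise ValidationError(
                "missing response for subject "
                f"{responses.sample_ids[idx[0]]!r}, item "
                f"{responses.item_ids[idx[1]]!r}; score is undefined "
                "(use complete_case=True to drop such subjects)"
            )
        responses = responses.complete_cases()
    w = weights.vector(responses.item_ids)
    s = responses.responses.astype(np.int64) @ w
    return pd.Series(s, index=responses.sample_ids, name="score")
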