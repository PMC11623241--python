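"""Long-format nominal-response tables for multiclass observer studies.

The canonical layout is one row per (case, rater) pair: the case's
ground-truth class and the rater's response, both coded as integers
``0..C-1``.  A complete study with I cases, J raters and C classes has
``I * J`` rows (the radiologist study this package targets is 150 cases
x 6 raters x 3 classes = 900 rows), but incomplete designs — a rater
skipping a case — are accepted and simply contribute nothing to the
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseTable",
    "ValidationError",
    "read_responses",
    "write_responses",
    "confusion_matrix",
    "DEFAULT_COLUMNS",
]

#: default CSV column names; override via ``column_map`` in :func:`read_responses`.
DEFAULT_COLUMNS = {
    "case": "case_id",
    "rater": "rater_id",
    "truth": "ground_truth",
    "response": "response",
}


class ValidationError(ValueError):
    """A response table violates one of its structural invariants."""


@dataclass(frozen=True)
class ResponseTable:
    """Validated long-format nominal responses with per-case ground truth.

    Attributes
    ----------
    case_id, rater_id : integer arrays, one entry per row
    ground_truth : ground-truth class of each row's case (constant per case)
    response : the rater's answer for that case
    n_cases, n_raters, n_classes : I, J, C
    labels : optional mapping from class code to a human-readable label
    """

    case_id: np.ndarray
    rater_id: np.ndarray
    ground_truth: np.ndarray
    response: np.ndarray
    n_cases: int
    n_raters: int
    n_classes: int
    labels: dict[int, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("case_id", "rater_id", "ground_truth", "response"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
        self._validate()

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        I, J, C = self.n_cases, self.n_raters, self.n_classes
        if C < 2 or I < 1 or J < 1:
            raise ValidationError(
                f"need C >= 2, I >= 1, J >= 1; got I={I}, J={J}, C={C}"
            )
        n = len(self.case_id)
        if not all(
            len(a) == n for a in (self.rater_id, self.ground_truth, self.response)
        ):
            raise ValidationError("column arrays have unequal lengths")
        if n == 0:
            raise ValidationError("empty response table")
        for name, arr, high in (
            ("case_id", self.case_id, I),
            ("rater_id", self.rater_id, J),
            ("ground_truth", self.ground_truth, C),
            ("response", self.response, C),
        ):
            if arr.min() < 0 or arr.max() >= high:
                bad = arr[(arr < 0) | (arr >= high)][0]
                raise ValidationError(
                    f"{name} value {bad} outside [0, {high})"
                )
        pairs = self.case_id * np.int64(self.n_raters) + self.rater_id
        if len(np.unique(pairs)) != n:
            raise ValidationError("duplicate (case_id, rater_id) pair")
        # ground truth must be constant within a case
        order = np.argsort(self.case_id, kind="stable")
        cid, gt = self.case_id[order], self.ground_truth[order]
        same_case = cid[1:] == cid[:-1]
        mismatch = same_case & (gt[1:] != gt[:-1])
        if mismatch.any():
            bad_case = int(cid[1:][mismatch][0])
            raise ValidationError(
                f"case {bad_case} has inconsistent ground truth across rows"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.case_id)

    def case_truths(self) -> np.ndarray:
        """Ground truth per case index (NaN-free; -1 for unobserved cases)."""
        out = np.full(self.n_cases, -1, dtype=np.int64)
        out[self.case_id] = self.ground_truth
        return out

    def to_frame(self, column_map: dict[str, str] | None = None) -> pd.DataFrame:
        cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
        return pd.DataFrame(
            {
                cols["case"]: self.case_id,
                cols["rater"]: self.rater_id,
                cols["truth"]: self.ground_truth,
                cols["response"]: self.response,
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        column_map: dict[str, str] | None = None,
        n_classes: int | None = None,
        labels: dict[int, str] | None = None,
    ) -> "ResponseTable":
        cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
        missing = [c for c in cols.values() if c not in frame.columns]
        if missing:
            raise KeyError(
                f"missing column(s) {missing}; available: {list(frame.columns)}"
            )
        get = lambda key: np.asarray(frame[cols[key]], dtype=np.int64)
        case, rater = get("case"), get("rater")
        truth, resp = get("truth"), get("response")
        C = int(max(truth.max(), resp.max())) + 1 if n_classes is None else n_classes
        return cls(
            case_id=case,
            rater_id=rater,
            ground_truth=truth,
            response=resp,
            n_cases=int(case.max()) + 1,
            n_raters=int(rater.max()) + 1,
            n_classes=C,
            labels=labels,
        )


def read_responses(
    path,
    column_map: dict[str, str] | None = None,
    n_classes: int | None = None,
    labels: dict[str, int] | None = None,
) -> ResponseTable:
    """Read a CSV of nominal responses into a validated :class:`ResponseTable`.

    Parameters
    ----------
    path : file path of a UTF-8 CSV with a header row.
    column_map : overrides for the default column names, keyed by role
        (``case``, ``rater``, ``truth``, ``response``).
    n_classes : override C upward when legal classes are unobserved;
        by default ``C = 1 + max`` observed class code.
    labels : optional mapping from string class labels to integer codes;
        when given, truth/response columns may hold the labels instead of
        codes and the inverse mapping is stored on the table.
    """
    frame = pd.read_csv(path)
    code_labels: dict[int, str] | None = None
    if labels is not None:
        cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
        for key in ("truth", "response"):
            col = cols[key]
            if col in frame.columns and frame[col].dtype == object:
                frame[col] = frame[col].map(labels)
                if frame[col].isna().any():
                    raise ValidationError(f"unmapped class label in column {col!r}")
        code_labels = {v: k for k, v in labels.items()}
    try:
        frame = frame.astype(
            {c: np.int64 for c in dict(DEFAULT_COLUMNS, **(column_map or {})).values()
             if c in frame.columns}
        )
    except (TypeError, ValueError) as err:
        raise ValidationError(f"non-integer class codes in {path}: {err}") from err
    return ResponseTable.from_frame(
        frame, column_map=column_map, n_classes=n_classes, labels=code_labels
    )


def write_responses(
    table: ResponseTable, path, column_map: dict[str, str] | None = None
) -> None:
    """Write the CSV dialect that :func:`read_responses` reads (round-trip safe)."""
    table.to_frame(column_map).to_csv(path, index=False)


def confusion_matrix(table: ResponseTable, rater: int) -> np.ndarray:
    """C x C count matrix for one rater: rows = ground truth, cols = response.

    Entry ``(s, t)`` counts the cases with ground truth ``s`` that the rater
    answered ``t``; all entries sum to the number of cases the rater answered.
    """
    if not 0 <= rater < table.n_raters:
        raise IndexError(f"rater {rater} outside [0, {table.n_raters})")
    mask = table.rater_id == rater
    C = table.n_classes
    flat = table.ground_truth[mask] * C + table.response[mask]
    return np.bincount(flat, minlength=C * C).reshape(C, C)
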