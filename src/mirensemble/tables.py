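"""Score-table I/O for heterogeneous pre-miRNA predictor panels.

A :class:`ScoreTable` holds one row per RNA hairpin: a sample id, a class
label (+1 genuine precursor, -1 pseudo-hairpin), and one column of raw
output per base predictor.  Base predictors speak different dialects --
some emit a token (``Yes``/``No``, ``1``/``NA``), some a real score with
special values (``0``, ``NA``) standing for negative calls -- so every
column is governed by a :class:`PredictorSpec` describing what its cells
may contain and how a cell maps to a +/-1 call.

Files are plain UTF-8 TSV with a mandatory ``id\\tlabel\\t<predictors...>``
header; ``NA`` is a literal token, lines starting with ``#`` are
provenance comments.  Columns not covered by the schema are rejected
rather than silently dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyTableError, ParseError, SchemaError

Cell = Union[float, str]

_POSITIVE_LABELS = {"1", "+1", "pos", "positive"}
_NEGATIVE_LABELS = {"-1", "neg", "negative"}


@dataclass(frozen=True)
class PredictorSpec:
    """Output dialect of one base predictor.

    Parameters
    ----------
    name
        Column name in score tables.
    output_kind
        ``"binary"`` (token-valued) or ``"numeric"`` (real-valued).
    positive_token, negative_tokens
        For binary specs, the token meaning a positive call and the
        set of tokens meaning a negative call; the sets must be disjoint.
    na_policy
        For numeric specs, whether the literal token ``NA`` is accepted
        (``"sentinel"``) or rejected (``"forbid"``).
    positive_min
        For numeric specs, the smallest score that constitutes a
        positive call; used when binarizing raw scores into +/-1 calls.
    """

    name: str
    output_kind: str
    positive_token: str | None = None
    negative_tokens: frozenset = frozenset()
    na_policy: str = "forbid"
    positive_min: float | None = None

    def __post_init__(self) -> None:
        if self.output_kind not in ("binary", "numeric"):
            raise SchemaError(f"{self.name}: unknown output_kind {self.output_kind!r}")
        if self.output_kind == "binary":
            if not self.positive_token or not self.negative_tokens:
                raise SchemaError(f"{self.name}: binary spec needs positive and negative tokens")
            if self.positive_token in self.negative_tokens:
                raise SchemaError(f"{self.name}: positive/negative token sets overlap")
        else:
            if self.na_policy not in ("forbid", "sentinel"):
                raise SchemaError(f"{self.name}: unknown na_policy {self.na_policy!r}")

    @property
    def is_binary(self) -> bool:
        return self.output_kind == "binary"

    def parse_cell(self, text: str) -> Cell:
        text = text.strip()
        if self.is_binary:
            if text == self.positive_token or text in self.negative_tokens:
                return text
            raise ParseError(
                f"column {self.name!r}: token {text!r} not in dialect "
                f"{{{self.positive_token!r}}} | {set(self.negative_tokens)!r}"
            )
        if text == "NA":
            if self.na_policy == "sentinel":
                return "NA"
            raise ParseError(f"column {self.name!r}: NA not allowed (na_policy=forbid)")
        try:
            value = float(text)
        except ValueError:
            raise ParseError(f"column {self.name!r}: expected a number, got {text!r}") from None
        if not np.isfinite(value):
            raise ParseError(f"column {self.name!r}: non-finite value {text!r}")
        return value

    def validate_cell(self, value: Cell) -> None:
        if self.is_binary:
            if value != self.positive_token and value not in self.negative_tokens:
                raise ParseError(f"column {self.name!r}: invalid binary cell {value!r}")
        elif isinstance(value, str):
            if value != "NA" or self.na_policy != "sentinel":
                raise ParseError(f"column {self.name!r}: invalid numeric cell {value!r}")
        elif not np.isfinite(value):
            raise ParseError(f"column {self.name!r}: non-finite cell {value!r}")

    def format_cell(self, value: Cell) -> str:
        if isinstance(value, str):
            return value
        return repr(float(value))

    def call(self, value: Cell) -> int:
        """Binarize a raw cell into a +/-1 call."""
        if self.is_binary:
            return 1 if value == self.positive_token else -1
        if isinstance(value, str):  # numeric NA counts as a negative call
            return -1
        if self.positive_min is None:
            raise SchemaError(f"{self.name}: positive_min unset, cannot binarize numeric scores")
        return 1 if value >= self.positive_min else -1


def default_specs() -> list[PredictorSpec]:
    """Dialects of the five classic pre-miRNA base predictors.

    MiPred scores positives in 50..91 and prints 0 for negatives; MIReNA
    answers Yes/No; miRPara scores positives in 0.8..1 with 0 for
    negatives; ProMiR prints positives in 0.017..3240 and negatives as a
    small number in 1e-10..1e-2, an exact 0, or NA; triplet-SVM prints
    1 for positives and NA otherwise.
    """
    return [
        PredictorSpec("MiPred", "numeric", positive_min=50.0),
        PredictorSpec("MIReNA", "binary", positive_token="Yes",
                      negative_tokens=frozenset({"No"})),
        PredictorSpec("miRPara", "numeric", positive_min=0.8),
        PredictorSpec("ProMiR", "numeric", na_policy="sentinel", positive_min=0.017),
        PredictorSpec("TripletSVM", "binary", positive_token="1",
                      negative_tokens=frozenset({"NA"})),
    ]


def load_specs(path: str | Path) -> list[PredictorSpec]:
    """Load predictor dialects from a YAML/JSON config (a list of mappings)."""
    with open(path, "r", encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list) or not entries:
        raise SchemaError(f"{path}: expected a non-empty list of predictor specs")
    specs = []
    for e in entries:
        specs.append(PredictorSpec(
            name=e["name"],
            output_kind=e["output_kind"],
            positive_token=e.get("positive_token"),
            negative_tokens=frozenset(e.get("negative_tokens", ())),
            na_policy=e.get("na_policy", "forbid"),
            positive_min=e.get("positive_min"),
        ))
    return specs


@dataclass
class ScoreTable:
    """Raw outputs of M base predictors on N labeled samples."""

    sample_ids: list[str]
    labels: np.ndarray
    predictors: list[PredictorSpec]
    raw: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) == 0:
            raise EmptyTableError("score table has no rows")
        if not self.predictors:
            raise SchemaError("score table has no predictor columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample ids")
        if len(self.labels) != len(self.sample_ids):
            raise SchemaError("labels/sample_ids length mismatch")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ParseError("labels must be +1 or -1")
        if list(self.raw.columns) != self.predictor_names:
            raise SchemaError("raw columns do not match predictor specs")
        if len(self.raw) != len(self.sample_ids):
            raise SchemaError("raw row count does not match sample_ids")
        for spec in self.predictors:
            for value in self.raw[spec.name]:
                spec.validate_cell(value)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def predictor_names(self) -> list[str]:
        return [s.name for s in self.predictors]

    def spec(self, name: str) -> PredictorSpec:
        for s in self.predictors:
            if s.name == name:
                return s
        raise SchemaError(f"unknown predictor {name!r}")

    def row_cells(self, i: int) -> tuple:
        return tuple(self.raw.iloc[i])

    def subset(self, names: Sequence[str]) -> "ScoreTable":
        """Restrict to an ensemble of predictor columns (order as given)."""
        specs = [self.spec(n) for n in names]
        return ScoreTable(
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            predictors=specs,
            raw=self.raw[list(names)].reset_index(drop=True),
        )

    def select_rows(self, indices: Iterable[int]) -> "ScoreTable":
        idx = list(indices)
        return ScoreTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            predictors=list(self.predictors),
            raw=self.raw.iloc[idx].reset_index(drop=True),
        )

    def calls(self) -> dict[str, np.ndarray]:
        """Binarized +/-1 calls of every predictor (see PredictorSpec.call)."""
        return {
            s.name: np.array([s.call(v) for v in self.raw[s.name]], dtype=int)
            for s in self.predictors
        }

    def equals(self, other: "ScoreTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
            and self.predictor_names == other.predictor_names
            and all(
                a == b
                for col in self.predictor_names
                for a, b in zip(self.raw[col], other.raw[col])
            )
        )


def _parse_label(text: str, row: int) -> int:
    t = text.strip().lower()
    if t in _POSITIVE_LABELS:
        return 1
    if t in _NEGATIVE_LABELS:
        return -1
    raise ParseError(f"row {row}: unrecognized class label {text!r}")


def read_score_table(path: str | Path, specs: Sequence[PredictorSpec] | None = None) -> ScoreTable:
    """Read and validate a TSV score table.

    The header must name ``id``, ``label`` and then exactly the predictor
    columns declared in *specs* (default: the five classic predictors).
    Every cell is checked against its column's dialect; a malformed cell
    raises :class:`ParseError` naming the row and column.
    """
    specs = list(specs) if specs is not None else default_specs()
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    cols = list(frame.columns)
    if len(cols) < 2 or cols[0] != "id" or cols[1] != "label":
        raise SchemaError(f"{path}: header must start with 'id\\tlabel'")
    by_name = {s.name: s for s in specs}
    extra = [c for c in cols[2:] if c not in by_name]
    if extra:
        raise SchemaError(f"{path}: columns {extra} not in the declared schema")
    missing = [n for n in by_name if n not in cols[2:]]
    if missing:
        raise SchemaError(f"{path}: schema columns {missing} absent from file")
    if len(frame) == 0:
        raise EmptyTableError(f"{path}: no data rows after header")
    ordered = [by_name[c] for c in cols[2:]]
    labels = np.array([_parse_label(v, i) for i, v in enumerate(frame["label"])])
    data = {}
    for spec in ordered:
        parsed = []
        for i, text in enumerate(frame[spec.name]):
            try:
                parsed.append(spec.parse_cell(text))
            except ParseError as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from None
        data[spec.name] = parsed
    raw = pd.DataFrame(data, columns=[s.name for s in ordered], dtype=object)
    return ScoreTable(
        sample_ids=[str(v) for v in frame["id"]],
        labels=labels,
        predictors=ordered,
        raw=raw,
    )


def write_score_table(table: ScoreTable, path: str | Path,
                      provenance: Sequence[str] | None = None) -> None:
    """Write a TSV score table; ``read_score_table`` round-trips it cell-for-cell.

    *provenance* lines, if given, are written as leading ``#`` comments.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        fh.write("id\tlabel\t" + "\t".join(table.predictor_names) + "\n")
        for i, sid in enumerate(table.sample_ids):
            cells = [
                spec.format_cell(table.raw[spec.name].iloc[i])
                for spec in table.predictors
            ]
            fh.write(f"{sid}\t{int(table.labels[i])}\t" + "\t".join(cells) + "\n")


def deduplicate(table: ScoreTable, seed: int) -> ScoreTable:
    """Collapse groups of samples with identical (label, prediction vector).

    Samples whose full raw prediction vector and class label agree are
    treated as duplicates; one survivor per group is chosen by a seeded
    uniform draw (one draw per group, groups visited in order of first
    occurrence), and surviving rows keep their original order.  Rows with
    identical predictions but different labels do not collapse.
    """
    groups: dict[tuple, list[int]] = {}
    for i in range(table.n_samples):
        key = (int(table.labels[i]), table.row_cells(i))
        groups.setdefault(key, []).append(i)
    rng = np.random.default_rng(seed)
    survivors = []
    for members in groups.values():
        survivors.append(members[int(rng.integers(len(members)))])
    return table.select_rows(sorted(survivors))


@dataclass(frozen=True)
class EnsembleSet:
    """Canonically ordered collection of predictor-name subsets."""

    members: tuple

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def enumerate_ensembles(predictor_names: Sequence[str], min_size: int = 2) -> EnsembleSet:
    """All predictor subsets of size >= *min_size*, in (size, lexicographic) order.

    For M predictors and min_size 2 the count is 2^M - M - 1; in
    particular five predictors admit C(5,2)+C(5,3)+C(5,4)+C(5,5) = 26
    distinct meta-predictors.
    """
    names = list(predictor_names)
    if len(set(names)) != len(names):
        raise ValueError("predictor names must be unique")
    if not 2 <= min_size <= len(names):
        raise ValueError(f"min_size must be in [2, {len(names)}], got {min_size}")
    ordered = sorted(names)
    members = []
    for size in range(min_size, len(ordered) + 1):
        members.extend(itertools.combinations(ordered, size))
    return EnsembleSet(members=tuple(members))
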