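"""Binding tables and leakage-aware train/test splits.

A binding dataset is a table of (CDR3β, epitope, binary label) records.
Besides the usual record-level random split, three group-aware splits are
provided that control sequence leakage between train and test:

* ``epitope_hard`` — every test epitope is unseen in training;
* ``tcr_hard`` — every test CDR3β is unseen in training;
* ``strict`` — both at once, discarding records that cross sides.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import SequenceError, validate_sequence

CDR3_LENGTH_RANGE = (9, 23)
EPITOPE_MAX_LENGTH = 15

SPLIT_KINDS = ("random", "epitope_hard", "tcr_hard", "strict")


@dataclass(frozen=True)
class BindingRecord:
    cdr3b: str
    epitope: str
    label: int
    source: str = ""


class BindingDataset:
    """An ordered collection of binding records with provenance notes."""

    def __init__(self, df: pd.DataFrame, provenance: list[str] | None = None):
        required = {"cdr3b", "epitope", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if "source" not in df.columns:
            df = df.assign(source="")
        self.df = df.reset_index(drop=True)
        self.provenance = list(provenance or [])

    def __len__(self) -> int:
        return len(self.df)

    def records(self):
        for r in self.df.itertuples(index=False):
            yield BindingRecord(r.cdr3b, r.epitope, int(r.label), r.source)


def read_dataset(path, column_map: dict | None = None,
                 label_map: dict | None = None, sep: str | None = None) -> BindingDataset:
    """Parse a CSV/TSV binding table into a validated dataset.

    ``column_map`` maps the logical names cdr3b/epitope/label to the file's
    column names (defaults to those names themselves). Rows whose sequences
    fail validation, or whose label cannot be mapped to {0, 1}, are dropped
    and logged in the dataset provenance.
    """
    column_map = {"cdr3b": "cdr3b", "epitope": "epitope", "label": "label",
                  **(column_map or {})}
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in (column_map[k] for k in ("cdr3b", "epitope", "label"))
               if v not in raw.columns]
    if missing:
        raise ValueError(f"input file lacks columns {missing}")

    rows, log = [], [f"read {len(raw)} rows from {path}"]
    for i, r in raw.iterrows():
        try:
            cdr = validate_sequence(r[column_map["cdr3b"]])
            epi = validate_sequence(r[column_map["epitope"]])
        except SequenceError as err:
            log.append(f"row {i}: dropped ({err})")
            continue
        lab = r[column_map["label"]]
        if label_map is not None:
            lab = label_map.get(lab, label_map.get(str(lab), None))
        try:
            lab = int(lab)
        except (TypeError, ValueError):
            lab = None
        if lab not in (0, 1):
            log.append(f"row {i}: dropped (unmappable label {r[column_map['label']]!r})")
            continue
        src = str(r.get("source", ""))
        rows.append((cdr, epi, lab, src))
    if not rows:
        raise ValueError(f"no valid rows in {path}")
    df = pd.DataFrame(rows, columns=["cdr3b", "epitope", "label", "source"])
    return BindingDataset(df, log)


def apply_filters(ds: BindingDataset,
                  cdr3_length_range: tuple[int, int] = CDR3_LENGTH_RANGE,
                  epitope_max_length: int = EPITOPE_MAX_LENGTH) -> BindingDataset:
    """Length filters, exact-duplicate removal, and label-conflict removal.

    Removes records with CDR3β length outside ``cdr3_length_range`` or epitope
    longer than ``epitope_max_length``; keeps the first of exact duplicate
    (cdr3b, epitope) pairs; removes entirely any pair observed with both
    labels. The per-rule counts are recorded in ``filter_log`` and appended to
    the provenance, and the operation is idempotent.
    """
    df = ds.df
    lo, hi = cdr3_length_range
    n0 = len(df)

    cdr_len = df["cdr3b"].str.len()
    keep_len = cdr_len.between(lo, hi) & (df["epitope"].str.len() <= epitope_max_length)
    df1 = df[keep_len]
    n_len = n0 - len(df1)

    dup = df1.duplicated(subset=["cdr3b", "epitope", "label"], keep="first")
    df2 = df1[~dup]
    n_dup = len(df1) - len(df2)

    nlab = df2.groupby(["cdr3b", "epitope"])["label"].transform("nunique")
    df3 = df2[nlab == 1]
    n_conflict = len(df2) - len(df3)

    log = {"input": n0, "length_filtered": n_len, "duplicates": n_dup,
           "label_conflicts": n_conflict, "output": len(df3)}
    out = BindingDataset(df3.reset_index(drop=True),
                         ds.provenance + [f"apply_filters: {log}"])
    out.filter_log = log
    return out


@dataclass(frozen=True)
class DataSplit:
    """A train/test index partition tagged with its split kind and seed."""

    kind: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    test_fraction: float
    discarded_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in SPLIT_KINDS:
            raise ValueError(f"unknown split kind {self.kind!r}")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")

    @property
    def realized_test_fraction(self) -> float:
        n = len(self.train_idx) + len(self.test_idx)
        return len(self.test_idx) / n if n else float("nan")


def _check_fraction(test_fraction: float) -> None:
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")


def random_split(ds: BindingDataset, seed: int, test_fraction: float = 0.2) -> DataSplit:
    """Uniform record-level partition; |test| = round(n * test_fraction)."""
    _check_fraction(test_fraction)
    n = len(ds)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    return DataSplit("random", np.sort(perm[n_test:]), np.sort(perm[:n_test]),
                     seed, test_fraction)


def _greedy_groups(groups: pd.Series, target_records: float,
                   rng: np.random.Generator) -> set:
    """Seeded shuffle of distinct group values; assign to the test side until
    the covered record count first reaches the target."""
    counts = groups.value_counts()
    values = np.sort(counts.index.to_numpy())
    rng.shuffle(values)
    chosen, covered = set(), 0
    for v in values:
        if covered >= target_records:
            break
        chosen.add(v)
        covered += int(counts[v])
    return chosen


def group_hard_split(ds: BindingDataset, group_key: str, seed: int,
                     test_fraction: float = 0.2) -> DataSplit:
    """Hard split on one key: all records of a group land on one side.

    ``group_key`` is ``"epitope"`` or ``"cdr3b"``; the corresponding split
    kinds are ``epitope_hard`` and ``tcr_hard``. Groups are shuffled with the
    seed and assigned greedily to the test side until the test record count
    first reaches ``test_fraction * n``.
    """
    _check_fraction(test_fraction)
    if group_key not in ("epitope", "cdr3b"):
        raise ValueError("group_key must be 'epitope' or 'cdr3b'")
    groups = ds.df[group_key]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 distinct group values")
    counts = groups.value_counts()
    if counts.iloc[0] > (1.0 - test_fraction) * len(ds):
        warnings.warn(f"largest {group_key} group holds more than "
                      f"{1 - test_fraction:.0%} of records; split will be lopsided")
    rng = np.random.default_rng(seed)
    test_groups = _greedy_groups(groups, test_fraction * len(ds), rng)
    mask = groups.isin(test_groups).to_numpy()
    kind = "epitope_hard" if group_key == "epitope" else "tcr_hard"
    split = DataSplit(kind, np.flatnonzero(~mask), np.flatnonzero(mask), seed,
                      test_fraction,
                      info={"n_unseen_groups": len(test_groups),
                            "group_key": group_key})
    return split


def strict_split(ds: BindingDataset, seed: int, test_fraction: float = 0.2) -> DataSplit:
    """Doubly-unseen split: test epitopes AND test CDR3βs absent from training.

    A test-side epitope set and CDR3β set are drawn greedily (seeded); test
    records have both keys on the test side, train records have both keys on
    the train side, and records crossing sides are discarded and counted.
    The per-key greedy fraction f solves f^2 (1-t) = t (1-f)^2, i.e.
    f = sqrt(t) / (sqrt(t) + sqrt(1-t)), so that the realized test share of
    the kept records lands near the target t.
    """
    _check_fraction(test_fraction)
    for key in ("epitope", "cdr3b"):
        if ds.df[key].nunique() < 2:
            raise ValueError(f"need at least 2 distinct {key} values")
    t = test_fraction
    f = math.sqrt(t) / (math.sqrt(t) + math.sqrt(1.0 - t))
    rng = np.random.default_rng(seed)
    test_epis = _greedy_groups(ds.df["epitope"], f * len(ds), rng)
    test_cdrs = _greedy_groups(ds.df["cdr3b"], f * len(ds), rng)
    epi_in = ds.df["epitope"].isin(test_epis).to_numpy()
    cdr_in = ds.df["cdr3b"].isin(test_cdrs).to_numpy()
    test_mask = epi_in & cdr_in
    train_mask = ~epi_in & ~cdr_in
    discard_mask = ~test_mask & ~train_mask
    if not test_mask.any() or not train_mask.any():
        raise ValueError("strict split produced an empty side")
    return DataSplit(
        "strict", np.flatnonzero(train_mask), np.flatnonzero(test_mask), seed,
        test_fraction, discarded_idx=np.flatnonzero(discard_mask),
        info={"n_unseen_epitopes": len(test_epis),
              "n_unseen_cdr3bs": len(test_cdrs),
              "n_discarded": int(discard_mask.sum())})


def make_split(ds: BindingDataset, kind: str, seed: int,
               test_fraction: float = 0.2) -> DataSplit:
    """Dispatch on split kind (random | epitope_hard | tcr_hard | strict)."""
    if kind == "random":
        return random_split(ds, seed, test_fraction)
    if kind == "epitope_hard":
        return group_hard_split(ds, "epitope", seed, test_fraction)
    if kind == "tcr_hard":
        return group_hard_split(ds, "cdr3b", seed, test_fraction)
    if kind == "strict":
        return strict_split(ds, seed, test_fraction)
    raise ValueError(f"unknown split kind {kind!r}")
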