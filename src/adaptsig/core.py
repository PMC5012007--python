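"""Core domain types and text-format I/O.

The analysis operates on three kinds of objects:

* :class:`QuantTable` — a features × samples matrix of (log2) intensities
  from label-free mass spectrometry or expression profiling, with a
  feature → protein/site mapping and per-sample (cell line, state,
  replicate) annotation.  Missing values are first-class (NaN mask) and are
  never imputed at I/O time; downstream operations decide policy.
* :class:`GeneSetCollection` — named identifier sets (GMT format), optionally
  direction-labelled (up/down), as used for mesenchymal, invasive/
  proliferative, kinase-substrate and TF-target signatures.
* :class:`RankedList` — identifiers strictly ordered by a real score
  (RNK format), with an explicit tie-resolution record.

Identifier matching is case-sensitive exact string match throughout; any
normalisation (upper-casing, alias tables) must be an explicit prior step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

STATES = ("parental", "persistent", "resistant")

__all__ = [
    "STATES",
    "QuantTable",
    "Contrast",
    "GeneSetCollection",
    "RankedList",
    "read_quant_table",
    "write_quant_table",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "rank_features",
]


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass
class QuantTable:
    """Features × samples quantification matrix with annotations.

    Parameters
    ----------
    values
        DataFrame indexed by ``feature_id`` with one column per sample.
        ``NaN`` marks a missing (undetected) value.
    feature_meta
        DataFrame indexed by ``feature_id`` with columns ``protein_id`` and
        ``site_label`` (empty string for protein-level features).
    sample_meta
        DataFrame indexed by sample name with columns ``cell_line``,
        ``state`` (one of :data:`STATES`) and ``replicate`` (positive int).
    scale
        ``"log2"`` or ``"raw"``; raw tables must be non-negative.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate feature_id {dup!r}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise DataError("sample columns do not match sample_meta index")
        if list(self.values.index) != list(self.feature_meta.index):
            raise DataError("feature index does not match feature_meta index")
        for col in ("protein_id", "site_label"):
            if col not in self.feature_meta.columns:
                raise DataError(f"feature_meta missing column {col!r}")
        for col in ("cell_line", "state", "replicate"):
            if col not in self.sample_meta.columns:
                raise DataError(f"sample_meta missing column {col!r}")
        bad_state = set(self.sample_meta["state"]) - set(STATES)
        if bad_state:
            raise DataError(f"unknown state(s) {sorted(bad_state)}")
        if (self.sample_meta["replicate"] < 1).any():
            raise DataError("replicate numbers must be positive")
        if self.scale == "raw":
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr) < 0 if np.isfinite(arr).any() else False:
                raise DataError("raw-scale table contains negative values")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def select(self, cell_line: str | None = None, state: str | None = None) -> list[str]:
        """Sample names matching a (cell_line, state) selector."""
        mask = pd.Series(True, index=self.sample_meta.index)
        if cell_line is not None:
            mask &= self.sample_meta["cell_line"] == cell_line
        if state is not None:
            mask &= self.sample_meta["state"] == state
        return list(self.sample_meta.index[mask])

    def subset_features(self, feature_ids: Sequence[str]) -> "QuantTable":
        return QuantTable(
            values=self.values.loc[list(feature_ids)],
            feature_meta=self.feature_meta.loc[list(feature_ids)],
            sample_meta=self.sample_meta,
            scale=self.scale,
        )


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison between (cell_line, state) selectors.

    ``group_a`` is the reference (typically parental); fold changes are
    reported as group_b − group_a on the log2 scale.
    """

    name: str
    group_a: tuple[str | None, str]
    group_b: tuple[str | None, str]
    paired: bool = False

    def resolve(self, table: QuantTable) -> tuple[list[str], list[str]]:
        a = table.select(*self.group_a)
        b = table.select(*self.group_b)
        if set(a) & set(b):
            raise DataError(f"contrast {self.name!r}: overlapping sample groups")
        if len(a) < 2 or len(b) < 2:
            raise DataError(
                f"contrast {self.name!r}: each group needs >=2 samples "
                f"(got {len(a)} and {len(b)})"
            )
        return a, b


# ----------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetCollection:
    """Named sets of identifiers with optional up/down direction labels."""

    sets: dict[str, tuple[str, ...]]
    direction: dict[str, str] = field(default_factory=dict)
    duplicate_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise DataError(f"empty gene set {name!r}")
        for name, d in self.direction.items():
            if d not in ("up", "down", "undirected"):
                raise DataError(f"bad direction {d!r} for set {name!r}")

    def members(self, name: str) -> frozenset[str]:
        return frozenset(self.sets[name])

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            direction={n: self.direction[n] for n in names if n in self.direction},
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members; tab-separated).

    Duplicate members within a set are de-duplicated (order-preserving)
    and counted in ``duplicate_counts``.  A description equal to ``up``,
    ``down`` or ``undirected`` is taken as the set's direction label.
    """
    sets: dict[str, tuple[str, ...]] = {}
    direction: dict[str, str] = {}
    dups: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}:{lineno}: GMT line with no members")
        name, desc, *members = parts
        members = [m for m in members if m != ""]
        if not members:
            raise DataError(f"{path}:{lineno}: empty set {name!r}")
        if name in sets:
            raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen: dict[str, None] = {}
        n_dup = 0
        for m in members:
            if m in seen:
                n_dup += 1
            else:
                seen[m] = None
        sets[name] = tuple(seen)
        if n_dup:
            dups[name] = n_dup
        if desc in ("up", "down", "undirected"):
            direction[name] = desc
    return GeneSetCollection(sets=sets, direction=direction, duplicate_counts=dups)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.direction.get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Ranked lists


@dataclass
class RankedList:
    """Identifiers strictly sorted descending by score, ties recorded."""

    ids: list[str]
    scores: np.ndarray
    ties: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise DataError("ids and scores length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate identifiers in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise DataError("scores not sorted descending")

    def __len__(self) -> int:
        return len(self.ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.ids)

    def reversed(self) -> "RankedList":
        return RankedList(
            ids=list(reversed(self.ids)),
            scores=-self.scores[::-1],
            ties=list(self.ties),
        )

    def rank_of(self, identifier: str) -> int:
        """1-based rank position."""
        return self.ids.index(identifier) + 1


def rank_features(scores: Mapping[str, float], tie_rule: str = "lexicographic") -> RankedList:
    """Order identifiers descending by score; ties broken deterministically.

    The default (and only built-in) tie rule orders tied identifiers
    lexicographically; each tied group is recorded in ``ties``.
    """
    if tie_rule != "lexicographic":
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    items = list(scores.items())
    arr = np.array([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [k for (k, v) in items if not np.isfinite(v)]
        raise DataError(f"non-finite score(s) for {bad[:5]}")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    # record tie groups
    ties: list[tuple[str, ...]] = []
    i = 0
    while i < len(items):
        j = i
        while j + 1 < len(items) and items[j + 1][1] == items[i][1]:
            j += 1
        if j > i:
            ties.append(tuple(k for k, _ in items[i : j + 1]))
        i = j + 1
    return RankedList(
        ids=[k for k, _ in items],
        scores=np.array([v for _, v in items], dtype=float),
        ties=ties,
    )


def read_rnk(path: str | Path) -> RankedList:
    """Read an id<TAB>score file and rank it (descending)."""
    scores: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            ident, val = line.rstrip("\n").split("\t")
            score = float(val)
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: malformed RNK line {line!r}") from exc
        if ident in scores:
            raise DataError(f"{path}:{lineno}: duplicate identifier {ident!r}")
        scores[ident] = score
    return rank_features(scores)


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    lines = [f"{i}\t{float(s)!r}" for i, s in zip(ranked.ids, ranked.scores)]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Quant table I/O

_META_COLS = ["protein_id", "site_label"]


def write_quant_table(
    table: QuantTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a TSV (feature_id, protein_id, site_label, samples...) plus a
    YAML sample-annotation sidecar (``<path>.meta.yaml`` by default).

    Floats are written with Python's shortest round-trip repr, so a
    write → read cycle is bit-exact.
    """
    path = Path(path)
    out = table.feature_meta[_META_COLS].copy()
    for col in table.values.columns:
        out[col] = table.values[col]
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(out.columns) + "\n")
        for fid, row in zip(out.index, out.to_numpy(dtype=object)):
            cells = [str(fid)]
            for cell in row:
                if isinstance(cell, float):
                    cells.append("NA" if np.isnan(cell) else repr(cell))
                else:
                    cells.append(str(cell))
            fh.write("\t".join(cells) + "\n")
    meta = {
        "scale": table.scale,
        "samples": {
            s: {
                "cell_line": str(r["cell_line"]),
                "state": str(r["state"]),
                "replicate": int(r["replicate"]),
            }
            for s, r in table.sample_meta.iterrows()
        },
    }
    meta_path = Path(meta_path) if meta_path else path.with_suffix(path.suffix + ".meta.yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))


def _load_meta(meta: str | Path | Mapping) -> dict:
    if isinstance(meta, (str, Path)):
        text = Path(meta).read_text()
        if str(meta).endswith(".json"):
            return json.loads(text)
        return yaml.safe_load(text)
    return dict(meta)


def read_quant_table(path: str | Path, meta: str | Path | Mapping) -> QuantTable:
    """Read a quantification TSV with its sample annotation.

    Missing values must be encoded as ``NA`` or an empty cell; any other
    non-numeric cell is an error (named by feature and sample), never a
    silent NaN.
    """
    meta_d = _load_meta(meta)
    scale = meta_d.get("scale", "log2")
    samples = meta_d["samples"]

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "feature_id":
        raise DataError(f"{path}: first column must be feature_id")
    has_meta_cols = header[1:3] == _META_COLS
    sample_cols = header[3:] if has_meta_cols else header[1:]
    for s in sample_cols:
        if s not in samples:
            raise DataError(f"{path}: sample {s!r} absent from annotation")

    fids: list[str] = []
    prot: list[str] = []
    site: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise DataError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
        fid = cells[0]
        if fid in seen:
            raise DataError(f"{path}: duplicate feature_id {fid!r}")
        seen.add(fid)
        fids.append(fid)
        if has_meta_cols:
            prot.append(cells[1])
            site.append("" if cells[2] in ("", "NA") else cells[2])
            data_cells = cells[3:]
        else:
            prot.append(fid)
            site.append("")
            data_cells = cells[1:]
        row: list[float] = []
        for s, cell in zip(sample_cols, data_cells):
            if cell in ("", "NA"):
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise DataError(
                        f"{path}:{lineno}: unparseable value {cell!r} "
                        f"for feature {fid!r}, sample {s!r}"
                    ) from exc
        rows.append(row)

    values = pd.DataFrame(rows, index=pd.Index(fids, name="feature_id"), columns=sample_cols)
    feature_meta = pd.DataFrame(
        {"protein_id": prot, "site_label": site}, index=pd.Index(fids, name="feature_id")
    )
    sample_meta = pd.DataFrame.from_dict(
        {s: samples[s] for s in sample_cols}, orient="index"
    )
    sample_meta.index.name = "sample"
    return QuantTable(values=values, feature_meta=feature_meta, sample_meta=sample_meta, scale=scale)
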