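"""Readers and writers for every external artifact of the pipeline.

All formats are plain text: tab-separated matrices and tables, SIF edge
lists, GMT gene sets.  Loading is strict — malformed cells raise
:class:`ParseError` naming the offending position, and structural problems
(duplicate identifiers, labels outside the vocabulary) raise
:class:`ValidationError` — because the downstream rank transform is
undefined on missing or duplicated entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("reference", "disease")

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "InteractionNetwork",
    "read_expression",
    "read_condition",
    "read_network",
    "read_survival",
    "read_gmt",
    "write_gmt",
    "read_coefficients",
    "write_matrix",
    "write_series",
    "write_json",
]


class ParseError(ValueError):
    """A cell or row of an input file could not be interpreted."""


class ValidationError(ValueError):
    """A structurally well-formed input violates a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional condition labels.

    ``values`` holds normalized expression (log2(TPM+1) for RNA-seq or
    normalized array intensities) with unique gene ids as the index and
    unique sample ids as columns.  ``condition`` maps each sample to
    ``reference`` or ``disease``; it is optional at load time but required
    before a perturbation baseline can be fitted.
    """

    values: pd.DataFrame
    condition: pd.Series | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if v.shape[0] < 2:
            raise ValidationError("expression matrix needs at least 2 genes")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise ValidationError("expression values must all be finite numbers")
        if self.condition is not None:
            cond = self.condition.reindex(v.columns)
            if cond.isna().any():
                missing = cond.index[cond.isna()][0]
                raise ValidationError(f"sample {missing!r} has no condition label")
            bad = set(cond.unique()) - set(CONDITIONS)
            if bad:
                raise ValidationError(
                    f"condition labels {sorted(bad)} outside {CONDITIONS}"
                )
            self.condition = cond

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with(self, condition: str) -> list[str]:
        if self.condition is None:
            raise ValidationError("expression matrix carries no condition labels")
        return list(self.condition.index[self.condition == condition])


@dataclass
class InteractionNetwork:
    """Directed gene-pair edge list.

    Direction is fixed metadata: the delta-rank of an edge (a -> b) is
    rank(a) - rank(b), so reversing an edge negates its row.
    """

    edges: list[tuple[str, str]]
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s, t in self.edges:
            if s == t:
                raise ValidationError(f"self-loop on {s!r}")
            if (s, t) in seen:
                raise ValidationError(f"duplicate edge ({s!r}, {t!r})")
            seen.add((s, t))
        if not self.edges:
            raise ValidationError("network has no edges")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s, t in self.edges:
            out.add(s)
            out.add(t)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def _check_unique_header(path: Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValidationError(f"duplicate sample id {s!r} in {path}")
        seen.add(s)
    return samples


def read_expression(
    path: str | Path,
    condition_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load a TSV expression matrix (first column gene ids, header samples).

    Duplicate gene rows are collapsed by arithmetic mean, mirroring the
    standard handling of multiple array probes mapping to one symbol; the
    number collapsed is recorded in ``.report``.  ``transpose`` handles the
    samples-in-rows dialect.
    """
    path = Path(path)
    _check_unique_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    # locate non-numeric / missing cells before any collapsing
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            raise ParseError(
                f"non-numeric value at gene {bad[0]!r}, sample {col!r} in {path}"
            )
        df[col] = series.astype(float)
    n_rows = df.shape[0]
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    report = {"rows_read": n_rows, "genes_collapsed": n_rows - df.shape[0]}
    condition = read_condition(condition_path) if condition_path else None
    return ExpressionMatrix(values=df, condition=condition, report=report)


def read_condition(path: str | Path) -> pd.Series:
    """Two-column sample/condition table; a header row is auto-detected."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {ln} of {path}: expected 2 columns")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][1] not in CONDITIONS:
        rows = rows[1:]  # header row
    cond = pd.Series({s: c for s, c in rows}, name="condition")
    if len(cond) != len(rows):
        raise ValidationError(f"duplicate sample id in condition table {path}")
    bad = set(cond.unique()) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"condition labels {sorted(bad)} outside {CONDITIONS}")
    return cond


def read_network(path: str | Path) -> InteractionNetwork:
    """Load a directed edge list: 2-column TSV or 3-column SIF.

    In the SIF dialect the middle (interaction-type) column is ignored.
    Duplicate pairs and self-loops are dropped; counts go in ``.report``.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 2:
                s, t = parts
            elif len(parts) >= 3:
                s, t = parts[0], parts[2]  # SIF: source type target
            else:
                raise ParseError(f"line {ln} of {path}: missing target column")
            if not s or not t:
                raise ParseError(f"line {ln} of {path}: missing target column")
            if s == t:
                n_self += 1
                continue
            if (s, t) in seen:
                n_dup += 1
                continue
            seen.add((s, t))
            edges.append((s, t))
    if not edges:
        raise ValidationError(f"network file {path} contains no usable edges")
    return InteractionNetwork(
        edges=edges, report={"duplicates_dropped": n_dup, "self_loops_dropped": n_self}
    )


def read_survival(path: str | Path) -> pd.DataFrame:
    """TSV survival table (sample_id, time, event) indexed by sample id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError(f"survival table {path} needs 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["sample_id", "time", "event"]
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"duplicate sample id in survival table {path}")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    if df[["time", "event"]].isna().any().any():
        raise ParseError(f"non-numeric time/event in survival table {path}")
    if (df["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 (censored) or 1 (event)")
    df["event"] = df["event"].astype(int)
    return df.set_index("sample_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {ln} of {path}: GMT needs name, desc, genes")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ValidationError(f"GMT file {path} is empty")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "perturbnet") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_coefficients(path: str | Path) -> pd.Series:
    """Two-column gene/coefficient TSV; a header row is auto-detected."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"coefficient table {path} needs 2 columns")
    first = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if pd.isna(first):
        df = df.iloc[1:]
    genes = df.iloc[:, 0].astype(str)
    coefs = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if coefs.isna().any():
        gene = genes[coefs.isna()].iloc[0]
        raise ParseError(f"non-numeric coefficient for gene {gene!r} in {path}")
    if genes.duplicated().any():
        raise ValidationError(f"duplicate gene in coefficient table {path}")
    if not np.isfinite(coefs.to_numpy()).all():
        raise ValidationError("coefficients must be finite")
    return pd.Series(coefs.to_numpy(float), index=list(genes), name="coef")


def write_matrix(obj: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a matrix as TSV with 17 significant digits (exact round-trip)."""
    obj.to_csv(path, sep="\t", float_format="%.17g", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_series(series: pd.Series, path: str | Path,
                 index_label: str = "sample_id", value_label: str = "value") -> None:
    df = series.rename(value_label).to_frame()
    df.to_csv(path, sep="\t", float_format="%.17g", index_label=index_label)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")
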