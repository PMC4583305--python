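"""Readers and writers: data matrices, summary tables, hierarchies, reports.

Conventions: variable indexing is 1-based in every human-facing file (merge
tables, Newick labels, reports) and 0-based internally.  Dendrogram export
uses the merge *step index* as the node height — Bayes-factor similarities
are not monotone along the merge sequence, and tree formats require monotone
heights; the true similarities live in the merge table.
"""

from __future__ import annotations

import json
from importlib import metadata, resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ahc import Hierarchy, MergeRecord, Partition, partition_at_level
from .evidence import SumOfSquares
from .linalg import symmetrize

__all__ = [
    "read_data_matrix",
    "read_summary_table",
    "read_square_matrix",
    "load_toy_example",
    "write_hierarchy",
    "read_merge_table",
    "read_partition_file",
    "to_newick",
    "validate_report",
]

PathLike = Union[str, Path]


def _package_version() -> str:
    try:
        return metadata.version("bayesahc")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_delimited(path: PathLike) -> pd.DataFrame:
    """Read a comma- or tab-delimited numeric table, auto-detecting an
    optional header row and an optional leading column of row names."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    tokens = [t for t in first.rstrip("\n").split(sep)]
    data_tokens = [t for t in tokens if t.strip() != ""]
    header = 0 if not all(_is_number(t) for t in data_tokens) else None
    df = pd.read_csv(path, sep=sep, header=header)
    # a non-numeric first column is a name column
    if df.shape[1] > 1 and df.iloc[:, 0].dtype == object:
        df = df.set_index(df.columns[0])
    return df


def read_data_matrix(
    path: PathLike, orientation: str = "samples_by_variables"
) -> SumOfSquares:
    """Read a raw data matrix and form the sum of squares about the sample mean.

    ``orientation`` says whether rows are samples (default) or variables.
    N_eff = N - 1 (unknown-mean rule).  Variable names come from the header
    when present.
    """
    if orientation not in ("samples_by_variables", "variables_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-numeric or missing cells")
    names: Optional[Sequence[str]] = None
    if orientation == "variables_by_samples":
        if isinstance(df.index, pd.Index) and df.index.dtype == object:
            names = [str(n) for n in df.index]
        values = values.T
    elif df.columns.dtype == object:
        names = [str(c) for c in df.columns]
    if values.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    return SumOfSquares.from_data(values, names=names)


def read_square_matrix(
    path: PathLike,
    n: int,
    mode: str = "covariance",
) -> SumOfSquares:
    """Read a full covariance or correlation matrix; S = (n-1) * matrix."""
    df = _read_delimited(path)
    mat = symmetrize(df.to_numpy(dtype=float))
    names = [str(c) for c in df.columns] if df.columns.dtype == object else None
    return SumOfSquares.from_covariance(mat, n_obs=int(n), mode=mode, names=names)


def read_summary_table(
    path: PathLike, n: int, mode: str = "covariance"
) -> SumOfSquares:
    """Read a summary table: variances on the diagonal, correlations below it.

    The upper triangle (partial correlations in the reference table layout)
    is ignored.  The covariance is reconstructed as
    Sigma_ij = r_ij sqrt(v_i v_j) and S = (n - 1) Sigma; in correlation mode
    S = (n - 1) R instead.  ``n`` is the number of observations.
    """
    df = _read_delimited(path)
    raw = df.to_numpy(dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"{path}: summary table must be square, got {raw.shape}")
    d = raw.shape[0]
    variances = np.diag(raw)
    if np.any(variances <= 0):
        raise ValueError(f"{path}: diagonal variances must be positive")
    corr = np.eye(d)
    for i in range(d):
        for j in range(i):
            r = raw[i, j]
            if abs(r) > 1.0:
                raise ValueError(f"{path}: correlation |{r}| > 1 at ({i}, {j})")
            corr[i, j] = corr[j, i] = r
    names = [str(c) for c in df.columns] if df.columns.dtype == object else None
    if mode == "correlation":
        return SumOfSquares.from_covariance(
            corr, n_obs=int(n), mode="correlation", names=names
        )
    sd = np.sqrt(variances)
    sigma = corr * np.outer(sd, sd)
    return SumOfSquares.from_covariance(
        sigma, n_obs=int(n), mode="covariance", names=names
    )


def load_toy_example(n: int = 107, mode: str = "covariance") -> SumOfSquares:
    """The packaged 6-variable HIV blood-measurement summary table.

    Immunoglobulins G and A (x1, x2), lymphocytes B and T4 (x3, x5), the
    T4/T8 ratio (x6) and the platelet count (x4), summarized by sample
    variances and correlations from n = 107 children.
    """
    with resources.as_file(
        resources.files("bayesahc").joinpath("data/hiv_summary.tsv")
    ) as p:
        return read_summary_table(p, n=n, mode=mode)


def to_newick(h: Hierarchy) -> str:
    """Newick string with merge-step heights and 1-based leaf labels.

    A truncated hierarchy (automatic stopping) is joined under an artificial
    root one step above the last merge so the output stays a single tree.
    """
    names = h.names or tuple(f"x{i + 1}" for i in range(h.n_vars))
    height: Dict[int, float] = {i: 0.0 for i in range(h.n_vars)}
    node: Dict[int, str] = {i: names[i] for i in range(h.n_vars)}
    roots = set(range(h.n_vars))
    for rec in h.merges:
        new_id = h.n_vars - 1 + rec.step
        bl_l = rec.step - height[rec.left]
        bl_r = rec.step - height[rec.right]
        node[new_id] = f"({node[rec.left]}:{bl_l:g},{node[rec.right]}:{bl_r:g})"
        height[new_id] = float(rec.step)
        roots -= {rec.left, rec.right}
        roots.add(new_id)
    if len(roots) == 1:
        return node[roots.pop()] + ";"
    top = len(h.merges) + 1
    parts = ",".join(f"{node[r]}:{top - height[r]:g}" for r in sorted(roots))
    return f"({parts});"


def write_hierarchy(
    h: Hierarchy,
    prefix: PathLike,
    seed: Optional[int] = None,
    partition: Optional[Partition] = None,
    input_description: Optional[str] = None,
    n_eff: Optional[float] = None,
) -> Dict[str, Path]:
    """Write merge table (TSV), Newick tree, and a JSON run report.

    Returns the mapping of artifact kind to path.  All ids in the files are
    1-based.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "merges": prefix.with_name(prefix.name + "_merges.tsv"),
        "tree": prefix.with_name(prefix.name + "_tree.nwk"),
        "report": prefix.with_name(prefix.name + "_report.json"),
    }

    cum = h.cumulative_evidence
    rows = []
    for rec in h.merges:
        rows.append(
            {
                "step": rec.step,
                "left_id": rec.left + 1,
                "right_id": rec.right + 1,
                "similarity": rec.similarity,
                "new_size": len(rec.members),
                "cumulative_evidence": cum[rec.step] if cum is not None else np.nan,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "step",
            "left_id",
            "right_id",
            "similarity",
            "new_size",
            "cumulative_evidence",
        ],
    ).to_csv(paths["merges"], sep="\t", index=False)

    paths["tree"].write_text(to_newick(h) + "\n")

    if partition is None:
        partition = partition_at_level(h, len(h.merges))
    report = {
        "version": _package_version(),
        "method": h.method,
        "input": input_description,
        "n_vars": h.n_vars,
        "n_eff": float(n_eff) if n_eff is not None else float("nan"),
        "seed": seed,
        "stop_level": h.stop_level,
        "n_merges": len(h.merges),
        "names": list(h.names) if h.names is not None else None,
        "cumulative_evidence": list(cum) if cum is not None else None,
        "merges": [
            [rec.step, rec.left + 1, rec.right + 1, rec.similarity] for rec in h.merges
        ],
        "partition": [lab + 1 for lab in partition.labels],
    }
    validate_report(report)
    paths["report"].write_text(json.dumps(report, indent=2, allow_nan=True) + "\n")
    return paths


def read_merge_table(path: PathLike, n_vars: int, method: str = "unknown") -> Hierarchy:
    """Reconstruct a hierarchy from a written merge table (round-trip reader)."""
    df = pd.read_csv(path, sep="\t")
    members: Dict[int, tuple] = {i: (i,) for i in range(n_vars)}
    merges: List[MergeRecord] = []
    for _, row in df.iterrows():
        step = int(row["step"])
        left, right = int(row["left_id"]) - 1, int(row["right_id"]) - 1
        new = tuple(sorted(members[left] + members[right]))
        members[n_vars - 1 + step] = new
        merges.append(
            MergeRecord(
                step=step,
                left=left,
                right=right,
                similarity=float(row["similarity"]),
                members=new,
            )
        )
    cum: Optional[tuple] = None
    if not df["cumulative_evidence"].isna().any():
        cum = (0.0, *[float(v) for v in df["cumulative_evidence"]])
    return Hierarchy(
        n_vars=n_vars,
        merges=tuple(merges),
        cumulative_evidence=cum,
        stop_level=len(merges),
        method=method,
    )


def read_partition_file(path: PathLike) -> Partition:
    """Read cluster labels: whitespace/comma-separated, one or many lines."""
    text = Path(path).read_text().replace(",", " ").split()
    if not text:
        raise ValueError(f"{path}: empty partition file")
    try:
        labels = [int(t) for t in text]
    except ValueError as exc:
        raise ValueError(f"{path}: labels must be integers") from exc
    return Partition(labels=tuple(labels))


_SCHEMA = json.loads(
    resources.files("bayesahc").joinpath("data/report.schema.json").read_text()
)

_TYPE_MAP = {
    "string": str,
    "integer": int,
    "number": (int, float),
    "array": list,
    "object": dict,
    "null": type(None),
}


def validate_report(report: dict) -> None:
    """Check a run report against the shipped schema (required keys + types)."""
    for key in _SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
    for key, spec in _SCHEMA["properties"].items():
        if key not in report:
            continue
        types = spec["type"]
        if isinstance(types, str):
            types = [types]
        allowed: tuple = ()
        for name in types:
            t = _TYPE_MAP[name]
            allowed += t if isinstance(t, tuple) else (t,)
        if not isinstance(report[key], allowed):
            raise ValueError(
                f"report field {key!r} has type {type(report[key]).__name__}, "
                f"expected {types}"
            )
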