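"""File I/O and run configuration.

On disk, expression matrices follow the genomics convention: rows are
features (genes), columns are samples, with the first column holding feature
identifiers and the header row holding sample identifiers.  Internally all
math runs on samples x features arrays.  TSV and CSV are chosen by file
extension; gzip compression (``.gz``) is transparent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import GroupLabels, OutlierReport
from .errors import DataError, DepthQCWarning

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_groups",
    "write_report",
    "read_report",
]


@dataclass
class RunConfig:
    """All knobs of a detection run (mirrors the CLI flags)."""

    matrix: str = None
    groups: str = None
    method: str = "3d"
    n_components: int = 3
    resolution: int | None = None
    fence_factor: float = 3.0
    padding: float = 0.1
    metric: str = "euclidean"
    transform: str = "none"
    seed: int = 0
    out: str = "report"
    verbosity: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("1d", "2d", "3d", "4d", "cluster"):
            raise DataError(f"unknown method '{self.method}'")
        if self.transform not in ("none", "log2p1"):
            raise DataError(f"unknown transform '{self.transform}'")
        if self.method == "4d" and self.n_components < 4:
            self.n_components = 4


def _sep_for(path: str) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def _raw_header(path, sep):
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return fh.readline().rstrip("\n").split(sep)


def read_expression(path):
    """Read a features x samples matrix; returns (X, sample_ids, feature_ids)
    with X oriented samples x features."""
    sep = _sep_for(path)
    try:
        header = _raw_header(path, sep)
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"expression matrix {path} is empty")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise DataError(f"duplicate sample identifiers in {path}: {dups}")
    df.columns = samples
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().all():
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                raise DataError(
                    f"non-numeric value in {path} at row '{bad[0]}', "
                    f"column '{col}'"
                )
    X = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(X)):
        raise DataError(f"expression matrix {path} contains missing or "
                        "non-finite values")
    return X, list(df.columns), list(df.index)


def write_expression(path, X, sample_ids, feature_ids) -> None:
    """Write a samples x features array as a features x samples table."""
    df = pd.DataFrame(np.asarray(X).T, index=feature_ids, columns=sample_ids)
    df.index.name = "feature"
    df.to_csv(path, sep=_sep_for(path))


def read_groups(path, sample_ids=None) -> GroupLabels:
    """Read a two-column sample_id/group table, validated against the matrix.

    Samples present in the matrix but unlabeled raise an error naming them;
    labels for samples absent from the matrix are dropped with a warning.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                         comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot parse group file {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise DataError(f"group file {path} must have exactly two columns")
    first = [str(v).lower() for v in df.iloc[0]]
    if first == ["sample_id", "group"] or first == ["sample", "group"]:
        df = df.iloc[1:]
    mapping = dict(zip(df[0], df[1]))
    if len(mapping) != len(df):
        raise DataError(f"duplicate sample identifiers in group file {path}")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DataError(f"samples without a group label: {missing[:5]}")
        extra = [s for s in mapping if s not in set(sample_ids)]
        if extra:
            warnings.warn(f"group file labels {len(extra)} samples absent "
                          f"from the matrix; ignored", DepthQCWarning,
                          stacklevel=2)
        mapping = {s: mapping[s] for s in sample_ids}
    return GroupLabels(mapping)


def write_report(report: OutlierReport, json_path, tsv_path=None) -> None:
    """Serialize a report as JSON (full provenance) and a flat per-sample TSV."""
    payload = report.to_dict()
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    if tsv_path is None or report.labels is None:
        return
    rows = []
    for sid, group in report.labels.items():
        flagged = sid in report.flags.get(group, frozenset())
        rows.append({
            "sample_id": sid,
            "group": group,
            "method": report.method,
            "flagged": int(flagged),
            "provenance": ";".join(report.provenance.get(sid, ())),
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_report(json_path) -> OutlierReport:
    """Load a JSON report back into an :class:`OutlierReport`."""
    with open(json_path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != "depthqc-report/1":
        raise DataError(f"unrecognized report schema in {json_path}")
    return OutlierReport(
        method=payload["method"],
        flags={g: frozenset(s) for g, s in payload["flags"].items()},
        provenance={s: tuple(p) for s, p in payload["provenance"].items()},
        parameters=payload.get("parameters", {}),
        scree_values=[(int(j), float(v)) for j, v in payload.get("scree", [])],
    )
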