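"""Reading and writing the package's file formats.

Data sets are plain CSV (comma-separated, UTF-8, header row, '.'
decimal) with one designated label column and metric feature columns.
Selection ensembles travel as JSON ({"p": ..., "sets": [[...], ...]})
or as plain text, one set per line with whitespace-separated feature
identifiers.  Sweep results serialize to CSV (tabular) and JSON (full,
including per-fold feature sets); undefined stability values are
written as null/empty, never as a numeric sentinel.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .ensemble import SelectionEnsemble
from .errors import FormatError
from .evaluation import Configuration, EvaluationResult
from .stability import StabilityScore, measure_range

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_feature_sets",
    "write_feature_sets",
    "write_results",
    "read_results",
    "write_manifest",
]

_PARAM_COLUMNS = ("m_stop", "lambda", "num.trees", "min.node.size", "sigma", "C")


def read_dataset(path, label_col: str = "class") -> LabeledDataset:
    """Read a labeled feature matrix from CSV.

    Raises :class:`FormatError` naming the offending cell for missing
    or non-numeric values, and :class:`SingleClassError` when the label
    column holds a single class.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if label_col not in frame.columns:
        raise FormatError(
            f"label column {label_col!r} not found in {path} "
            f"(columns: {list(frame.columns)[:5]}...)"
        )
    y = frame[label_col].to_numpy()
    X = frame.drop(columns=[label_col])
    for col in X.columns:
        if X[col].isna().any():
            row = int(X[col].isna().idxmax())
            raise FormatError(f"missing value at row {row}, column {col!r}")
        if not np.issubdtype(X[col].dtype, np.number):
            bad = X[col][pd.to_numeric(X[col], errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else 0
            raise FormatError(
                f"non-numeric value at row {row}, column {col!r}"
            )
    if pd.Series(y).isna().any():
        row = int(pd.Series(y).isna().idxmax())
        raise FormatError(f"missing label at row {row}")
    return LabeledDataset(X=X, y=y, provenance=str(path))


def write_dataset(data: LabeledDataset, path, label_col: str = "class") -> None:
    frame = data.X.copy()
    frame[label_col] = data.y
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# selection ensembles


def write_feature_sets(ens: SelectionEnsemble, path, names=None) -> None:
    """Write an ensemble as JSON (``.json``) or plain text (anything else).

    With ``names``, sets are written as feature names instead of 0-based
    indices; JSON then records the full name list so indices can be
    recovered on read.
    """
    path = Path(path)
    if names is not None and len(names) != ens.p:
        raise FormatError("names must have length p")
    sets = [sorted(s) for s in ens.sets]
    if path.suffix == ".json":
        payload: Dict = {"p": ens.p}
        if names is None:
            payload["sets"] = sets
        else:
            payload["feature_names"] = list(names)
            payload["sets"] = [[names[j] for j in s] for s in sets]
        path.write_text(json.dumps(payload, indent=1))
    else:
        lines = []
        for s in sets:
            items = [str(j) if names is None else str(names[j]) for j in s]
            lines.append(" ".join(items))
        path.write_text("\n".join(lines) + "\n")


def read_feature_sets(path, p: Optional[int] = None, names=None) -> SelectionEnsemble:
    """Read an ensemble written by :func:`write_feature_sets`.

    For the text format ``p`` (or ``names``) must be supplied, since the
    file does not record the number of candidate features.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        names = payload.get("feature_names", names)
        p = int(payload["p"])
        raw_sets = payload["sets"]
    else:
        raw_sets = [
            line.split() for line in path.read_text().splitlines() if line.strip()
        ]
        if names is not None:
            p = len(names)
        if p is None:
            raise FormatError("text feature-set files need p or feature names")
    index = {str(nm): j for j, nm in enumerate(names)} if names is not None else None
    sets = []
    for s in raw_sets:
        if index is not None and all(str(x) in index for x in s):
            sets.append(frozenset(index[str(x)] for x in s))
        else:
            sets.append(frozenset(int(x) for x in s))
    return SelectionEnsemble(p=p, sets=tuple(sets))


# ---------------------------------------------------------------------------
# sweep results


def _result_record(r: EvaluationResult) -> Dict:
    rec: Dict = {
        "filter": r.configuration.filter,
        "n_feats": r.configuration.n_feats,
        "classifier": r.configuration.classifier,
    }
    for name in _PARAM_COLUMNS:
        rec[name] = r.configuration.params.get(name)
    rec["error"] = None if math.isnan(r.error) else r.error
    rec["size"] = None if math.isnan(r.size) else r.size
    rec["folds"] = r.folds
    rec["seed"] = r.seed
    for key in sorted(r.stability):
        rec[key] = r.stability[key].value
    return rec


def write_results(
    results: Sequence[EvaluationResult], path, format: Optional[str] = None
) -> None:
    """Write sweep results as CSV (tabular) or JSON (full round-trip).

    The JSON form additionally stores the per-fold feature sets, so
    :func:`read_results` can reconstruct the ensembles exactly.
    Undefined stability values become JSON null / empty CSV cells.
    """
    if len(results) == 0:
        raise FormatError("refusing to write an empty result set")
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    records = [_result_record(r) for r in results]
    if fmt == "csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    elif fmt == "json":
        for rec, r in zip(records, results):
            rec["p"] = r.ensemble.p
            rec["fold_sets"] = [sorted(s) for s in r.ensemble.sets]
            rec["stability_reasons"] = {
                k: v.reason for k, v in r.stability.items() if not v.defined
            }
            rec["alphas"] = {
                k: v.alpha for k, v in r.stability.items() if v.alpha is not None
            }
        path.write_text(json.dumps(records, indent=1))
    else:
        raise FormatError(f"unknown results format {fmt!r}")


def read_results(path) -> List[EvaluationResult]:
    """Reconstruct results from a JSON file written by :func:`write_results`."""
    path = Path(path)
    records = json.loads(path.read_text())
    out = []
    for rec in records:
        params = {
            k: rec[k] for k in _PARAM_COLUMNS if rec.get(k) is not None
        }
        config = Configuration(
            filter=rec["filter"],
            n_feats=int(rec["n_feats"]),
            classifier=rec["classifier"],
            params=params,
        )
        ens = SelectionEnsemble(
            p=int(rec["p"]), sets=tuple(frozenset(s) for s in rec["fold_sets"])
        )
        reasons = rec.get("stability_reasons", {})
        alphas = rec.get("alphas", {})
        stability = {}
        meta_keys = set(
            ["filter", "n_feats", "classifier", "error", "size", "folds",
             "seed", "p", "fold_sets", "stability_reasons", "alphas"]
        ) | set(_PARAM_COLUMNS)
        for key, value in rec.items():
            if key in meta_keys:
                continue
            alpha = alphas.get(key)
            stability[key] = StabilityScore(
                measure=key,
                value=value,
                range=measure_range(key, ens.m, ens.p, alpha or 0.0),
                alpha=alpha,
                reason=reasons.get(key),
            )
        out.append(
            EvaluationResult(
                configuration=config,
                error=float("nan") if rec["error"] is None else float(rec["error"]),
                size=float("nan") if rec["size"] is None else float(rec["size"]),
                ensemble=ens,
                stability=stability,
                folds=int(rec["folds"]),
                seed=int(rec["seed"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run manifests


def write_manifest(
    out_path, command: str, params: Dict, seed: Optional[int], inputs: Sequence
) -> Path:
    """Write a JSON manifest next to a CLI output file.

    Records the command, fully resolved parameters, seed, SHA-256 of
    every input file and the package version, so deterministic runs can
    be reproduced bit-identically.
    """
    from . import __version__

    out_path = Path(out_path)
    hashes = {}
    for ipath in inputs:
        ipath = Path(ipath)
        hashes[str(ipath)] = hashlib.sha256(ipath.read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "parameters": params,
        "seed": seed,
        "input_sha256": hashes,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    mpath = out_path.with_suffix(out_path.suffix + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
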