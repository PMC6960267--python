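"""Reading and writing datasets, truths, configs and results.

The canonical on-disk form of a dataset is a long CSV with one row per
observed person-item pair::

    person_id,item_id,response,time_seconds

IDs are strings (never assumed integer or contiguous); person and item order
is first-appearance order.  A wide paired format — two CSVs holding the
response matrix and the time matrix with a shared layout — is supported for
spreadsheet-style inputs: for a base path ``data``, the files are
``data_responses.csv`` and ``data_times.csv`` (first column person_id, one
column per item; empty cells mean unobserved).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import Dataset, HyperParams, ItemParams, PersonParams, TestParams
from .sampler import MCMCConfig, PosteriorResult
from .simulate import SimDesign, SimTruth

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_truth",
    "read_truth",
    "write_posterior",
]

_FLOAT_FMT = "%.15g"  # >= 12 significant digits round-trip


def read_dataset(path, format: str = "long-csv") -> Dataset:
    """Read a dataset from disk.

    ``format`` is ``"long-csv"`` (one row per observed pair) or
    ``"wide-pair-csv"`` (``path`` is a base; ``<base>_responses.csv`` and
    ``<base>_times.csv`` are read).  Pairs absent from the file are masked
    out.  Duplicate pairs, nonpositive times and non-binary responses raise
    with the offending pair / row identified.
    """
    if format == "long-csv":
        return _read_long(Path(path))
    if format == "wide-pair-csv":
        return _read_wide(Path(path))
    raise ValueError(f"unknown format {format!r}")


def _read_long(path: Path) -> Dataset:
    df = pd.read_csv(path, dtype={"person_id": str, "item_id": str})
    required = {"person_id", "item_id", "response", "time_seconds"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    dup = df.duplicated(subset=["person_id", "item_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"{path}: duplicate (person,item) pair ({row.person_id!r}, {row.item_id!r})")
    bad_t = ~(df["time_seconds"] > 0)
    if bad_t.any():
        # +2: header line plus 1-based indexing
        raise ValueError(f"{path}: nonpositive time_seconds at row {int(np.flatnonzero(bad_t)[0]) + 2}")
    bad_u = ~df["response"].isin([0, 1])
    if bad_u.any():
        raise ValueError(f"{path}: response outside {{0,1}} at row {int(np.flatnonzero(bad_u)[0]) + 2}")

    persons = list(dict.fromkeys(df["person_id"]))
    items = list(dict.fromkeys(df["item_id"]))
    p_idx = {p: i for i, p in enumerate(persons)}
    i_idx = {it: j for j, it in enumerate(items)}
    n, m = len(persons), len(items)
    responses = np.zeros((n, m))
    times = np.ones((n, m))
    mask = np.zeros((n, m), dtype=bool)
    rows = df["person_id"].map(p_idx).to_numpy()
    cols = df["item_id"].map(i_idx).to_numpy()
    responses[rows, cols] = df["response"].to_numpy(dtype=float)
    times[rows, cols] = df["time_seconds"].to_numpy(dtype=float)
    mask[rows, cols] = True
    return Dataset(responses=responses, times=times, mask=mask, person_ids=persons, item_ids=items)


def _read_wide(base: Path) -> Dataset:
    resp = pd.read_csv(f"{base}_responses.csv", index_col=0, dtype={0: str})
    times = pd.read_csv(f"{base}_times.csv", index_col=0, dtype={0: str})
    if list(resp.index) != list(times.index) or list(resp.columns) != list(times.columns):
        raise ValueError("response and time matrices must share persons and items")
    r = resp.to_numpy(dtype=float)
    t = times.to_numpy(dtype=float)
    mask = ~(np.isnan(r) | np.isnan(t))
    if np.any(t[mask] <= 0):
        raise ValueError("nonpositive time in wide time matrix")
    if not np.all(np.isin(r[mask], (0.0, 1.0))):
        raise ValueError("non-binary response in wide response matrix")
    return Dataset(
        responses=np.where(mask, r, 0.0),
        times=np.where(mask, t, 1.0),
        mask=mask,
        person_ids=[str(p) for p in resp.index],
        item_ids=[str(c) for c in resp.columns],
    )


def write_dataset(dataset: Dataset, path, format: str = "long-csv") -> None:
    """Write a dataset; deterministic row/column order, round-trips with read."""
    if format == "long-csv":
        rows, cols = np.nonzero(dataset.mask)
        df = pd.DataFrame(
            {
                "person_id": [dataset.person_ids[i] for i in rows],
                "item_id": [dataset.item_ids[j] for j in cols],
                "response": dataset.responses[rows, cols].astype(int),
                "time_seconds": dataset.times[rows, cols],
            }
        )
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "wide-pair-csv":
        r = pd.DataFrame(np.where(dataset.mask, dataset.responses, np.nan), index=dataset.person_ids, columns=dataset.item_ids)
        t = pd.DataFrame(np.where(dataset.mask, dataset.times, np.nan), index=dataset.person_ids, columns=dataset.item_ids)
        r.to_csv(f"{path}_responses.csv", index_label="person_id", float_format=_FLOAT_FMT)
        t.to_csv(f"{path}_times.csv", index_label="person_id", float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_config(path) -> MCMCConfig:
    """Read an MCMCConfig from a YAML or JSON file (keys = config fields)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(MCMCConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return MCMCConfig(**data)


def write_truth(truth: SimTruth, path) -> None:
    """Serialize generating parameters (a JSON sidecar to a simulated dataset)."""
    payload = {
        "design": {
            "n_persons": truth.design.n_persons,
            "n_items": truth.design.n_items,
            "sigma_theta_tau": truth.design.sigma_theta_tau,
            "item_mean": list(truth.design.item_mean),
            "item_cov": truth.design.item_cov.tolist(),
            "generating_model": truth.design.generating_model,
            "seed": truth.design.seed,
        },
        "item": {k: getattr(truth.item, k).tolist() for k in ("a", "b", "beta", "sigma", "alpha")},
        "test": {"zeta": truth.test.zeta},
        "person": {"theta": truth.person.theta.tolist(), "tau": truth.person.tau.tolist()},
        "hyper": {
            "sigma_theta_tau": truth.hyper.sigma_theta_tau,
            "mu_b": truth.hyper.mu_b,
            "mu_beta": truth.hyper.mu_beta,
            "Sigma_I": truth.hyper.Sigma_I.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    design = SimDesign(
        n_persons=d["design"]["n_persons"],
        n_items=d["design"]["n_items"],
        sigma_theta_tau=d["design"]["sigma_theta_tau"],
        item_mean=tuple(d["design"]["item_mean"]),
        item_cov=np.array(d["design"]["item_cov"]),
        generating_model=d["design"]["generating_model"],
        seed=d["design"]["seed"],
    )
    return SimTruth(
        item=ItemParams(**{k: np.array(v) for k, v in d["item"].items()}),
        test=TestParams(zeta=d["test"]["zeta"]),
        person=PersonParams(theta=np.array(d["person"]["theta"]), tau=np.array(d["person"]["tau"])),
        hyper=HyperParams(
            sigma_theta_tau=d["hyper"]["sigma_theta_tau"],
            mu_b=d["hyper"]["mu_b"],
            mu_beta=d["hyper"]["mu_beta"],
            Sigma_I=np.array(d["hyper"]["Sigma_I"]),
        ),
        design=design,
    )


def write_posterior(result: PosteriorResult, out_dir) -> None:
    """Write a fit to a directory: JSON summary plus per-parameter chain CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "model": result.model,
        "mpsrf": result.mpsrf,
        "converged": result.converged,
        "acceptance": result.acceptance,
        "deviance": result.deviance,
        "metadata": result.metadata,
        "config": dataclasses.asdict(result.config),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    result.summary.to_csv(out / "posterior_summary.csv", float_format=_FLOAT_FMT)
    for key, arr in result.chains.items():
        flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
        pd.DataFrame(flat).to_csv(out / f"chain_{key}.csv", index=False, float_format=_FLOAT_FMT)
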