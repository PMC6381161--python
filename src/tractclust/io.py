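"""Plain-text I/O: TSV tables, square matrices with id headers, connectome
stacks (one TSV per participant), time-series TSVs, and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import CommunityPartition
from .similarity import SimilarityNetwork


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: np.ndarray, ids: list[str], path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_network(path) -> SimilarityNetwork:
    w, ids = read_matrix(path)
    np.fill_diagonal(w, 0.0)
    return SimilarityNetwork(ids=ids, weights=w)


def write_partition(partition: CommunityPartition, path) -> None:
    write_table(partition.to_frame(), path)


def read_partition(path, q: float = float("nan")) -> CommunityPartition:
    df = read_table(path)
    return CommunityPartition(
        ids=[str(i) for i in df["participant_id"]],
        labels=df["module"].to_numpy(dtype=int), q=q,
    )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_connectome_stack(stack: np.ndarray, ids: list[str],
                           roi_names: list[str], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid, mat in zip(ids, stack):
        pd.DataFrame(mat, index=roi_names, columns=roi_names).to_csv(
            out_dir / f"{pid}_connectome.tsv", sep="\t"
        )


def read_connectome_stack(in_dir) -> tuple[np.ndarray, list[str], list[str]]:
    paths = sorted(Path(in_dir).glob("*_connectome.tsv"))
    if not paths:
        raise FileNotFoundError(f"no *_connectome.tsv files in {in_dir}")
    mats = []
    ids = []
    roi_names: list[str] | None = None
    for p in paths:
        df = pd.read_csv(p, sep="\t", index_col=0)
        if roi_names is None:
            roi_names = [str(c) for c in df.columns]
        elif [str(c) for c in df.columns] != roi_names:
            raise ValueError(f"ROI mismatch in {p}")
        mats.append(df.to_numpy())
        ids.append(p.name.replace("_connectome.tsv", ""))
    return np.stack(mats), ids, roi_names


def write_timeseries(timeseries: dict, ids: list[str], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels = timeseries["channels"]
    for pid, mat in zip(ids, timeseries["data"]):
        pd.DataFrame(mat.T, columns=channels).to_csv(
            out_dir / f"{pid}_timeseries.tsv", sep="\t", index=False
        )
    write_json({"tr": timeseries["tr"], "channels": channels},
               out_dir / "timeseries_meta.json")


def read_timeseries(in_dir) -> tuple[dict, list[str]]:
    in_dir = Path(in_dir)
    with open(in_dir / "timeseries_meta.json") as fh:
        meta = json.load(fh)
    paths = sorted(in_dir.glob("*_timeseries.tsv"))
    data = []
    ids = []
    for p in paths:
        df = pd.read_csv(p, sep="\t")
        data.append(df[meta["channels"]].to_numpy().T)
        ids.append(p.name.replace("_timeseries.tsv", ""))
    return {"data": np.stack(data), "tr": meta["tr"],
            "channels": meta["channels"]}, ids
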