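"""File formats: responses, linkage designs, posterior draws, reports.

Responses travel as a long-form CSV (``person_id,item_id,slot,score``) with
the fixed total declared in a ``# total=...`` comment line, which keeps the
format independent of the number of dimensions.  Linkage designs are wide
CSVs with one statement-id column per dimension, matching the layout of the
printed design table of the bundled value test.  Posterior draws serialize
to a directory of per-block CSVs plus a JSON manifest.

Identifiers are opaque strings; indices are 0-based internally and 1-based
in every file and report.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

try:  # py>=3.9
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore

from .core_model import CompositionMatrix, LinkageDesign
from .sampler import MCMCConfig, PosteriorSample

__all__ = [
    "read_responses",
    "write_responses",
    "read_design",
    "write_design",
    "load_value_test_design",
    "read_response_times",
    "save_posterior",
    "load_posterior",
]

_TOTAL_RE = re.compile(r"^#\s*total\s*=\s*([0-9.eE+-]+)\s*$")


def read_responses(path: str | Path) -> CompositionMatrix:
    """Read a long-form response CSV into a composition matrix.

    The file must declare the fixed total in a ``# total=`` comment line,
    carry a header row, and contain exactly D rows (slots 1..D) per
    (person, item) pair whose scores sum to the total within 1e-6 relative.
    Parse errors name the offending line.
    """
    path = Path(path)
    total = None
    with path.open() as fh:
        for line in fh:
            m = _TOTAL_RE.match(line.strip())
            if m:
                total = float(m.group(1))
                break
    if total is None:
        raise ValueError(f"{path}: missing '# total=' declaration")
    df = pd.read_csv(path, comment="#", dtype={"person_id": str, "item_id": str})
    required = {"person_id", "item_id", "slot", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    dup = df.duplicated(["person_id", "item_id", "slot"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (person,item,slot) = "
            f"({row.person_id},{row.item_id},{int(row.slot)}) near line {int(df[dup].index[0]) + 2}"
        )
    slots = sorted(df["slot"].unique())
    D = len(slots)
    if slots != list(range(1, D + 1)):
        raise ValueError(f"{path}: slots must be 1..D, got {slots}")
    persons = list(dict.fromkeys(df["person_id"]))
    items = list(dict.fromkeys(df["item_id"]))
    counts = df.groupby(["person_id", "item_id"], sort=False).size()
    if (counts != D).any():
        pid, iid = counts[counts != D].index[0]
        raise ValueError(f"{path}: person {pid!r}, item {iid!r} has {counts[(pid, iid)]} rows, expected {D}")
    if len(counts) != len(persons) * len(items):
        raise ValueError(f"{path}: not every person answered every item")
    wide = df.pivot_table(
        index="person_id", columns=["item_id", "slot"], values="score", sort=False
    ).reindex(index=persons, columns=pd.MultiIndex.from_product([items, range(1, D + 1)]))
    scores = wide.to_numpy().reshape(len(persons), len(items), D)
    if np.any(scores < 0):
        raise ValueError(f"{path}: negative scores are not allowed")
    sums = scores.sum(axis=2)
    bad = ~np.isclose(sums, total, rtol=0, atol=1e-6 * total)
    if bad.any():
        n, i = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: scores of person {persons[n]!r}, item {items[i]!r} sum to "
            f"{sums[n, i]:g}, expected {total:g}"
        )
    # re-normalize the writing-precision remainder so the container invariant holds
    scores = scores * (total / sums)[:, :, None]
    return CompositionMatrix(scores, total, tuple(persons), tuple(items))


def write_responses(X: CompositionMatrix, path: str | Path) -> None:
    """Write a composition matrix as a long-form CSV (lossless round trip)."""
    path = Path(path)
    N, I, D = X.scores.shape
    df = pd.DataFrame(
        {
            "person_id": np.repeat(list(X.person_ids), I * D),
            "item_id": np.tile(np.repeat(list(X.item_ids), D), N),
            "slot": np.tile(np.arange(1, D + 1), N * I),
            "score": X.scores.ravel(),
        }
    )
    with path.open("w") as fh:
        fh.write(f"# total={X.total:g}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_design(path: str | Path, reference_dim: int = -1) -> LinkageDesign:
    """Read a wide design CSV: ``item_id`` plus one statement column per dimension."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    if "item_id" not in df.columns or df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns item_id plus one column per dimension (D >= 2)")
    dim_names = tuple(c for c in df.columns if c != "item_id")
    seen: dict[str, int] = {}
    statement_ids: list[str] = []
    statement_dim: list[int] = []
    slots = np.empty((len(df), len(dim_names)), dtype=np.intp)
    for d, col in enumerate(dim_names):
        for r, sid in enumerate(df[col].astype(str)):
            if sid not in seen:
                seen[sid] = len(statement_ids)
                statement_ids.append(sid)
                statement_dim.append(d)
            elif statement_dim[seen[sid]] != d:
                raise ValueError(
                    f"{path}: statement {sid!r} appears under two dimensions "
                    f"({dim_names[statement_dim[seen[sid]]]} and {col})"
                )
            slots[r, d] = seen[sid]
    return LinkageDesign(
        item_ids=tuple(df["item_id"].astype(str)),
        dim_names=dim_names,
        slots=slots,
        statement_ids=tuple(statement_ids),
        statement_dim=np.array(statement_dim),
        reference_dim=reference_dim,
    )


def write_design(design: LinkageDesign, path: str | Path) -> None:
    """Write a linkage design as a wide CSV."""
    data = {"item_id": list(design.item_ids)}
    for d, name in enumerate(design.dim_names):
        data[name] = [design.statement_ids[s] for s in design.slots[:, d]]
    pd.DataFrame(data).to_csv(path, index=False)


def load_value_test_design() -> LinkageDesign:
    """The bundled 40-item, 4-dimension, 32-statement value-test design."""
    with resources.as_file(resources.files("limcomp.data") / "value_test_design.csv") as p:
        return read_design(p)


def read_response_times(path: str | Path) -> pd.Series:
    """Read a ``person_id,response_seconds`` companion table."""
    df = pd.read_csv(path, comment="#", dtype={"person_id": str})
    if not {"person_id", "response_seconds"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns person_id,response_seconds")
    return df.set_index("person_id")["response_seconds"].astype(float)


# ---------------------------------------------------------------------------
# posterior serialization
# ---------------------------------------------------------------------------

def _block_frame(arr: np.ndarray, names: list[str]) -> pd.DataFrame:
    chains, n = arr.shape[:2]
    flat = arr.reshape(chains, n, -1)
    recs = {
        "chain": np.repeat(np.arange(1, chains + 1), n * flat.shape[2]),
        "iteration": np.tile(np.repeat(np.arange(1, n + 1), flat.shape[2]), chains),
        "parameter": np.tile(names, chains * n),
        "value": flat.ravel(),
    }
    return pd.DataFrame(recs)


def _scalar_names(block: str, shape: tuple[int, ...], sample: PosteriorSample) -> list[str]:
    design = sample.design
    if block == "sigma2":
        return ["sigma2"]
    if block in ("delta", "slope"):
        return [f"{block}[{sid}]" for sid in design.statement_ids]
    if block == "mu":
        return [f"mu[{k + 1}]" for k in range(shape[0])]
    if block == "cov":
        return [f"cov[{j + 1},{k + 1}]" for j in range(shape[0]) for k in range(shape[1])]
    if block == "pair_location":
        return [f"loc[{design.item_ids[i]},{k + 1}]" for i in range(shape[0]) for k in range(shape[1])]
    if block == "theta":
        return [f"theta[{n + 1},{d + 1}]" for n in range(shape[0]) for d in range(shape[1])]
    raise KeyError(block)


def save_posterior(sample: PosteriorSample, out_dir: str | Path) -> None:
    """Serialize draws to per-block CSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shapes = {}
    for block, arr in sample.draws.items():
        names = _scalar_names(block, arr.shape[2:], sample)
        _block_frame(arr, names).to_csv(out / f"{block}.csv", index=False)
        shapes[block] = list(arr.shape)
    manifest = {
        "model": sample.model,
        "config": {k: v for k, v in vars(sample.config).items()},
        "shapes": shapes,
        "acceptance": sample.acceptance,
        "psr": {k: float(v) for k, v in sample.psr_table.items()},
        "converged": bool(sample.converged),
        "design": {
            "item_ids": list(sample.design.item_ids),
            "dim_names": list(sample.design.dim_names),
            "statement_ids": list(sample.design.statement_ids),
            "statement_dim": sample.design.statement_dim.tolist(),
            "slots": sample.design.slots.tolist(),
            "reference_dim": int(sample.design.reference_dim),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_posterior(in_dir: str | Path) -> PosteriorSample:
    """Reload a serialized posterior sample."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    d = manifest["design"]
    design = LinkageDesign(
        item_ids=tuple(d["item_ids"]),
        dim_names=tuple(d["dim_names"]),
        slots=np.array(d["slots"]),
        statement_ids=tuple(d["statement_ids"]),
        statement_dim=np.array(d["statement_dim"]),
        reference_dim=d["reference_dim"],
    )
    cfg = MCMCConfig(**manifest["config"])
    draws = {}
    for block, shape in manifest["shapes"].items():
        df = pd.read_csv(src / f"{block}.csv")
        draws[block] = df["value"].to_numpy().reshape(shape)
    sample = PosteriorSample(
        model=manifest["model"],
        draws=draws,
        design=design,
        config=cfg,
        acceptance=manifest["acceptance"],
        monitored={},
        psr_table=pd.Series(manifest["psr"], dtype=float),
        converged=manifest["converged"],
    )
    return sample
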