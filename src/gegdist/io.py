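"""File I/O, report rendering and synthetic fixture generation.

Reaction-time samples travel as plain single-column CSV/TSV text (header
optional); an optional ``scale`` divisor supports the common practice of
dividing RTs by a constant (e.g. 100) for numerical stability.  Reports
are written either as round-trippable full-precision JSON or as
human-readable TSV with "estimate (SE)" cells.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geg import GEGParams, EGParams, geg_rvs
from .model import FitResult

__all__ = ["read_samples", "write_report", "format_estimate", "generate_fixture"]

logger = logging.getLogger("gegdist")


def read_samples(path, scale: float = 1.0, column=None) -> np.ndarray:
    """Read one numeric sample from a single-column CSV/TSV file.

    A header row is auto-detected; blank lines are skipped (with a
    logged count); non-numeric rows raise with their line numbers.  All
    values are divided by ``scale``.
    """
    if scale <= 0:
        raise ValueError(f"scale divisor must be > 0, got {scale}")
    path = Path(path)
    raw = path.read_text()
    lines = raw.splitlines()
    if not lines or not raw.strip():
        raise ValueError(f"{path}: empty input file")

    records = []  # (line_number, cells)
    n_blank = 0
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            n_blank += 1
            continue
        sep = "\t" if "\t" in line else ","
        records.append((i, [c.strip() for c in line.split(sep)]))
    if n_blank:
        logger.warning("%s: skipped %d blank line(s)", path, n_blank)

    header = None
    first_cells = records[0][1]
    if not all(_is_number(c) for c in first_cells if c != ""):
        header = first_cells
        records = records[1:]
        if not records:
            raise ValueError(f"{path}: header only, no data rows")

    width = max(len(cells) for _, cells in records)
    if width > 1:
        if column is None:
            raise ValueError(
                f"{path}: {width} columns found; pass a column name/index"
            )
        if isinstance(column, str):
            if header is None or column not in header:
                raise ValueError(f"{path}: no header column named {column!r}")
            idx = header.index(column)
        else:
            idx = int(column)
    else:
        idx = 0

    values, bad = [], []
    for lineno, cells in records:
        cell = cells[idx] if idx < len(cells) else ""
        if _is_number(cell):
            values.append(float(cell))
        else:
            bad.append((lineno, cell))
    if bad:
        shown = ", ".join(f"line {ln}: {c!r}" for ln, c in bad[:5])
        raise ValueError(
            f"{path}: {len(bad)} non-numeric row(s) ({shown}"
            + (", ..." if len(bad) > 5 else "") + ")"
        )
    data = np.asarray(values, dtype=float) / scale
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite values after scaling")
    logger.info("%s: read %d values (scale=%g)", path, data.size, scale)
    return data


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def format_estimate(estimate: float, se: float, digits: int = 3) -> str:
    """Render "estimate (SE)" cells, e.g. ``2.471 (0.078)``."""
    est = f"{estimate:.{digits}f}" if np.isfinite(estimate) else "NA"
    s = f"{se:.{digits}f}" if np.isfinite(se) else "NA"
    return f"{est} ({s})"


def _results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, FitResult):
        results = [results]
    rows = []
    for fr in results:
        row = {"family": fr.family}
        for name, est, se in zip(fr.param_names, fr.estimates, fr.std_errors):
            row[name] = format_estimate(est, se)
        row.update(
            aic=fr.aic, bic=fr.bic, loglik=fr.loglik,
            n=fr.n, converged=fr.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(results, path, fmt: str = "json") -> Path:
    """Write fit/simulation/shape results to ``path``.

    ``fmt="json"`` keeps full float precision and round-trips;
    ``fmt="tsv"`` renders a human table ("estimate (SE)" for fits).
    Accepts FitResult, a list of FitResult, a DataFrame, or any
    JSON-serializable mapping.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = _to_jsonable(results)
        path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    elif fmt == "tsv":
        frame = (
            _results_frame(results)
            if isinstance(results, (FitResult, list, pd.DataFrame))
            else pd.DataFrame(_to_jsonable(results))
        )
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"format must be 'json' or 'tsv', got {fmt!r}")
    return path


def _to_jsonable(obj):
    if isinstance(obj, FitResult):
        return obj.as_dict()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# Default fixture parameters: a strongly right-skewed GEG on the
# divided-by-100 RT scale typical of behavioural data.
_FIXTURE_GEG = GEGParams(0.835, 2.471, 0.253, 0.486)


def generate_fixture(kind: str, params=None, n: int = 1000, seed: int = 0, path=None):
    """Write (or return) a reproducible synthetic RT-like sample.

    ``kind``:

    * ``"geg"``     -- GEG draws (default: a strongly right-skewed,
      ADHD-fit-scale parameter set),
    * ``"eg"``      -- EG draws,
    * ``"normal"``  -- Gaussian draws,
    * ``"two-group"`` -- a two-column table (rt, group) with a location
      shift between groups, for regression exercises.

    Returns the DataFrame; if ``path`` is given the same table is also
    written as CSV (byte-identical for identical seeds).
    """
    rng = np.random.default_rng(seed)
    if kind == "geg":
        p = GEGParams(*params) if params is not None else _FIXTURE_GEG
        frame = pd.DataFrame({"rt": np.round(geg_rvs(n, p, seed=rng), 10)})
    elif kind == "eg":
        if params is None:
            params = (0.996, 2.109, 0.264)
        p = EGParams(*params)
        frame = pd.DataFrame(
            {"rt": np.round(geg_rvs(n, GEGParams(p.tau, p.mu, p.sigma, 1.0), seed=rng), 10)}
        )
    elif kind == "normal":
        mu, sigma = params if params is not None else (3.0, 1.0)
        frame = pd.DataFrame({"rt": np.round(rng.normal(mu, sigma, n), 10)})
    elif kind == "two-group":
        p = GEGParams(*params) if params is not None else _FIXTURE_GEG
        shift = 0.5
        group = rng.integers(0, 2, n)
        base = np.asarray(geg_rvs(n, p, seed=rng))
        frame = pd.DataFrame(
            {
                "rt": np.round(base + shift * group, 10),
                "group": np.where(group == 1, "b", "a"),
            }
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False)
    return frame
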