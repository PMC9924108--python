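"""Expected-vs-actual delivery parameter checking.

Machine trajectory logs record, for every ~20 ms sample, the parameter
values the control system expected (from the plan) and the values the
machine actually reached.  Given such paired series in tabular form,
this module computes the percent error per sample,

    %error = (actual - expected) / expected * 100,

and reports the maximum absolute error per parameter (optionally per
treatment site).  Samples with expected exactly zero are flagged as
undefined — the ratio has no meaning there — and excluded from the
maxima rather than silently zeroed.  Angles (gantry, collimator) are
compared on the unwrapped scale so 359.9 vs 0.1 deg is a 0.2 deg
discrepancy, not a 359.8 deg one.

Parsing of binary vendor log files is out of scope; the input is a
plain table with columns ``parameter, expected, actual`` and an
optional ``site``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ANGLE_PARAMETERS",
    "ParameterSeries",
    "percent_error",
    "compare_delivery",
]

#: Parameters compared on the unwrapped (mod-360) angular scale.
ANGLE_PARAMETERS = frozenset({"gantry", "collimator"})


@dataclass(frozen=True)
class ParameterSeries:
    """Paired expected/actual samples of one delivery parameter."""

    parameter: str
    expected: np.ndarray
    actual: np.ndarray
    units: str = ""
    site: str | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.expected, dtype=float)
        a = np.asarray(self.actual, dtype=float)
        if e.shape != a.shape or e.ndim != 1 or e.size < 1:
            raise ValueError("expected and actual must be equal-length 1-D series")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(a))):
            raise ValueError("series values must be finite")
        object.__setattr__(self, "expected", e)
        object.__setattr__(self, "actual", a)


def _unwrap_actual(actual: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Shift each actual angle to the representative nearest its expected value."""
    return expected + (np.mod(actual - expected + 180.0, 360.0) - 180.0)


def percent_error(actual, expected, *, angular: bool = False) -> np.ndarray:
    """Per-sample percent error; NaN where expected is exactly zero."""
    a = np.asarray(actual, dtype=float)
    e = np.asarray(expected, dtype=float)
    if angular:
        a = _unwrap_actual(a, e)
    out = np.full(np.broadcast(a, e).shape, np.nan)
    ok = e != 0
    out[ok] = (a[ok] - e[ok]) / e[ok] * 100.0
    return out


def compare_delivery(series_set: list[ParameterSeries] | pd.DataFrame) -> pd.DataFrame:
    """Maximum absolute percent error per parameter (and site, if given).

    Accepts a list of :class:`ParameterSeries` or a long-format frame
    with columns ``parameter, expected, actual`` and optional ``site``.
    The report carries, per group: ``max_abs_percent_error``, the row
    index achieving it (for audit), the sample count and the count of
    undefined (expected = 0) samples.
    """
    if isinstance(series_set, pd.DataFrame):
        df = series_set.copy()
        required = {"parameter", "expected", "actual"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
    else:
        frames = []
        for s in series_set:
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": s.parameter,
                        "expected": s.expected,
                        "actual": s.actual,
                        "site": s.site,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
    has_site = "site" in df.columns and df["site"].notna().any()
    keys = ["site", "parameter"] if has_site else ["parameter"]

    rows = []
    for key, g in df.groupby(keys, dropna=False):
        param = key[-1] if isinstance(key, tuple) else key
        err = percent_error(
            g["actual"].to_numpy(dtype=float),
            g["expected"].to_numpy(dtype=float),
            angular=str(param).lower() in ANGLE_PARAMETERS,
        )
        defined = ~np.isnan(err)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        if defined.any():
            j = int(np.nanargmax(np.abs(err)))
            row.update(
                max_abs_percent_error=float(np.abs(err[defined]).max()),
                argmax_index=int(g.index[j]),
            )
        else:
            row.update(max_abs_percent_error=np.nan, argmax_index=-1)
        row.update(n_samples=int(len(g)), n_undefined=int((~defined).sum()))
        rows.append(row)
    return pd.DataFrame(rows)
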