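"""Long-format CSV input/output and per-cohort variance aggregation.

The interchange format is a long table with columns ``cohort``, ``time``,
``size`` and optionally ``individual`` (required only by the
repeated-measures comparator). Times may be in any units; they are
rescaled per cohort to [0, 1] before fitting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import VarianceTrajectory
from .simulate import CohortSizes

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "cohort_to_long",
    "variances_from_table",
    "read_config",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cohort", "time", "size")


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format measurement table.

    Comma-separated, dot decimal, UTF-8, header row required. ``time``
    and ``size`` must parse as numbers; rows that do not are rejected
    with their line numbers.
    """
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad_lines = []
    for col in ("time", "size"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        # +2: header line and 1-based numbering
        bad_lines.extend((int(i) + 2, col) for i in bad)
        df[col] = coerced
    if bad_lines:
        msgs = ", ".join(f"line {ln} ({col})" for ln, col in sorted(bad_lines))
        raise ValueError(f"non-numeric values: {msgs}")
    if df[["time", "size"]].isna().any().any():
        raise ValueError("time and size must not contain missing values")
    if "individual" in df.columns:
        dup = df.duplicated(subset=["cohort", "individual", "time"])
        if dup.any():
            raise ValueError(
                f"duplicate (cohort, individual, time) rows at lines "
                f"{[int(i) + 2 for i in df.index[dup]]}"
            )
    return df


def write_long_csv(df: pd.DataFrame, path) -> None:
    """Write a long table as comma-separated UTF-8 with 12 significant
    digits (round-tripping values through read_long_csv)."""
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def cohort_to_long(cohort: CohortSizes, cohort_label="cohort") -> pd.DataFrame:
    """Flatten a CohortSizes to long format, omitting unmeasured rows."""
    rows, cols = np.where(cohort.alive)
    return pd.DataFrame(
        {
            "cohort": cohort_label,
            "individual": cohort.individual_ids[rows],
            "time": cohort.times[cols],
            "size": cohort.sizes[rows, cols],
        }
    )


def variances_from_table(
    table: pd.DataFrame,
) -> dict[str, VarianceTrajectory]:
    """Occasion-wise sample variances per cohort, times rescaled to [0, 1].

    Uses the unbiased (n-1 denominator) sample variance. Cohorts with
    fewer than 3 distinct times, or with any occasion carrying fewer than
    2 measurements, are skipped with a logged reason rather than
    poisoning the whole run.
    """
    out: dict[str, VarianceTrajectory] = {}
    for label, grp in table.groupby("cohort", sort=True):
        agg = grp.groupby("time")["size"].agg(["var", "count"]).reset_index()
        if len(agg) < 3:
            logger.warning("cohort %r skipped: fewer than 3 occasions", label)
            continue
        if (agg["count"] < 2).any():
            logger.warning(
                "cohort %r skipped: an occasion has fewer than 2 measurements",
                label,
            )
            continue
        t = agg["time"].to_numpy(dtype=float)
        t = (t - t[0]) / (t[-1] - t[0])
        out[str(label)] = VarianceTrajectory(
            t, agg["var"].to_numpy(dtype=float), agg["count"].to_numpy(dtype=int)
        )
    return out


def read_config(path) -> dict[str, str]:
    """Flat key=value plain-text config; '#' starts a comment line."""
    cfg: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            cfg[key.strip()] = value.strip()
    return cfg
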