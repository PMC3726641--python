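"""End-point binding free-energy bookkeeping.

The entropy column is stored as the penalty -TdS (positive for binding),
so the combination is plain addition: dG = dH + (-TdS). Component
uncertainties are treated as independent and propagated in quadrature.
Rounding to one decimal happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import UsageError
from .model_io import Trajectory


@dataclass
class EnergySamples:
    """Per-snapshot binding-enthalpy and entropy-penalty samples, kcal/mol."""

    model: str
    dH: np.ndarray
    mTdS: np.ndarray

    def __post_init__(self) -> None:
        self.dH = np.asarray(self.dH, dtype=float)
        self.mTdS = np.asarray(self.mTdS, dtype=float)
        if self.dH.size < 2 or self.mTdS.size < 2:
            raise UsageError("need >= 2 samples per component for an sd")


def select_snapshots(times: np.ndarray | Trajectory,
                     interval: float = 10.0,
                     entropy_subsample: int = 20,
                     window: tuple[float | None, float | None] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Snapshot index sets for enthalpy and entropy estimation.

    The enthalpy set holds frames whose times are multiples of
    ``interval`` ps inside the half-open window (start, end]; the entropy
    set is ``entropy_subsample`` evenly spaced members of the enthalpy
    set, first and last included.
    """
    if isinstance(times, Trajectory):
        times = times.times
    times = np.asarray(times, dtype=float)
    start, end = window if window is not None else (None, None)
    mask = np.ones(times.shape, dtype=bool)
    if start is not None:
        mask &= times > start
    if end is not None:
        mask &= times <= end
    on_grid = np.isclose(np.mod(times, interval), 0.0) | \
        np.isclose(np.mod(times, interval), interval)
    enthalpy = np.flatnonzero(mask & on_grid)
    if enthalpy.size == 0:
        raise UsageError("analysis window shorter than the snapshot interval")
    if enthalpy.size < entropy_subsample:
        raise UsageError(
            f"entropy subsample needs {entropy_subsample} snapshots, "
            f"only {enthalpy.size} available")
    picks = np.round(np.linspace(0, enthalpy.size - 1, entropy_subsample)).astype(int)
    entropy = enthalpy[picks]
    return enthalpy, entropy


def combine_components(dh_mean: float, dh_sd: float,
                       mtds_mean: float, mtds_sd: float) -> tuple[float, float]:
    """dG mean and quadrature sd from component means and sds."""
    return dh_mean + mtds_mean, math.sqrt(dh_sd ** 2 + mtds_sd ** 2)


def combine_free_energy(samples: EnergySamples) -> tuple[float, float]:
    """dG mean and sd from per-snapshot component samples.

    mean dG = mean dH + mean(-TdS); sd is the quadrature of the two
    component sample sds (components treated as independent).
    """
    dh_m, dh_s = float(samples.dH.mean()), float(samples.dH.std(ddof=1))
    mt_m, mt_s = float(samples.mTdS.mean()), float(samples.mTdS.std(ddof=1))
    return combine_components(dh_m, dh_s, mt_m, mt_s)


def relative_free_energy(table: pd.DataFrame, reference: str,
                         block: str | None = None) -> pd.DataFrame:
    """Add a ddG column: dG - dG(reference row), per block.

    ``table`` needs columns ``model`` and ``dG`` (and ``block`` when
    blocks are used). The reference row's ddG is exactly 0.0.
    """
    out = table.copy()
    if block is not None:
        out = out[out["block"] == block].copy()
    ref_rows = out.index[out["model"] == reference]
    if len(ref_rows) == 0:
        raise UsageError(f"reference model {reference!r} not found")
    ref_dg = float(out.loc[ref_rows[0], "dG"])
    out["ddG"] = out["dG"] - ref_dg
    return out


def aggregate_components(samples: pd.DataFrame,
                         reference: str | dict[str, str] | None = None
                         ) -> pd.DataFrame:
    """Full energy table from a per-snapshot component table.

    Input columns: model, snapshot, dH, mTdS, optional replica and block.
    Replica rows are kept separate. ddG is computed per block against the
    block's reference model when ``reference`` is given (a single label,
    or a block -> label mapping).
    """
    required = {"model", "snapshot", "dH", "mTdS"}
    missing = required - set(samples.columns)
    if missing:
        raise UsageError(f"samples table missing columns: {sorted(missing)}")
    bad = samples[samples[["dH", "mTdS"]].isna().any(axis=1)]
    if len(bad):
        raise UsageError(f"non-numeric component values at rows {list(bad.index)}")

    df = samples.copy()
    if "replica" not in df.columns:
        df["replica"] = 0
    if "block" not in df.columns:
        df["block"] = "all"

    rows = []
    for (block, model, replica), grp in df.groupby(["block", "model", "replica"],
                                                   sort=False):
        dh_m = float(grp["dH"].mean())
        dh_s = float(grp["dH"].std(ddof=1))
        mt_m = float(grp["mTdS"].mean())
        mt_s = float(grp["mTdS"].std(ddof=1))
        dg, dg_s = combine_components(dh_m, dh_s, mt_m, mt_s)
        rows.append(dict(block=block, model=model, replica=replica,
                         dH=dh_m, dH_sd=dh_s, mTdS=mt_m, mTdS_sd=mt_s,
                         dG=dg, dG_sd=dg_s))
    table = pd.DataFrame(rows)

    if reference is not None:
        refs = ({b: reference for b in table["block"].unique()}
                if isinstance(reference, str) else reference)
        parts = []
        for b, grp in table.groupby("block", sort=False):
            ref_label = refs.get(b)
            if ref_label is None:
                grp = grp.copy()
                grp["ddG"] = np.nan
            else:
                grp = relative_free_energy(grp, ref_label)
            parts.append(grp)
        table = pd.concat(parts, ignore_index=True)
    return table


def present(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation rounding; all arithmetic upstream is full precision."""
    out = table.copy()
    for col in ("dH", "dH_sd", "mTdS", "mTdS_sd", "dG", "dG_sd", "ddG"):
        if col in out.columns:
            out[col] = out[col].round(decimals)
    return out
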