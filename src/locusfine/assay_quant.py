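"""Quantification of the functional assays: receptor internalization from
flow-cytometry gMFI, comparative-CT relative expression, and a cell-line
level permutation comparison of internalization time courses.

Percent internalization compares the surface signal kept on ice (4 deg C,
no internalization) with the signal after incubation at 37 deg C:
((gMFI_4C - gMFI_37C) / gMFI_4C) x 100.  Relative qPCR expression uses the
comparative CT method: target Ct normalized to the 18S reference in the
same well (dCt), re-normalized to a calibrator sample (ddCt), and
exponentially transformed to fold change 2^(-ddCt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def percent_internalization(gmfi_4c, gmfi_37c):
    """Percent of surface receptor internalized, from gMFI measurements.

    May be negative if the surface signal rose; the value is reported, not
    clamped.  Scale-invariant: multiplying both gMFIs by a constant leaves
    it unchanged.
    """
    g4 = np.asarray(gmfi_4c, dtype=float)
    g37 = np.asarray(gmfi_37c, dtype=float)
    if np.any(g4 <= 0):
        raise ValueError("the no-internalization (4C) gMFI must be positive")
    out = (g4 - g37) / g4 * 100.0
    return float(out) if out.ndim == 0 else out


def add_percent_column(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["percent_internalization"] = percent_internalization(
        out["gmfi_4c"].to_numpy(), out["gmfi_37c"].to_numpy()
    )
    return out


def ddct_relative_expression(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Fold changes by the comparative CT method.

    ``records`` columns: sample, target_ct, reference_ct (one row per
    well; replicate wells of a sample are averaged on the Ct scale before
    the ddCt step).  The calibrator sample's fold change is exactly 1.
    """
    required = {"sample", "target_ct", "reference_ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if records[["target_ct", "reference_ct"]].isna().any().any():
        raise ValueError("missing Ct values")
    per_sample = (
        records.groupby("sample", sort=False)[["target_ct", "reference_ct"]].mean()
    )
    if calibrator not in per_sample.index:
        raise ValueError(f"calibrator sample {calibrator!r} not present")
    dct = per_sample["target_ct"] - per_sample["reference_ct"]
    ddct = dct - dct.loc[calibrator]
    fold = np.power(2.0, -ddct)
    out = per_sample.reset_index()
    out["delta_ct"] = dct.to_numpy()
    out["delta_delta_ct"] = ddct.to_numpy()
    out["fold_change"] = fold.to_numpy()
    return out


def group_compare_timecourse(
    table: pd.DataFrame, n_perms: int = 10_000, seed: int = 0
) -> dict:
    """Permutation comparison of internalization between genotype groups.

    Group labels are permuted at the cell-line level, so repeated measures
    within a line stay together.  The statistic is the difference of group
    mean percent internalization (group listed first minus second),
    overall and per timepoint.  Returns one- and two-sided overall p's and
    a per-timepoint table.
    """
    df = add_percent_column(table) if "percent_internalization" not in table.columns else table.copy()
    lines = df.groupby(["cell_line", "genotype_group"], sort=False).size().reset_index()
    groups = sorted(lines["genotype_group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two genotype groups are required")
    g1, g2 = groups
    line_group = dict(zip(lines["cell_line"], lines["genotype_group"]))
    per_line = (
        df.groupby(["cell_line", "timepoint"], sort=False)["percent_internalization"]
        .mean()
        .unstack("timepoint")
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    line_ids = per_line.index.to_numpy()
    labels = np.array([line_group[l] for l in line_ids])
    n1 = int((labels == g1).sum())
    if n1 < 3 or (len(labels) - n1) < 3:
        raise ValueError("need at least 3 cell lines per group")
    mat = per_line.to_numpy()  # (lines, timepoints)

    def stat(lab):
        return mat[lab == g1].mean(axis=0) - mat[lab != g1].mean(axis=0)

    obs_t = stat(labels)
    obs = float(obs_t.mean())

    rng = np.random.default_rng(seed)
    perm_overall = np.empty(n_perms)
    perm_t = np.empty((n_perms, mat.shape[1]))
    for b in range(n_perms):
        perm = labels[rng.permutation(len(labels))]
        s = stat(perm)
        perm_t[b] = s
        perm_overall[b] = s.mean()
    p_one = (np.sum(perm_overall >= obs - 1e-12) + 1) / (n_perms + 1)
    p_two = (np.sum(np.abs(perm_overall) >= abs(obs) - 1e-12) + 1) / (n_perms + 1)
    p_per_t = (np.sum(np.abs(perm_t) >= np.abs(obs_t)[None, :] - 1e-12, axis=0) + 1) / (
        n_perms + 1
    )
    return {
        "group_order": (str(g1), str(g2)),
        "statistic_overall": obs,
        "p_one_sided": float(p_one),
        "p_two_sided": float(p_two),
        "per_timepoint": pd.DataFrame(
            {
                "timepoint": per_line.columns.to_numpy(),
                "difference": obs_t,
                "p_two_sided": p_per_t,
            }
        ),
        "n_perms": n_perms,
    }
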