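"""Mismatch computation and the factorial statistical analysis.

The unit of analysis is the *mismatch*: headphone minus loudspeaker sound
pressure level at the eardrum at equal loudness, one value per subject and
condition (room x stimulus x headphone presentation mode).  The analyses
mirror the study design:

* per-condition one-sample t-tests against zero with Bonferroni correction
  for the 64 conditions of the full factorial;
* a three-way fixed-effects ANOVA (Room x Stimulus x Mode) with all
  two-way interactions and the three-way interaction, Type II sums of
  squares, subjects pooled as replicates;
* post-hoc contrasts of the room marginal means (6 pairs, Bonferroni);
* pairwise presentation-mode t-tests within each room x stimulus cell;
* Pearson correlations of individual mismatches between diotic and
  room-matched presentation;
* apparent-source-width (ASW) summaries on the -50..50 rating scale.

All functions consume/produce tidy :class:`pandas.DataFrame` tables.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONDITION_FACTORS = ("room", "stimulus", "mode")


def bonferroni(p: float | np.ndarray, n_comparisons: int) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    return np.minimum(np.asarray(p, dtype=float) * n_comparisons, 1.0)


def compute_mismatch(results: pd.DataFrame, ear_convention: str = "left") -> pd.DataFrame:
    """Per-row mismatch (dB): headphone minus loudspeaker eardrum level.

    ``ear_convention`` selects how binaural rows combine the two ears:
    ``"left"`` (the stimuli are referenced to the left ear) uses left-ear
    levels for both sources; ``"per_ear_mean"`` averages the per-ear
    differences.  Monaural rows always use the presented (left) ear.  Rows
    missing a counterpart level are excluded with a log entry.
    """
    if ear_convention not in ("left", "per_ear_mean"):
        raise ValueError(f"unknown ear convention {ear_convention!r}")
    df = results.copy()
    left_diff = df["hp_level_eardrum_left"] - df["ls_level_eardrum_left"]
    if ear_convention == "left":
        mismatch = left_diff
    else:
        right_diff = df["hp_level_eardrum_right"] - df["ls_level_eardrum_right"]
        mismatch = np.where(df["mode"] == "monaural", left_diff, (left_diff + right_diff) / 2)
    df["mismatch"] = mismatch
    bad = ~np.isfinite(df["mismatch"])
    if bad.any():
        logger.warning("excluding %d rows with missing levels", int(bad.sum()))
        df = df[~bad]
    keep = ["subject", "site", *CONDITION_FACTORS, "mismatch"]
    extra = [c for c in ("converged",) if c in df.columns]
    return df[keep + extra].reset_index(drop=True)


def condition_tests(mismatch: pd.DataFrame, n_comparisons: int = 64) -> pd.DataFrame:
    """One-sample t-test of the mismatch against zero per condition.

    Two-sided, Bonferroni-corrected for ``n_comparisons`` (64 in the full
    factorial); singleton conditions are flagged and left untested.
    """
    rows = []
    for key, group in mismatch.groupby(list(CONDITION_FACTORS), sort=True):
        x = group["mismatch"].to_numpy()
        if x.size < 2:
            logger.warning("condition %s has fewer than 2 subjects; no test", key)
            rows.append((*key, x.size, float(np.mean(x)) if x.size else np.nan,
                         np.nan, np.nan, np.nan, False))
            continue
        t, p = stats.ttest_1samp(x, 0.0)
        p_adj = float(bonferroni(p, n_comparisons))
        rows.append((*key, x.size, float(np.mean(x)), float(t), float(p), p_adj, p_adj < 0.05))
    return pd.DataFrame(
        rows,
        columns=[*CONDITION_FACTORS, "n", "mean", "t", "p", "p_adjusted", "significant"],
    )


def three_way_anova(mismatch: pd.DataFrame) -> pd.DataFrame:
    """Three-way fixed-effects ANOVA of the mismatch (Type II sums of squares).

    Factors Room, Stimulus and Headphone Presentation Mode with all two-way
    interactions and the three-way interaction; repeated measures are
    pooled as replicates.  Empty design cells are rejected with a report.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    counts = mismatch.groupby(list(CONDITION_FACTORS), sort=True).size()
    full = np.prod([mismatch[f].nunique() for f in CONDITION_FACTORS])
    if len(counts) < full:
        present = set(counts.index)
        cells = itertools.product(
            *(sorted(mismatch[f].unique()) for f in CONDITION_FACTORS)
        )
        empty = [c for c in cells if c not in present]
        raise ValueError(f"empty design cells: {empty}")
    model = ols("mismatch ~ C(room) * C(stimulus) * C(mode)", data=mismatch).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = int(table.loc["Residual", "df"])
    out = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = (
            term.replace("C(room)", "room")
            .replace("C(stimulus)", "stimulus")
            .replace("C(mode)", "mode")
            .replace(":", " x ")
        )
        out.append((name, int(row["df"]), df_den, float(row["F"]), float(row["PR(>F)"])))
    return pd.DataFrame(out, columns=["term", "df_num", "df_den", "F", "p"])


def room_marginal_mismatch(mismatch: pd.DataFrame) -> pd.DataFrame:
    """Per-subject marginal mean mismatch per room (over stimuli and modes)."""
    return (
        mismatch.groupby(["room", "subject"], sort=True)["mismatch"]
        .mean()
        .reset_index()
    )


def room_marginal_contrasts(mismatch: pd.DataFrame) -> pd.DataFrame:
    """All pairwise contrasts of the room marginal distributions.

    Subjects' room-marginal means are compared between rooms with Welch
    two-sample t-tests; p-values are Bonferroni-corrected for the number
    of pairs (6 for four rooms).  Missing rooms reduce the family (logged).
    """
    marginals = room_marginal_mismatch(mismatch)
    rooms = sorted(marginals["room"].unique())
    if len(rooms) < 2:
        raise ValueError("room contrasts need at least two rooms with data")
    pairs = list(itertools.combinations(rooms, 2))
    if len(rooms) < 4:
        logger.warning("only %d rooms present; %d contrasts computed", len(rooms), len(pairs))
    rows = []
    for a, b in pairs:
        xa = marginals.loc[marginals["room"] == a, "mismatch"].to_numpy()
        xb = marginals.loc[marginals["room"] == b, "mismatch"].to_numpy()
        delta = float(np.mean(xa) - np.mean(xb))
        se = float(np.sqrt(np.var(xa, ddof=1) / xa.size + np.var(xb, ddof=1) / xb.size))
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        p_adj = float(bonferroni(p, len(pairs)))
        rows.append((f"{a} - {b}", a, b, delta, se, float(t), float(p), p_adj, p_adj < 0.05))
    return pd.DataFrame(
        rows,
        columns=["pair", "room_a", "room_b", "delta", "se", "t", "p", "p_adjusted", "significant"],
    )


def mode_pairwise_tests(
    mismatch: pd.DataFrame, modes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Paired t-tests between presentation modes within each room x stimulus cell.

    The Bonferroni family is the set of mode pairs within one cell
    (``family_size`` column); the total number of comparisons performed is
    reported in ``n_comparisons_total`` on every row for bookkeeping.
    """
    if modes is None:
        modes = sorted(mismatch["mode"].unique())
    modes = list(modes)
    pairs = list(itertools.combinations(modes, 2))
    rows = []
    for (room, stim), cell in mismatch.groupby(["room", "stimulus"], sort=True):
        wide = cell.pivot_table(index="subject", columns="mode", values="mismatch")
        for a, b in pairs:
            if a not in wide.columns or b not in wide.columns:
                logger.warning("cell (%s, %s) lacks mode %s or %s", room, stim, a, b)
                continue
            paired = wide[[a, b]].dropna()
            if len(paired) < 2:
                continue
            diff = paired[a] - paired[b]
            t, p = stats.ttest_rel(paired[a], paired[b])
            p_adj = float(bonferroni(p, len(pairs)))
            rows.append(
                (room, stim, a, b, float(diff.mean()),
                 float(diff.std(ddof=1) / np.sqrt(len(diff))),
                 float(t), float(p), p_adj, len(pairs), p_adj < 0.05)
            )
    out = pd.DataFrame(
        rows,
        columns=["room", "stimulus", "mode_a", "mode_b", "delta", "se", "t", "p",
                 "p_adjusted", "family_size", "significant"],
    )
    out["n_comparisons_total"] = len(out)
    return out


def diotic_vs_matched_correlation(mismatch: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between subjects' diotic and room-matched mismatches.

    Computed per room x stimulus; cells with fewer than three paired
    observations carry no test.
    """
    rows = []
    for (room, stim), cell in mismatch.groupby(["room", "stimulus"], sort=True):
        wide = cell.pivot_table(index="subject", columns="mode", values="mismatch")
        if "diotic" not in wide.columns or "ic_matched" not in wide.columns:
            raise ValueError(f"cell ({room}, {stim}) lacks diotic or ic_matched data")
        paired = wide[["diotic", "ic_matched"]].dropna()
        if len(paired) < 3:
            rows.append((room, stim, len(paired), np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(paired["ic_matched"], paired["diotic"])
        rows.append((room, stim, len(paired), float(r), float(p), p < 0.05))
    return pd.DataFrame(rows, columns=["room", "stimulus", "n", "r", "p", "significant"])


def asw_summary(
    asw: pd.DataFrame, mismatch: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Apparent-source-width condition means/SDs and ASW-mismatch correlation.

    Ratings must lie on the -50..50 scale; out-of-scale rows are rejected
    with a log entry.  When a mismatch table is supplied, the Pearson
    correlation between individual ratings and mismatches is computed per
    condition.
    """
    bad = (asw["rating"] < -50) | (asw["rating"] > 50) | ~np.isfinite(asw["rating"])
    if bad.any():
        logger.warning("rejecting %d out-of-scale ASW ratings", int(bad.sum()))
        asw = asw[~bad]
    summary = (
        asw.groupby(list(CONDITION_FACTORS), sort=True)["rating"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    if mismatch is None:
        return summary, None
    merged = asw.merge(mismatch, on=["subject", *CONDITION_FACTORS], how="inner")
    rows = []
    for key, cell in merged.groupby(list(CONDITION_FACTORS), sort=True):
        if len(cell) < 3:
            rows.append((*key, len(cell), np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(cell["rating"], cell["mismatch"])
        rows.append((*key, len(cell), float(r), float(p), p < 0.05))
    corr = pd.DataFrame(rows, columns=[*CONDITION_FACTORS, "n", "r", "p", "significant"])
    return summary, corr
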