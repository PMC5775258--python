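"""Lickometer aversion analysis.

Water-deprived mice lick a spout for 1 h; aversion to an agonist dissolved
in the water is quantified as licking under the agonist expressed as a
percent of each animal's baseline (water-only) licking.  Values above 100
are meaningful (less aversion than baseline).  Normalization is per animal
before averaging within genotype.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caimaging import group_compare

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "load_sessions",
    "percent_of_baseline",
    "dose_response_table",
]

#: Agonist concentration grid (uM) used by default.
DEFAULT_CONCENTRATIONS = (1.0, 10.0, 100.0, 1000.0)

BASELINE_CONDITION = "water"

_REQUIRED = {"animal_id", "genotype", "condition", "session", "licks"}


def load_sessions(path: str | Path) -> pd.DataFrame:
    """Load a sessions CSV (animal_id, genotype, condition, session, licks).

    ``condition`` is 'water' for baseline sessions or a concentration in uM.
    """
    df = pd.read_csv(path)
    if not _REQUIRED <= set(df.columns):
        raise ValueError(f"sessions file needs columns {sorted(_REQUIRED)}")
    if (df["licks"] < 0).any():
        raise ValueError("negative lick counts")
    return df


def _is_baseline(condition: pd.Series) -> pd.Series:
    return condition.astype(str).str.lower().eq(BASELINE_CONDITION)


def percent_of_baseline(
    sessions: pd.DataFrame, animal: str, concentration: float, last_k: int | None = None
) -> float:
    """Licks at a concentration as a percent of the animal's water baseline.

    100 x mean(agonist-session licks) / mean(baseline-session licks).  The
    baseline is the mean over all water sessions, or the last ``last_k`` of
    them if given.  Scale-invariant: doubling every count leaves it
    unchanged.
    """
    mine = sessions[sessions["animal_id"] == animal]
    base = mine.loc[_is_baseline(mine["condition"]), "licks"]
    if last_k is not None:
        base = base.tail(last_k)
    test = mine.loc[
        pd.to_numeric(mine["condition"], errors="coerce") == float(concentration),
        "licks",
    ]
    if base.empty:
        raise ValueError(f"animal {animal}: no baseline (water) sessions")
    if test.empty:
        raise ValueError(f"animal {animal}: no sessions at {concentration} uM")
    baseline_mean = base.mean()
    if baseline_mean == 0:
        raise ValueError(f"animal {animal}: zero baseline lick mean")
    return float(100.0 * test.mean() / baseline_mean)


def dose_response_table(
    sessions: pd.DataFrame,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    last_k: int | None = None,
) -> pd.DataFrame:
    """Per-genotype, per-concentration mean +/- SEM of %baseline licking.

    The animal is the unit: each animal contributes one %baseline value per
    concentration.  With exactly two genotypes an unpaired t-test compares
    them at each concentration; with more, a one-way ANOVA on the first two
    is not meaningful so all groups are compared pairwise against the first
    (reference) genotype.  With a single genotype the test columns are NaN
    and a notice is attached in ``table.attrs['note']``.
    """
    genotypes = sorted(sessions["genotype"].unique())
    rows = []
    for conc in concentrations:
        per_geno: dict[str, list[float]] = {}
        for geno in genotypes:
            animals = sessions.loc[sessions["genotype"] == geno, "animal_id"].unique()
            vals = []
            for animal in animals:
                try:
                    vals.append(
                        percent_of_baseline(sessions, animal, conc, last_k=last_k)
                    )
                except ValueError:
                    continue  # animal untested at this concentration
            per_geno[geno] = vals
        for geno in genotypes:
            vals = per_geno[geno]
            row = {
                "genotype": geno,
                "concentration_uM": conc,
                "n_animals": len(vals),
                "mean_pct_baseline": float(np.mean(vals)) if vals else np.nan,
                "sem_pct_baseline": float(stats.sem(vals)) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
            }
            ref = per_geno[genotypes[0]]
            if geno != genotypes[0] and len(vals) >= 2 and len(ref) >= 2:
                t, p = group_compare(ref, vals, test="unpaired_t")
                row["t_vs_reference"] = t
                row["p_vs_reference"] = p
            else:
                row["t_vs_reference"] = np.nan
                row["p_vs_reference"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(genotypes) < 2:
        table.attrs["note"] = "single genotype: group tests skipped"
    return table
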