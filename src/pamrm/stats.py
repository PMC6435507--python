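"""Per-species two-group comparisons and restoration/elevation calls.

"Restored to wild type" is operationalized as *failure to reject* the null
of equal means between the reconstituted and wild-type groups at the chosen
alpha — an absence-of-evidence criterion that is the implicit rule behind
rescue-experiment species counts.  The alpha, the equal-variance assumption
and an optional Bonferroni correction are all exposed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["compare_species", "call_restoration"]

logger = logging.getLogger(__name__)

VALUE_COLUMN = "amount_per_phosphate"


def compare_species(
    quant: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_column: str = VALUE_COLUMN,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Unpaired two-tailed t test per species between two groups.

    Student's (equal-variance) t by default; set ``equal_var=False`` for
    Welch.  No multiple-testing correction is applied here.  Species with
    fewer than two replicates in either group are skipped with a log entry.

    Returns columns: species, group_a, group_b, mean_a, mean_b, n_a, n_b,
    t_statistic, p_value.
    """
    for column in ("species", "group", value_column):
        if column not in quant.columns:
            raise ValueError(f"quant table lacks column {column!r}")
    rows = []
    for species, sub in quant.groupby("species", sort=True):
        values_a = sub.loc[sub["group"] == group_a, value_column].to_numpy(float)
        values_b = sub.loc[sub["group"] == group_b, value_column].to_numpy(float)
        if len(values_a) < 2 or len(values_b) < 2:
            logger.warning(
                "skipping %s: %d vs %d replicates (need >= 2 per group)",
                species, len(values_a), len(values_b),
            )
            continue
        if np.ptp(np.concatenate([values_a, values_b])) == 0.0:
            # all values identical in both groups: no evidence of difference
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = sps.ttest_ind(values_a, values_b,
                                            equal_var=equal_var)
        rows.append(
            {
                "species": species,
                "group_a": group_a,
                "group_b": group_b,
                "mean_a": float(values_a.mean()),
                "mean_b": float(values_b.mean()),
                "n_a": len(values_a),
                "n_b": len(values_b),
                "t_statistic": float(t_stat),
                "p_value": float(p_value),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "group_a", "group_b", "mean_a", "mean_b",
                 "n_a", "n_b", "t_statistic", "p_value"],
    )


def call_restoration(
    vs_wildtype: pd.DataFrame,
    vs_mutant: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Classify each species from two comparison tables.

    ``vs_wildtype`` compares the reconstituted group (group_a) against wild
    type (group_b); ``vs_mutant`` compares the reconstituted group (group_a)
    against the mutant (group_b).  Rules at the (optionally
    Bonferroni-corrected) alpha:

    * ``restored_to_wt``: p(reconstituted vs WT) >= alpha;
    * ``elevated_over_mutant``: p(reconstituted vs mutant) < alpha AND
      mean(reconstituted) > mean(mutant).

    Species missing from either table are omitted.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")

    wt = vs_wildtype.set_index("species")
    mut = vs_mutant.set_index("species")
    species = sorted(set(wt.index) & set(mut.index))
    dropped = sorted(set(wt.index) ^ set(mut.index))
    if dropped:
        logger.warning("omitting species without both comparisons: %s", dropped)

    alpha_eff = alpha / len(species) if correction == "bonferroni" and species \
        else alpha

    rows = []
    for sp in species:
        p_wt = float(wt.loc[sp, "p_value"])
        p_mut = float(mut.loc[sp, "p_value"])
        elevated = p_mut < alpha_eff and \
            float(mut.loc[sp, "mean_a"]) > float(mut.loc[sp, "mean_b"])
        rows.append(
            {
                "species": sp,
                "restored_to_wt": p_wt >= alpha_eff,
                "elevated_over_mutant": bool(elevated),
                "p_vs_wildtype": p_wt,
                "p_vs_mutant": p_mut,
                "alpha_effective": alpha_eff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "restored_to_wt", "elevated_over_mutant",
                 "p_vs_wildtype", "p_vs_mutant", "alpha_effective"],
    )
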