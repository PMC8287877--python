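"""Mouse -> dendrite -> spine cohort representation, inclusion filters and summaries.

The canonical in-memory container is a pandas DataFrame with one row per spine
(the cohort CSV schema); dendrite- and mouse-level quantities are carried as
repeated columns and aggregated on demand.  Densities are spines per um^2 of
the dendrite's lateral cylinder surface pi * diameter * length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_CONDITIONS = {
    "P13": ("S", "EW4", "EW15", "Rec"),
    "P30": ("S", "SW", "EW", "CSR"),
}

#: dendrite diameter inclusion range (um) per age group
DIAMETER_RANGE = {"P13": (0.44, 2.24), "P30": (0.54, 1.74)}

#: spine-level columns of the cohort CSV schema
COHORT_COLUMNS = [
    "mouse_id",
    "condition",
    "age_group",
    "dendrite_id",
    "diameter_um",
    "length_um",
    "has_synapse",
    "oblique",
    "asi_um2",
    "has_endosome",
    "endosome_vol_um3",
    "has_spine_apparatus",
    "sa_vol_um3",
]


class IncompleteAnnotationError(ValueError):
    """Raised when synapse-defining annotations are missing."""


class EmptyGroupError(ValueError):
    """Raised when a summary is requested for an empty condition group."""


def classify_synapse(vesicle_count_within_50nm, has_cleft, has_psd):
    """Apply the synapse definition: >=1 presynaptic vesicle within 50 nm of the
    membrane facing the spine, a visible synaptic cleft and a postsynaptic density.

    Accepts scalars or aligned array-likes; returns bool or boolean array.
    """
    v = np.asarray(vesicle_count_within_50nm, dtype=float)
    cleft = np.asarray(has_cleft, dtype=object)
    psd = np.asarray(has_psd, dtype=object)
    if np.any(pd.isna(v)) or np.any(pd.isna(cleft)) or np.any(pd.isna(psd)):
        raise IncompleteAnnotationError("synapse annotations are incomplete")
    out = (v >= 1) & cleft.astype(bool) & psd.astype(bool)
    return bool(out) if out.ndim == 0 else out


def dendrite_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a spine-level cohort to one row per dendrite with counts,
    densities and organelle percentages."""
    def agg(g: pd.DataFrame) -> pd.Series:
        n_all = len(g)
        n_syn = int(g["has_synapse"].sum())
        surface = np.pi * g["diameter_um"].iloc[0] * g["length_um"].iloc[0]
        return pd.Series(
            {
                "mouse_id": g["mouse_id"].iloc[0],
                "condition": g["condition"].iloc[0],
                "age_group": g["age_group"].iloc[0],
                "diameter_um": g["diameter_um"].iloc[0],
                "length_um": g["length_um"].iloc[0],
                "n_shaft_synapses": int(g.get("n_shaft_synapses", pd.Series(0, index=g.index)).iloc[0]),
                "n_spines": n_all,
                "n_spines_with_synapse": n_syn,
                "n_spines_without_synapse": n_all - n_syn,
                "surface_um2": surface,
                "density_all": n_all / surface,
                "density_with_synapse": n_syn / surface,
                # difference, not a fresh quotient: keeps all = with + without exact
                "density_without_synapse": n_all / surface - n_syn / surface,
                "pct_without_synapse": 100.0 * (n_all - n_syn) / n_all if n_all else np.nan,
                "pct_spine_apparatus": 100.0 * g["has_spine_apparatus"].mean(),
                "pct_endosome": 100.0 * g["has_endosome"].mean(),
            }
        )

    out = cohort.groupby("dendrite_id", sort=True).apply(agg, include_groups=False)
    return out.reset_index()


def spine_densities(dendrite_spines: pd.DataFrame) -> dict:
    """Densities (per um^2 of lateral cylinder surface) for one dendrite's spines.

    Returns ``{"all", "with_synapse", "without_synapse"}``; the parts sum to the
    total exactly.
    """
    d = float(dendrite_spines["diameter_um"].iloc[0])
    length = float(dendrite_spines["length_um"].iloc[0])
    if length <= 0 or d <= 0:
        raise ZeroDivisionError("dendrite has non-positive diameter or length")
    surface = np.pi * d * length
    n_all = len(dendrite_spines)
    n_syn = int(dendrite_spines["has_synapse"].sum())
    all_d = n_all / surface
    with_d = n_syn / surface
    return {"all": all_d, "with_synapse": with_d, "without_synapse": all_d - with_d}


def filter_dendrites(
    cohort: pd.DataFrame,
    age_group: str,
    min_spines: int = 3,
    few_spines: int | None = None,
):
    """Apply the dendrite inclusion filters for an age group.

    Keeps dendrites whose diameter lies inside the age-group sampling range,
    that carry at least ``min_spines`` protrusions, and that are not sparsely
    spiny segments dominated by shaft synapses (fewer than ``few_spines``
    spines *and* more shaft synapses than spine synapses; default
    ``few_spines = 2 * min_spines``).

    Returns ``(included_cohort, exclusion_log)`` where the log has one row per
    excluded dendrite with its reason.  The filter is idempotent.
    """
    if age_group not in DIAMETER_RANGE:
        raise ValueError(f"unknown age_group {age_group!r}")
    if few_spines is None:
        few_spines = 2 * min_spines
    lo, hi = DIAMETER_RANGE[age_group]
    dend = dendrite_table(cohort)
    reasons = {}
    for _, row in dend.iterrows():
        if not (lo <= row["diameter_um"] <= hi):
            reasons[row["dendrite_id"]] = "diameter_out_of_range"
        elif row["n_spines"] < min_spines:
            reasons[row["dendrite_id"]] = "too_few_spines"
        elif (
            row["n_spines"] < few_spines
            and row["n_shaft_synapses"] > row["n_spines_with_synapse"]
        ):
            reasons[row["dendrite_id"]] = "shaft_synapses_exceed_spine_synapses"
    log = pd.DataFrame(
        {"dendrite_id": list(reasons), "reason": list(reasons.values())}
    )
    kept = cohort[~cohort["dendrite_id"].isin(reasons)].reset_index(drop=True)
    return kept, log


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-condition descriptive summary (one row per condition).

    ASI statistics use synapse-bearing, non-oblique spines with a measured
    area; densities, percentages, diameter and length are summarized across
    dendrites.  The SD of a single observation is reported as 0.
    """
    if len(cohort) == 0:
        raise EmptyGroupError("empty cohort")

    def sd(x):
        x = np.asarray(x, dtype=float)
        return 0.0 if len(x) <= 1 else float(np.std(x, ddof=1))

    rows = []
    for cond, g in cohort.groupby("condition", sort=True):
        if len(g) == 0:
            raise EmptyGroupError(f"condition {cond} has no spines")
        dend = dendrite_table(g)
        measured = g[g["has_synapse"] & ~g["oblique"].astype(bool)]["asi_um2"].dropna()
        rows.append(
            {
                "condition": cond,
                "n_dendrites": len(dend),
                "n_spines_with_synapse_measured": len(measured),
                "asi_mean_um2": float(measured.mean()) if len(measured) else np.nan,
                "asi_sd_um2": sd(measured),
                "asi_min_um2": float(measured.min()) if len(measured) else np.nan,
                "asi_max_um2": float(measured.max()) if len(measured) else np.nan,
                "density_all_mean": float(dend["density_all"].mean()),
                "density_all_sd": sd(dend["density_all"]),
                "density_with_synapse_mean": float(dend["density_with_synapse"].mean()),
                "density_with_synapse_sd": sd(dend["density_with_synapse"]),
                "density_without_synapse_mean": float(dend["density_without_synapse"].mean()),
                "density_without_synapse_sd": sd(dend["density_without_synapse"]),
                "pct_without_synapse_mean": float(dend["pct_without_synapse"].mean()),
                "pct_without_synapse_sd": sd(dend["pct_without_synapse"]),
                "diameter_mean_um": float(dend["diameter_um"].mean()),
                "diameter_sd_um": sd(dend["diameter_um"]),
                "length_mean_um": float(dend["length_um"].mean()),
                "length_sd_um": sd(dend["length_um"]),
                "pct_spine_apparatus_mean": float(dend["pct_spine_apparatus"].mean()),
                "pct_spine_apparatus_sd": sd(dend["pct_spine_apparatus"]),
                "pct_endosome_mean": float(dend["pct_endosome"].mean()),
                "pct_endosome_sd": sd(dend["pct_endosome"]),
            }
        )
    return pd.DataFrame(rows)


def check_diameter_balance(cohort: pd.DataFrame):
    """Likelihood-ratio p-value for a condition effect on dendrite diameter.

    Fits diameter ~ condition with a mouse random intercept on the dendrite
    table against the intercept-only model; a large p-value supports balanced
    sampling of dendrite calibres across groups.
    """
    from . import lme

    dend = dendrite_table(cohort)
    if dend["condition"].nunique() < 2:
        raise ValueError("diameter balance needs >=2 condition groups")
    ref = dend["condition"].iloc[0]
    full = lme.fit_lme(
        dend,
        lme.ModelSpec(
            response="diameter_um",
            transform="identity",
            fixed_effects=["condition"],
            random_intercepts=["mouse"],
            reference_level=ref,
        ),
    )
    reduced = lme.fit_lme(
        dend,
        lme.ModelSpec(
            response="diameter_um",
            transform="identity",
            fixed_effects=[],
            random_intercepts=["mouse"],
            reference_level=ref,
        ),
    )
    return lme.lrt(full, reduced)


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, coercing boolean columns."""
    df = pd.read_csv(path)
    for col in ("has_synapse", "oblique", "has_endosome", "has_spine_apparatus"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
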