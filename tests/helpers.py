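"""Shared builders for hierarchical test data.

``simulate_hier`` draws directly from the nested-intercepts model (the
independent generative route, bypassing the package's cohort generator) so
that fits can be checked against the generating truth and against external
oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_hier(
    rng,
    conditions=("A", "B", "C", "D"),
    effects=None,
    n_mice_per_cond=8,
    n_dend=3,
    n_spine=8,
    intercept=-2.14,
    slope=0.166,
    sd_mouse=0.0273,
    sd_dend=0.1025,
    sd_resid=0.8974,
) -> pd.DataFrame:
    """Spine-level frame with log-normal responses from the nested LME model."""
    effects = effects or {c: 0.0 for c in conditions}
    rows = []
    for c in conditions:
        for m in range(n_mice_per_cond):
            um = rng.normal(0, sd_mouse)
            mid = f"{c}m{m}"
            for d in range(n_dend):
                ud = rng.normal(0, sd_dend)
                diam = rng.normal(0.9, 0.25)
                for yy in (
                    intercept
                    + effects[c]
                    + slope * diam
                    + um
                    + ud
                    + rng.normal(0, sd_resid, n_spine)
                ):
                    rows.append((mid, f"{mid}d{d}", c, diam, np.exp(yy)))
    return pd.DataFrame(
        rows, columns=["mouse_id", "dendrite_id", "condition", "diameter_um", "asi_um2"]
    )


def lme4_reference_dataset() -> pd.DataFrame:
    """The fixed dataset whose ML fit was pinned against R lme4 (see tests)."""
    return simulate_hier(np.random.default_rng(0))


def minimal_cohort_rows(
    mouse_id,
    condition,
    dendrite_id,
    diameter,
    length,
    n_syn,
    n_no_syn=0,
    n_shaft=0,
    age_group="P13",
    asi=0.2,
):
    """Spine rows for one dendrite with all cohort-schema columns populated."""
    rows = []
    for i in range(n_syn + n_no_syn):
        syn = i < n_syn
        rows.append(
            dict(
                mouse_id=mouse_id,
                condition=condition,
                age_group=age_group,
                dendrite_id=dendrite_id,
                diameter_um=diameter,
                length_um=length,
                n_shaft_synapses=n_shaft,
                spine_id=f"{dendrite_id}_s{i}",
                has_synapse=syn,
                oblique=False,
                asi_um2=asi if syn else np.nan,
                has_endosome=False,
                endosome_vol_um3=np.nan,
                has_spine_apparatus=False,
                sa_vol_um3=np.nan,
                vesicle_count_within_50nm=2 if syn else 0,
                has_cleft=syn,
                has_psd=syn,
            )
        )
    return rows
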