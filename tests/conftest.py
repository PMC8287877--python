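import re
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from asinorm import cohort, lme, scaling, simulate  # noqa: E402

warnings.filterwarnings("ignore", category=UserWarning)

#: generating-model specs matching the packaged configurations
P13_ASI_SPEC = lme.ModelSpec(
    response="asi_um2",
    transform="log",
    fixed_effects=["condition", "diameter"],
    random_intercepts=["mouse", "dendrite"],
    reference_level="EW15",
)
P30_INTERACTION_SPEC = lme.ModelSpec(
    response="asi_um2",
    transform="log",
    fixed_effects=["condition", "diameter", "endosome", "condition:endosome"],
    random_intercepts=["mouse", "dendrite"],
    reference_level="CSR",
)
P13_DENSITY_SPEC = lme.ModelSpec(
    response="density_with_synapse",
    transform="sqrt",
    fixed_effects=["condition"],
    random_intercepts=["mouse"],
    reference_level="EW15",
)


def condition_effects(fit: lme.LmeFit) -> dict:
    """Map condition level -> estimated main effect (reference -> 0)."""
    out = {fit.spec.reference_level: 0.0}
    for name in fit.params.index:
        m = re.fullmatch(r"C\(condition.*\)\[T\.(.+?)\]", name)
        if m:
            out[m.group(1)] = float(fit.params[name])
    return out


@pytest.fixture(scope="session")
def p13_config():
    return simulate.load_packaged_config("P13")


@pytest.fixture(scope="session")
def p30_config():
    return simulate.load_packaged_config("P30")


@pytest.fixture(scope="session")
def big_p13(p13_config):
    """Large recovery cohort: 40 mice/condition, 15 dendrites/mouse."""
    return simulate.generate_cohort(
        p13_config, seed=11, n_mice=40, n_dendrites_per_mouse=15
    )


@pytest.fixture(scope="session")
def big_p13_fit(big_p13):
    return lme.fit_lme(big_p13, P13_ASI_SPEC)


@pytest.fixture(scope="session")
def big_p13_dendrites(big_p13):
    return cohort.dendrite_table(big_p13)


@pytest.fixture(scope="session")
def big_p13_density_fit(big_p13_dendrites):
    return lme.fit_lme(big_p13_dendrites, P13_DENSITY_SPEC)


@pytest.fixture(scope="session")
def big_p30(p30_config):
    return simulate.generate_cohort(
        p30_config, seed=11, n_mice=40, n_dendrites_per_mouse=15
    )


@pytest.fixture(scope="session")
def big_p30_fit(big_p30):
    return lme.fit_lme(big_p30, P30_INTERACTION_SPEC)


@pytest.fixture(scope="session")
def study_sweep():
    """200 study-matched synthetic replicates of both experiments.

    Per seed: the P13 base-model condition effects, the EW4-vs-S single-step
    contrast, the S-vs-EW15 scaling test, the P30 interaction LRT and the
    S-vs-CSR effect among endosome-bearing spines.
    """
    noint = P30_INTERACTION_SPEC.model_copy(
        update={"fixed_effects": ["condition", "diameter", "endosome"]}
    )
    records = []
    for seed in range(200):
        p13 = simulate.generate_study_fixture("P13", seed=seed, with_stacks=False).cohort
        fit = lme.fit_lme(p13, P13_ASI_SPEC)
        eff = condition_effects(fit)
        pairs = lme.pairwise_contrasts(fit, seed=seed, n_draws=20_000).pairs
        row = pairs[
            pairs.level_i.isin(["EW4", "S"]) & pairs.level_j.isin(["EW4", "S"])
        ].iloc[0]
        sign = 1.0 if row.level_i == "EW4" else -1.0
        s_asi = p13[(p13.condition == "S") & p13.has_synapse]["asi_um2"].dropna()
        ew15_asi = p13[(p13.condition == "EW15") & p13.has_synapse]["asi_um2"].dropna()
        sc = scaling.scaling_test(s_asi, ew15_asi)

        p30 = simulate.generate_study_fixture("P30", seed=seed, with_stacks=False).cohort
        full = lme.fit_lme(p30, P30_INTERACTION_SPEC)
        reduced = lme.fit_lme(p30, noint)
        s_endo = float(
            full.params["C(condition, Treatment('CSR'))[T.S]"]
            + full.params["C(condition, Treatment('CSR'))[T.S]:has_endosome"]
        )
        records.append(
            dict(
                seed=seed,
                p13_ew4=eff["EW4"],
                p13_s=eff["S"],
                p13_rec=eff["Rec"],
                ew4_vs_s_estimate=sign * float(row.estimate),
                ew4_vs_s_p_adjusted=float(row.p_adjusted),
                scaling_p=sc.p_value,
                p30_interaction_p=lme.lrt(full, reduced).p_value,
                p30_s_vs_csr_endosome=s_endo,
            )
        )
    return pd.DataFrame(records)
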