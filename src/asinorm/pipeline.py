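"""End-to-end analyses mirroring the two halves of the study.

``run_p13_analysis`` covers the pup experiment: condition + diameter mixed
model on log-ASI with all pairwise contrasts, a condition-by-endosome
interaction check, the S-vs-EW15 scaling test, organelle-volume models,
sqrt-density models and the lower-tail truncation sweep for EW4 vs EW15.
``run_p30_analysis`` covers the adolescent experiment: the same base model,
the interaction model with contrasts inside each endosome stratum, the
S-vs-CSR scaling test and density models.  Reports are plain nested dicts
(JSON-serialisable) and deterministic given cohort and seed; every statistic
can be reproduced by calling the underlying module operation directly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, cohort as cohort_mod, lme, scaling

ALPHA = 0.05
TREND = 0.10


def _annotate(p: float) -> str:
    return "significant" if p < ALPHA else ("trend" if p < TREND else "ns")


def _fit_dict(fit: lme.LmeFit) -> dict:
    return {
        "fixed_effects": [
            {"term": name, "estimate": float(fit.params[name]), "se": float(fit.se[name])}
            for name in fit.params.index
        ],
        "sd_mouse": fit.sd_mouse,
        "sd_dendrite": fit.sd_dendrite,
        "sd_residual": fit.sd_residual,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
    }


def _lrt_dict(res: lme.LrtResult) -> dict:
    return {
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "verdict": _annotate(res.p_value),
    }


def _contrast_records(res: lme.ContrastResult) -> list[dict]:
    out = res.pairs.to_dict("records")
    for row in out:
        row["verdict"] = _annotate(row["p_adjusted"])
    return out


def _scaling_dict(res: scaling.ScalingResult) -> dict:
    return {
        "c_hat": res.c_hat,
        "scale_factor": float(np.exp(res.c_hat)),
        "ks_statistic": res.ks_statistic,
        "p_value": res.p_value,
        "n1": res.n1,
        "n2": res.n2,
        "consistent_with_scaling": res.p_value >= ALPHA,
    }


def _measured_asi(df: pd.DataFrame, condition: str) -> np.ndarray:
    sel = df[
        (df["condition"] == condition)
        & df["has_synapse"]
        & ~df["oblique"].astype(bool)
        & df["asi_um2"].notna()
    ]
    return sel["asi_um2"].to_numpy()


def _density_models(dend: pd.DataFrame, reference: str, seed: int) -> dict:
    """Sqrt-scale density models (all / with / without synapse) with condition
    LRT and pairwise contrasts."""
    out = {}
    for label, col in [
        ("all", "density_all"),
        ("with_synapse", "density_with_synapse"),
        ("without_synapse", "density_without_synapse"),
    ]:
        spec = lme.ModelSpec(
            response=col,
            transform="sqrt",
            fixed_effects=["condition"],
            random_intercepts=["mouse"],
            reference_level=reference,
        )
        fit = lme.fit_lme(dend, spec)
        null = lme.fit_lme(
            dend, spec.model_copy(update={"fixed_effects": [], "reference_level": ""})
        )
        out[label] = {
            "fit": _fit_dict(fit),
            "condition_lrt": _lrt_dict(lme.lrt(fit, null)),
            "contrasts": _contrast_records(
                lme.pairwise_contrasts(fit, seed=seed)
            ),
        }
    return out


def _volume_model(df: pd.DataFrame, response: str, reference: str, seed: int) -> dict:
    spec = lme.ModelSpec(
        response=response,
        transform="log",
        fixed_effects=["condition", "diameter"],
        random_intercepts=["mouse", "dendrite"],
        reference_level=reference,
    )
    fit = lme.fit_lme(df, spec)
    reduced = lme.fit_lme(
        df, spec.model_copy(update={"fixed_effects": ["diameter"], "reference_level": ""})
    )
    return {
        "fit": _fit_dict(fit),
        "condition_lrt": _lrt_dict(lme.lrt(fit, reduced)),
        "contrasts": _contrast_records(lme.pairwise_contrasts(fit, seed=seed)),
    }


def _base_asi_analysis(df: pd.DataFrame, reference: str, seed: int) -> dict:
    """Condition + diameter model, condition LRT, all-pairs contrasts and the
    condition-by-endosome interaction LRT shared by both age groups."""
    base_spec = lme.ModelSpec(
        response="asi_um2",
        transform="log",
        fixed_effects=["condition", "diameter"],
        random_intercepts=["mouse", "dendrite"],
        reference_level=reference,
    )
    fit = lme.fit_lme(df, base_spec)
    diam_only = lme.fit_lme(
        df,
        base_spec.model_copy(update={"fixed_effects": ["diameter"], "reference_level": ""}),
    )
    inter_spec = base_spec.model_copy(
        update={"fixed_effects": ["condition", "diameter", "endosome", "condition:endosome"]}
    )
    inter_fit = lme.fit_lme(df, inter_spec)
    no_inter = lme.fit_lme(
        df,
        inter_spec.model_copy(
            update={"fixed_effects": ["condition", "diameter", "endosome"]}
        ),
    )
    return {
        "model": _fit_dict(fit),
        "condition_lrt": _lrt_dict(lme.lrt(fit, diam_only)),
        "contrasts": _contrast_records(lme.pairwise_contrasts(fit, seed=seed)),
        "interaction_model": _fit_dict(inter_fit),
        "interaction_lrt": _lrt_dict(lme.lrt(inter_fit, no_inter)),
        "_fits": {"base": fit, "interaction": inter_fit},
    }


def run_p13_analysis(cohort: pd.DataFrame, seed: int = 0) -> dict:
    """Full pup analysis on a P13 cohort (see module docstring)."""
    filtered, exclusions = cohort_mod.filter_dendrites(cohort, "P13")
    dend = cohort_mod.dendrite_table(filtered)
    base = _base_asi_analysis(filtered, reference="EW15", seed=seed)
    fits = base.pop("_fits")
    sweep = lme.truncation_sweep(
        filtered,
        fits["base"].spec,
        pair=("EW4", "EW15"),
    )
    report = {
        "age_group": "P13",
        "n_spines_in": int(len(cohort)),
        "n_spines_kept": int(len(filtered)),
        "n_dendrites_excluded": int(len(exclusions)),
        "summary": cohort_mod.summarize_cohort(filtered).to_dict("records"),
        "asi": base,
        "scaling_S_vs_EW15": _scaling_dict(
            scaling.scaling_test(
                _measured_asi(filtered, "S"), _measured_asi(filtered, "EW15")
            )
        ),
        "endosome_volume": _volume_model(
            filtered[filtered["has_endosome"]], "endosome_vol_um3", "EW15", seed
        ),
        "spine_apparatus_volume": _volume_model(
            filtered[filtered["has_spine_apparatus"]], "sa_vol_um3", "EW15", seed
        ),
        "density": _density_models(dend, "EW15", seed),
        "truncation_sweep_EW4_vs_EW15": {
            "profile": sweep["profile"].to_dict("records"),
            "first_nonsignificant_quantile": sweep["first_nonsignificant_quantile"],
        },
    }
    return report


def run_p30_analysis(cohort: pd.DataFrame, seed: int = 0) -> dict:
    """Full adolescent analysis on a P30 cohort (see module docstring)."""
    filtered, exclusions = cohort_mod.filter_dendrites(cohort, "P30")
    dend = cohort_mod.dendrite_table(filtered)
    base = _base_asi_analysis(filtered, reference="CSR", seed=seed)
    fits = base.pop("_fits")
    report = {
        "age_group": "P30",
        "n_spines_in": int(len(cohort)),
        "n_spines_kept": int(len(filtered)),
        "n_dendrites_excluded": int(len(exclusions)),
        "summary": cohort_mod.summarize_cohort(filtered).to_dict("records"),
        "asi": base,
        "contrasts_with_endosome": _contrast_records(
            lme.pairwise_contrasts(fits["interaction"], within_endosome=1, seed=seed)
        ),
        "contrasts_without_endosome": _contrast_records(
            lme.pairwise_contrasts(fits["interaction"], within_endosome=0, seed=seed)
        ),
        "scaling_S_vs_CSR": _scaling_dict(
            scaling.scaling_test(
                _measured_asi(filtered, "S"), _measured_asi(filtered, "CSR")
            )
        ),
        "density": _density_models(dend, "CSR", seed),
    }
    return report


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    seed: int
    inputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__

    @staticmethod
    def hash_file(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        return h.hexdigest()

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _Timer()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "inputs": self.inputs,
                    "stage_seconds": self.stage_seconds,
                    "outputs": self.outputs,
                    "version": self.version,
                },
                fh,
                indent=2,
            )


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
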