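"""Virtual microdialysis experiments emulating the animal study design.

Each virtual animal gets true model parameters drawn log-normally around the
species medians, true probe recoveries drawn around the observed
retrodialysis means, a retrodialysis phase (three 20-min dialysate
fractions per probe at the species perfusate concentration), a washout with
no carryover, an i.v. dose (rat: 20/5 mg/kg CAZ/AVI bolus; pig: 40/10 mg/kg
as a 2-h infusion) and interval dialysate sampling (rat: every 10 min for
1 h then every 30 min for 1.5 h; pig: every 30 min for 6 h).  Dialysate
concentrations are the true recovery fraction times the model interval
average with multiplicative proportional error.  All randomness flows
through one seeded generator so cohorts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import (
    DoseRegimen,
    load_drug_parameters,
    load_kidney_geometry,
    load_species_physiology,
)
from .estimation import (
    DEFAULT_FREE,
    FitSpec,
    fit_animal,
)
from .microdialysis import PROBE_SITES, PROBE_TRACKER, correct_dialysate, recovery_by_loss
from .model import build_whole_body_model
from .simulate import simulate

__all__ = [
    "SyntheticDesign",
    "generate_virtual_animal",
    "generate_cohort",
    "recovery_harness",
    "RECOVERY_BY_LOSS_OBSERVED",
    "PERFUSATE_MG_L",
    "DOSE_MG_PER_KG",
]

#: Observed mean +- SD in vivo recovery by loss (%) per species/drug/probe.
RECOVERY_BY_LOSS_OBSERVED = {
    ("rat", "CAZ", "blood"): (70.6, 16.2),
    ("rat", "CAZ", "muscle"): (50.9, 5.6),
    ("rat", "CAZ", "kidney"): (44.2, 4.7),
    ("rat", "AVI", "blood"): (80.9, 6.7),
    ("rat", "AVI", "muscle"): (77.6, 4.9),
    ("rat", "AVI", "kidney"): (57.1, 13.8),
    ("pig", "CAZ", "blood"): (78.0, 30.0),
    ("pig", "CAZ", "muscle"): (41.3, 18.3),
    ("pig", "CAZ", "kidney"): (63.8, 22.9),
    ("pig", "AVI", "blood"): (85.8, 25.8),
    ("pig", "AVI", "muscle"): (47.1, 15.5),
    ("pig", "AVI", "kidney"): (71.2, 21.0),
}

#: Retrodialysis perfusate concentration (mg/L == ug/mL).
PERFUSATE_MG_L = {
    ("rat", "CAZ"): 100.0,
    ("rat", "AVI"): 10.0,
    ("pig", "CAZ"): 50.0,
    ("pig", "AVI"): 12.5,
}

DOSE_MG_PER_KG = {
    ("rat", "CAZ"): 20.0,
    ("rat", "AVI"): 5.0,
    ("pig", "CAZ"): 40.0,
    ("pig", "AVI"): 10.0,
}

INFUSION_H = {"rat": 0.0, "pig": 2.0}

#: Dialysate collection interval boundaries (h after dose).
SAMPLING_BOUNDS = {
    "rat": [i / 6.0 for i in range(7)] + [1.5, 2.0, 2.5],
    "pig": [0.5 * i for i in range(13)],
}

#: Retrodialysis interval boundaries (h; before washout and dosing).
RETRO_BOUNDS = (-3.0, -3.0 + 1 / 3, -3.0 + 2 / 3, -2.0)


@dataclass(frozen=True)
class SyntheticDesign:
    """The study conditions for one virtual cohort."""

    species: str
    drug_name: str
    n_animals: int = 5
    residual_cv: float = 0.15          # proportional assay+probe error
    parameter_cv: float = 0.25         # between-animal log-normal CV
    seed: int = 0
    probe_sites: tuple = PROBE_SITES
    true_medians: dict = field(default_factory=dict)   # parameter -> median

    def __post_init__(self) -> None:
        if self.species not in SAMPLING_BOUNDS:
            raise ValueError(f"unknown species {self.species!r}")
        if self.residual_cv < 0 or self.parameter_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.n_animals < 1:
            raise ValueError("need n_animals >= 1")
        if not self.true_medians:
            drug = load_drug_parameters(self.drug_name, species=self.species)
            free = DEFAULT_FREE[(drug.drug_name, self.species)]
            medians = {name: getattr(drug, name) for name in free}
            object.__setattr__(self, "true_medians", medians)

    @property
    def sampling_bounds(self) -> list:
        return list(SAMPLING_BOUNDS[self.species])

    @property
    def perfusate_mg_l(self) -> float:
        return PERFUSATE_MG_L[(self.species, self.drug_name)]

    def regimen(self, body_weight: float) -> DoseRegimen:
        amount = DOSE_MG_PER_KG[(self.species, self.drug_name)] * body_weight
        infusion = INFUSION_H[self.species]
        if infusion > 0:
            return DoseRegimen.infusion(amount, infusion)
        return DoseRegimen.bolus(amount)


def _draw_true_parameters(design: SyntheticDesign, rng) -> dict:
    """Log-normal parameter draw with median at the species value."""
    cv = design.parameter_cv
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return {
        name: float(median * np.exp(rng.normal(0.0, sigma))) if cv > 0 else float(median)
        for name, median in design.true_medians.items()
    }


def _draw_recoveries(design: SyntheticDesign, rng) -> dict:
    out = {}
    for site in design.probe_sites:
        mean, sd = RECOVERY_BY_LOSS_OBSERVED[(design.species, design.drug_name, site)]
        rl = rng.normal(mean, sd)
        out[site] = float(np.clip(rl, 20.0, 95.0))
    return out


def generate_virtual_animal(design: SyntheticDesign, animal_index: int):
    """One virtual animal: (long-format dialysate frame, ground-truth dict).

    The truth dict holds the drawn model parameters, the true per-probe
    recoveries and the dose.
    """
    rng = np.random.default_rng([design.seed, animal_index])
    phys = load_species_physiology(design.species)
    geom = load_kidney_geometry(design.species)
    drug = load_drug_parameters(design.drug_name, species=design.species)

    true_params = _draw_true_parameters(design, rng)
    true_rl = _draw_recoveries(design, rng)
    regimen = design.regimen(phys.body_weight)

    net = build_whole_body_model(phys, geom, drug.with_updates(**true_params))
    bounds = np.array(design.sampling_bounds)
    res = simulate(net, regimen, float(bounds.max()), grid=bounds)

    animal_id = f"{design.species}{animal_index + 1:02d}"
    cv = design.residual_cv
    rows = []
    for site in design.probe_sites:
        # retrodialysis phase
        c_in = design.perfusate_mg_l
        for lo, hi in zip(RETRO_BOUNDS[:-1], RETRO_BOUNDS[1:]):
            noise = 1.0 + cv * rng.standard_normal()
            c_out = c_in * (1.0 - true_rl[site] / 100.0) * max(noise, 1e-6)
            rows.append(dict(
                animal_id=animal_id, species=design.species, drug=design.drug_name,
                probe_site=site, phase="retrodialysis",
                t_start_h=lo, t_end_h=hi, conc_mg_L=c_out, c_in_mg_L=c_in,
            ))
        # PK phase: dialysate = recovery fraction x interval-averaged tissue conc
        tracker = res.tracker(PROBE_TRACKER[site])
        auc_at = dict(zip(res.times, tracker))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            avg = (auc_at[hi] - auc_at[lo]) / (hi - lo)
            noise = 1.0 + cv * rng.standard_normal()
            conc = true_rl[site] / 100.0 * avg * max(noise, 1e-6)
            rows.append(dict(
                animal_id=animal_id, species=design.species, drug=design.drug_name,
                probe_site=site, phase="pk",
                t_start_h=float(lo), t_end_h=float(hi), conc_mg_L=conc,
                c_in_mg_L=np.nan,
            ))
    truth = dict(animal_id=animal_id, dose_mg=regimen.total_dose,
                 **{f"true_{k}": v for k, v in true_params.items()},
                 **{f"true_rl_{site}": true_rl[site] for site in design.probe_sites})
    return pd.DataFrame(rows), truth


def generate_cohort(design: SyntheticDesign):
    """Concatenated per-animal datasets plus the ground-truth table."""
    frames, truths = [], []
    for i in range(design.n_animals):
        frame, truth = generate_virtual_animal(design, i)
        frames.append(frame)
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truths)


def fit_cohort(data: pd.DataFrame, design: SyntheticDesign, n_starts: int = 3,
               seed: int = 0):
    """Recovery-correct and fit every animal in a cohort; returns fit list.

    Convenience wrapper running the full observation pipeline:
    retrodialysis recovery -> dialysate correction -> per-animal weighted
    least squares with the species' default free-parameter set.
    """
    phys = load_species_physiology(design.species)
    geom = load_kidney_geometry(design.species)
    drug = load_drug_parameters(design.drug_name, species=design.species)
    spec = FitSpec(
        free=tuple(design.true_medians),
        initial=dict(design.true_medians),
        n_starts=n_starts,
    )
    regimen = design.regimen(phys.body_weight)
    fits = {}
    for animal_id, animal in data.groupby("animal_id"):
        corrected = []
        scale_var = {}
        for site, probe in animal.groupby("probe_site"):
            retro = probe[probe["phase"] == "retrodialysis"]
            rec = recovery_by_loss(
                float(retro["c_in_mg_L"].iloc[0]), retro["conc_mg_L"].to_list(),
                animal_id=animal_id, probe_site=site, drug=design.drug_name,
            )
            corrected.append(correct_dialysate(probe[probe["phase"] == "pk"], rec))
            # relative SE of the mean recovery -> shared calibration variance
            valid = [v for v, ok in zip(rec.interval_values, rec.valid) if ok]
            if len(valid) > 1:
                se = float(np.std(valid, ddof=1) / np.sqrt(len(valid)))
                scale_var[site] = (se / rec.mean) ** 2
        obs = pd.concat(corrected, ignore_index=True)
        fits[animal_id] = fit_animal(obs, phys, geom, drug, regimen, spec, seed=seed,
                                     scale_variance_by_site=scale_var)
    return fits


def recovery_harness(design: SyntheticDesign, n_repetitions: int, seed: int = 0):
    """Repeated generate -> correct -> fit cycles; bias/RMSE/coverage report.

    Each repetition draws a fresh cohort (seed offset by the repetition
    index), runs the full pipeline and compares per-animal estimates with
    the generating truth.  Returns (per-fit frame, per-parameter summary
    with median relative bias, relative RMSE and 95%-CI coverage).
    """
    records = []
    failures = []
    for rep in range(n_repetitions):
        rep_design = replace(design, seed=design.seed + 1000 * rep)
        data, truth = generate_cohort(rep_design)
        try:
            fits = fit_cohort(data, rep_design, seed=seed + rep)
        except Exception as exc:
            failures.append((rep, str(exc)))
            continue
        truth = truth.set_index("animal_id")
        for animal_id, fit in fits.items():
            for name in fit.param_names:
                true_value = truth.loc[animal_id, f"true_{name}"]
                lo, hi = fit.ci95(name)
                records.append(dict(
                    repetition=rep, animal_id=animal_id, parameter=name,
                    estimate=fit.estimates[name], truth=float(true_value),
                    ci_lower=lo, ci_upper=hi,
                    covered=bool(lo <= true_value <= hi),
                ))
    per_fit = pd.DataFrame(records)
    if per_fit.empty:
        raise RuntimeError(f"all repetitions failed: {failures}")
    per_fit["relative_error"] = per_fit["estimate"] / per_fit["truth"] - 1.0
    summary = per_fit.groupby("parameter").agg(
        median_relative_bias=("relative_error", "median"),
        relative_rmse=("relative_error", lambda e: float(np.sqrt(np.mean(e**2)))),
        ci95_coverage=("covered", "mean"),
        n_fits=("estimate", "size"),
    )
    summary.attrs["failures"] = failures
    return per_fit, summary
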