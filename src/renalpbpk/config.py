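"""Species physiology, kidney geometry, drug parameters and dose regimens.

Configuration lives in YAML files with top-level keys ``species``,
``kidney_geometry`` and ``drug``.  Shipped defaults for rat, pig and human
(and for ceftazidime and avibactam) are packaged under ``renalpbpk/configs``
and can be loaded by name; any file with the same schema can be loaded by
path.  Internal units are h, L, mg and mg/L; permeabilities are stored in
cm/s and become L/h clearances via the exchange surface (cm^2) at build
time (1 cm^3/s = 3.6 L/h).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = [
    "SpeciesPhysiology",
    "KidneyGeometry",
    "DrugParameters",
    "DoseEvent",
    "DoseRegimen",
    "ConfigError",
    "SEGMENT_ORDER",
    "REGIONS",
    "load_species_physiology",
    "load_kidney_geometry",
    "load_drug_parameters",
    "validate_physiology",
    "save_config",
]

#: Fixed anatomical order of the tubular chain.
SEGMENT_ORDER = (
    "PT1", "PT2", "PT3", "DLH", "ALH", "DT",
    "CD1", "CD2", "CD3", "CD4", "CD5", "CD6", "CD7", "CD8", "CD9",
)

#: Kidney regions from cortex outward.
REGIONS = ("cortex", "outer_medulla", "inner_medulla_1", "inner_medulla_2")

#: Perfusion-limited organs needing a tissue:plasma partition coefficient.
PERFUSION_LIMITED = ("lungs", "adipose", "liver", "rest")

CM3_PER_S_TO_L_PER_H = 3.6  # 1 cm^3/s = 3600 cm^3/h = 3.6 L/h


class ConfigError(ValueError):
    """A configuration value violates the schema or an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesPhysiology:
    """Body-level physiology of one species.

    ``blood_flows`` covers adipose, muscle, liver, kidney and rest (L/h);
    the rest-of-body flow is the closure term CO minus the named organ
    flows.  ``organ_volumes`` (L) covers venous/arterial blood, lungs,
    adipose, the three muscle spaces, liver and rest of body.
    ``medullary_blood_flow_fractions`` are the fractions of renal blood
    flow reaching the outer medulla and the two inner-medulla regions.
    """

    species_name: str
    body_weight: float
    cardiac_output: float
    blood_flows: dict
    organ_volumes: dict
    hematocrit: float
    gfr: float
    urine_flow: float
    medullary_blood_flow_fractions: dict
    source: str = ""

    def __post_init__(self) -> None:
        errors = _physiology_errors(self)
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass(frozen=True)
class KidneyGeometry:
    """Regional kidney anatomy and the 15-segment tubular chain.

    ``regions`` maps each of cortex, outer_medulla, inner_medulla_1 and
    inner_medulla_2 to blood_volume (L), interstitial_volume (L) and
    vascular_exchange_surface (cm^2).  ``segments`` maps each tubule
    segment to lumen_volume (L), surface_area (cm^2), its host region and
    the fraction of GFR still flowing at the segment exit
    (``water_fraction_exit``), which is non-increasing along the chain and
    ends at urine_flow/GFR.
    """

    regions: dict
    segments: dict
    source: str = ""

    def __post_init__(self) -> None:
        errors = _geometry_errors(self)
        if errors:
            raise ConfigError("; ".join(errors))

    @property
    def water_remaining_fraction(self) -> dict:
        return {s: self.segments[s]["water_fraction_exit"] for s in SEGMENT_ORDER}

    def segments_in_region(self, region: str) -> list:
        return [s for s in SEGMENT_ORDER if self.segments[s]["region"] == region]


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific constants of the model.

    Permeabilities are in cm/s: the directional tubular values
    (``papp_lumen_to_interstitium`` apical->basal and the reverse) come from
    LLC-PK1 monolayer transport, and the kidney vascular pair shares the
    same scale, with the blood->interstitium reference fixed high (1e-4
    cm/s, printed as "100") and the interstitium->blood value estimated
    from in vivo data.  ``cl_glomerular`` is the glomerular plasma
    clearance; when None it defaults to fu x GFR at build time.  ``kp``
    holds tissue:plasma partition coefficients for the perfusion-limited
    organs and ``kp_muscle_cell`` the muscle cell:water partition.
    """

    drug_name: str
    molecular_weight: float
    fu_plasma: float
    blood_plasma_ratio: float
    papp_lumen_to_interstitium: float
    papp_interstitium_to_lumen: float
    p_blood_to_interstitium: float
    p_interstitium_to_blood: float
    kp: dict
    cl_nonrenal: float = 0.0
    cl_tubular_secretion: float = 0.0
    cl_glomerular: float | None = None
    kp_muscle_cell: float = 0.1
    muscle_ps_multiplier: float = 10.0
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise ConfigError(f"fu_plasma must be in (0, 1], got {self.fu_plasma}")
        if self.blood_plasma_ratio <= 0:
            raise ConfigError("blood_plasma_ratio must be > 0")
        for name in (
            "papp_lumen_to_interstitium",
            "papp_interstitium_to_lumen",
            "p_blood_to_interstitium",
            "p_interstitium_to_blood",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("cl_nonrenal", "cl_tubular_secretion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.cl_glomerular is not None and self.cl_glomerular <= 0:
            raise ConfigError("cl_glomerular must be > 0 when given")
        missing = [o for o in PERFUSION_LIMITED if o not in self.kp]
        if missing:
            raise ConfigError(f"kp missing organs: {missing}")

    def with_updates(self, **kwargs) -> "DrugParameters":
        return replace(self, **kwargs)

    def glomerular_clearance(self, gfr: float) -> float:
        """Glomerular plasma clearance: the explicit value or fu x GFR."""
        return self.cl_glomerular if self.cl_glomerular is not None else self.fu_plasma * gfr


@dataclass(frozen=True)
class DoseEvent:
    start: float          # h
    amount: float         # mg
    infusion_duration: float = 0.0   # h; 0 = bolus
    target: str = "venous_blood"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ConfigError("dose amount must be > 0")
        if self.infusion_duration < 0:
            raise ConfigError("infusion duration must be >= 0")


@dataclass(frozen=True)
class DoseRegimen:
    """Time-ordered i.v. dose events."""

    events: tuple

    def __post_init__(self) -> None:
        starts = [e.start for e in self.events]
        if starts != sorted(starts):
            raise ConfigError("dose events must be time-ordered")

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    @property
    def span(self) -> float:
        return max((e.start + e.infusion_duration for e in self.events), default=0.0)

    @classmethod
    def bolus(cls, amount: float, start: float = 0.0, target: str = "venous_blood"):
        return cls((DoseEvent(start, amount, 0.0, target),))

    @classmethod
    def infusion(cls, amount: float, duration: float, start: float = 0.0,
                 target: str = "venous_blood"):
        return cls((DoseEvent(start, amount, duration, target),))

    @classmethod
    def repeated(cls, amount: float, interval: float, n_doses: int,
                 infusion_duration: float = 0.0, target: str = "venous_blood"):
        return cls(tuple(
            DoseEvent(i * interval, amount, infusion_duration, target)
            for i in range(n_doses)
        ))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _physiology_errors(p: SpeciesPhysiology) -> list:
    errors = []
    if p.body_weight <= 0:
        errors.append("body_weight must be > 0")
    if p.cardiac_output <= 0:
        errors.append("cardiac_output must be > 0")
    for organ in ("adipose", "muscle", "liver", "kidney", "rest"):
        q = p.blood_flows.get(organ)
        if q is None or q <= 0:
            errors.append(f"blood flow to {organ} must be > 0")
    if not errors:
        total = sum(p.blood_flows[o] for o in ("adipose", "muscle", "liver", "kidney", "rest"))
        if abs(total - p.cardiac_output) > 1e-9 * p.cardiac_output:
            errors.append(
                f"organ blood flows sum to {total:g} L/h but cardiac output is "
                f"{p.cardiac_output:g} L/h"
            )
    required_volumes = (
        "venous_blood", "arterial_blood", "lungs", "adipose",
        "muscle_vascular", "muscle_interstitial", "muscle_cellular",
        "liver", "rest",
    )
    for organ in required_volumes:
        v = p.organ_volumes.get(organ)
        if v is None or v <= 0:
            errors.append(f"organ volume {organ} must be > 0")
    if not 0 < p.hematocrit < 1:
        errors.append("hematocrit must be in (0, 1)")
    if p.gfr <= 0:
        errors.append("GFR must be > 0")
    if not 0 < p.urine_flow < p.gfr:
        errors.append("urine_flow must be in (0, GFR)")
    fr = [p.medullary_blood_flow_fractions.get(r) for r in REGIONS[1:]]
    if any(f is None or not 0 < f < 1 for f in fr):
        errors.append("medullary blood-flow fractions must be in (0, 1)")
    elif not (fr[0] > fr[1] > fr[2]):
        errors.append("medullary blood-flow fractions must decrease from cortex outward")
    return errors


def _geometry_errors(g: KidneyGeometry) -> list:
    errors = []
    for region in REGIONS:
        spec = g.regions.get(region)
        if spec is None:
            errors.append(f"missing region {region}")
            continue
        for key in ("blood_volume", "interstitial_volume", "vascular_exchange_surface"):
            v = spec.get(key)
            if v is None or v <= 0:
                errors.append(f"{region}.{key} must be > 0")
    missing = [s for s in SEGMENT_ORDER if s not in g.segments]
    if missing:
        errors.append(f"missing tubule segments: {missing}")
        return errors
    extra = [s for s in g.segments if s not in SEGMENT_ORDER]
    if extra:
        errors.append(f"unknown tubule segments: {extra}")
    prev = 1.0
    for s in SEGMENT_ORDER:
        spec = g.segments[s]
        for key in ("lumen_volume", "surface_area"):
            v = spec.get(key)
            if v is None or v <= 0:
                errors.append(f"{s}.{key} must be > 0")
        if spec.get("region") not in REGIONS:
            errors.append(f"{s}.region {spec.get('region')!r} is not a declared region")
        f = spec.get("water_fraction_exit")
        if f is None or not 0 < f <= 1:
            errors.append(f"{s}.water_fraction_exit must be in (0, 1]")
        elif f > prev + 1e-12:
            errors.append(
                f"water_fraction_exit increases at {s} ({prev:g} -> {f:g}); "
                "filtrate flow must be non-increasing along the tubule"
            )
        else:
            prev = f
    return errors


def validate_physiology(phys: SpeciesPhysiology, geom: KidneyGeometry) -> list:
    """Cross-validate a physiology/geometry pair; returns violated invariants.

    An empty list means the pair is consistent: flows close to cardiac
    output, the water-remaining profile is monotone, every segment lives in
    a declared region, and the CD9 exit fraction matches urine_flow/GFR.
    """
    report = list(_physiology_errors(phys))
    report.extend(_geometry_errors(geom))
    if not report:
        cd9 = geom.segments["CD9"]["water_fraction_exit"]
        target = phys.urine_flow / phys.gfr
        if abs(cd9 - target) > 1e-6 * target:
            report.append(
                f"CD9 exit water fraction {cd9:g} does not equal urine_flow/GFR "
                f"= {target:g}"
            )
    return report


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

_BUILTIN_SPECIES = {"rat": "rat.yaml", "pig": "pig.yaml", "human": "human.yaml"}
_BUILTIN_DRUGS = {"caz": "caz.yaml", "avi": "avi.yaml"}


def _read_builtin(filename: str) -> dict:
    ref = importlib.resources.files("renalpbpk") / "configs" / filename
    return yaml.safe_load(ref.read_text())


def _read_config(path_or_name, table: dict, kind: str) -> dict:
    key = str(path_or_name).lower()
    if key in table:
        return _read_builtin(table[key])
    path = Path(path_or_name)
    if not path.exists():
        known = ", ".join(sorted(table))
        raise KeyError(
            f"unknown {kind} {path_or_name!r}: not a built-in ({known}) and no such file"
        )
    return yaml.safe_load(path.read_text())


def load_species_physiology(path_or_name) -> SpeciesPhysiology:
    """Load a species physiology by built-in name (rat/pig/human) or path."""
    doc = _read_config(path_or_name, _BUILTIN_SPECIES, "species")
    try:
        spec = dict(doc["species"])
    except (TypeError, KeyError) as exc:
        raise ConfigError("config lacks a top-level 'species' mapping") from exc
    return SpeciesPhysiology(**spec)


def load_kidney_geometry(path_or_name) -> KidneyGeometry:
    """Load a kidney geometry by built-in species name or path."""
    doc = _read_config(path_or_name, _BUILTIN_SPECIES, "species")
    try:
        spec = dict(doc["kidney_geometry"])
    except (TypeError, KeyError) as exc:
        raise ConfigError("config lacks a top-level 'kidney_geometry' mapping") from exc
    return KidneyGeometry(**spec)


def load_drug_parameters(path_or_name, species: str | None = None) -> DrugParameters:
    """Load drug parameters by built-in name (CAZ/AVI) or path.

    When ``species`` is given, the per-species estimated values recorded in
    the config's ``fitted`` section (glomerular / non-renal / secretion
    clearances and the kidney interstitium->blood permeability) override
    the base values.
    """
    doc = _read_config(path_or_name, _BUILTIN_DRUGS, "drug")
    try:
        spec = dict(doc["drug"])
    except (TypeError, KeyError) as exc:
        raise ConfigError("config lacks a top-level 'drug' mapping") from exc
    if species is not None:
        fitted = doc.get("fitted", {})
        if species not in fitted:
            raise KeyError(
                f"no fitted parameter set for species {species!r} in "
                f"{spec.get('drug_name', path_or_name)}"
            )
        spec.update(fitted[species])
    return DrugParameters(**spec)


def save_config(path, *, species: SpeciesPhysiology | None = None,
                kidney_geometry: KidneyGeometry | None = None,
                drug: DrugParameters | None = None) -> None:
    """Write a configuration YAML that round-trips through the loaders."""
    doc = {}
    if species is not None:
        doc["species"] = asdict(species)
    if kidney_geometry is not None:
        doc["kidney_geometry"] = asdict(kidney_geometry)
    if drug is not None:
        doc["drug"] = asdict(drug)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
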