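"""Linear compartment networks for whole-body PBPK models.

A :class:`CompartmentNetwork` is a continuous-time linear system over drug
*amounts* (mg).  Compartments carry a volume (L) and a set of emission
factors that translate the local total concentration ``x/V`` into the
concentration that drives each transfer:

``total``
    the raw concentration in the compartment's reference phase (blood
    concentration for blood compartments, tissue concentration for
    perfusion-limited organs, aqueous concentration for interstitial and
    lumen spaces);
``plasma``
    the plasma-equivalent concentration (blood / blood:plasma ratio, or
    tissue / Kp for a perfusion-limited organ);
``unbound``
    the unbound aqueous concentration (fu x plasma for blood-side spaces;
    interstitial and tubular-lumen fluid is treated as fully unbound).

Every transfer is a directed clearance edge ``flux = CL * C_driving(source)``
so the assembled system is ``dx/dt = A x + u(t)`` with ``A`` constant between
dose events.  Time integrals of selected concentrations (AUC trackers) are
co-integrated as extra states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "Transfer",
    "AucTracker",
    "CompartmentNetwork",
    "BuildError",
    "blood_compartment",
    "aqueous_compartment",
    "tissue_compartment",
    "cellular_compartment",
    "sink_compartment",
]

PHASES = ("blood", "interstitial", "cellular", "lumen", "tissue", "sink")
DRIVINGS = ("total", "plasma", "unbound")


class BuildError(ValueError):
    """A network could not be assembled from the given configuration."""


@dataclass(frozen=True)
class Compartment:
    """A well-mixed space holding a drug amount (mg).

    ``emission`` maps each driving-concentration kind to the factor that
    multiplies the total concentration ``x/V``.  Sinks have no volume and
    never emit.
    """

    name: str
    volume: float | None
    phase: str
    emission: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise BuildError(f"unknown phase {self.phase!r} for {self.name}")
        if self.phase != "sink" and (self.volume is None or self.volume <= 0):
            raise BuildError(f"compartment {self.name!r} needs a positive volume")


@dataclass(frozen=True)
class Transfer:
    """A directed clearance edge ``flux = clearance * C_driving(source)``."""

    source: str
    target: str
    clearance: float
    driving: str = "unbound"
    mechanism: str = ""

    def __post_init__(self) -> None:
        if self.driving not in DRIVINGS:
            raise BuildError(f"unknown driving concentration {self.driving!r}")
        if self.clearance < 0:
            raise BuildError(
                f"negative clearance on {self.source}->{self.target}"
            )


@dataclass(frozen=True)
class AucTracker:
    """Co-integrated time integral of a driving concentration."""

    name: str
    compartment: str
    driving: str = "total"


def blood_compartment(name: str, volume: float, fu: float, bp: float) -> Compartment:
    """Blood-phase compartment: plasma = total/BP, unbound = fu*total/BP."""
    return Compartment(
        name, volume, "blood",
        {"total": 1.0, "plasma": 1.0 / bp, "unbound": fu / bp},
    )


def aqueous_compartment(name: str, volume: float, phase: str) -> Compartment:
    """Interstitial or tubular-lumen fluid; concentration is fully unbound."""
    return Compartment(name, volume, phase, {"total": 1.0, "plasma": 1.0, "unbound": 1.0})


def tissue_compartment(
    name: str, volume: float, kp: float, fu: float, bp: float
) -> Compartment:
    """Perfusion-limited organ with tissue:plasma partition coefficient kp.

    Out-flowing blood is in equilibrium with the tissue, so the emitted
    blood concentration is ``BP * C_t / kp``.
    """
    if kp <= 0:
        raise BuildError(f"tissue {name!r} needs kp > 0")
    return Compartment(
        name, volume, "tissue",
        {"total": bp / kp, "plasma": 1.0 / kp, "unbound": fu / kp},
    )


def cellular_compartment(name: str, volume: float, kp_cell: float) -> Compartment:
    """Intracellular space with cell:water partition kp_cell (<=1 for polar drugs)."""
    if kp_cell <= 0:
        raise BuildError(f"cellular {name!r} needs kp_cell > 0")
    f = 1.0 / kp_cell
    return Compartment(name, volume, "cellular", {"total": f, "plasma": f, "unbound": f})


def sink_compartment(name: str) -> Compartment:
    return Compartment(name, None, "sink", {})


class CompartmentNetwork:
    """An assembled linear ODE system over compartment amounts.

    Compartments, transfers and AUC trackers are registered with ``add_*`` /
    ``track``; :meth:`matrices` returns the constant system matrix including
    tracker rows.
    """

    def __init__(self) -> None:
        self._compartments: dict[str, Compartment] = {}
        self._transfers: list[Transfer] = []
        self._trackers: list[AucTracker] = []
        self.dose_targets: set[str] = set()

    # -- construction -------------------------------------------------
    def add_compartment(self, comp: Compartment) -> None:
        if comp.name in self._compartments:
            raise BuildError(f"duplicate compartment {comp.name!r}")
        self._compartments[comp.name] = comp

    def add_transfer(
        self,
        source: str,
        target: str,
        clearance: float,
        driving: str = "unbound",
        mechanism: str = "",
    ) -> None:
        for end in (source, target):
            if end not in self._compartments:
                raise BuildError(f"transfer endpoint {end!r} is not a compartment")
        if self._compartments[source].phase == "sink":
            raise BuildError(f"sink {source!r} cannot emit")
        self._transfers.append(Transfer(source, target, clearance, driving, mechanism))

    def track(self, compartment: str, driving: str = "total", name: str | None = None) -> str:
        """Register the time integral of a driving concentration as a state."""
        if compartment not in self._compartments:
            raise BuildError(f"cannot track unknown compartment {compartment!r}")
        if self._compartments[compartment].phase == "sink":
            raise BuildError("sinks hold amounts, not concentrations; nothing to track")
        name = name or f"auc:{compartment}:{driving}"
        if any(t.name == name for t in self._trackers):
            return name
        self._trackers.append(AucTracker(name, compartment, driving))
        return name

    def add_dose_target(self, compartment: str) -> None:
        if compartment not in self._compartments:
            raise BuildError(f"dose target {compartment!r} is not a compartment")
        self.dose_targets.add(compartment)

    # -- inspection ---------------------------------------------------
    @property
    def compartments(self) -> list[Compartment]:
        return list(self._compartments.values())

    @property
    def transfers(self) -> list[Transfer]:
        return list(self._transfers)

    @property
    def tracker_names(self) -> list[str]:
        return [t.name for t in self._trackers]

    @property
    def names(self) -> list[str]:
        return list(self._compartments)

    def __contains__(self, name: str) -> bool:
        return name in self._compartments

    def compartment(self, name: str) -> Compartment:
        return self._compartments[name]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def n_states(self) -> int:
        return len(self._compartments) + len(self._trackers)

    def emission_factor(self, name: str, driving: str) -> float:
        comp = self._compartments[name]
        try:
            return comp.emission[driving]
        except KeyError as exc:
            raise BuildError(
                f"compartment {name!r} ({comp.phase}) has no {driving!r} emission"
            ) from exc

    def rate_coefficient(self, name: str, driving: str) -> float:
        """Driving concentration per unit amount: emission / volume (1/L)."""
        comp = self._compartments[name]
        return self.emission_factor(name, driving) / comp.volume

    # -- assembly -----------------------------------------------------
    def matrices(self) -> np.ndarray:
        """Constant system matrix A with AUC-tracker rows appended.

        State ordering: compartments in registration order, then trackers.
        """
        names = self.names
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        m = len(self._trackers)
        a = np.zeros((n + m, n + m))
        for tr in self._transfers:
            i = idx[tr.source]
            j = idx[tr.target]
            k = tr.clearance * self.rate_coefficient(tr.source, tr.driving)
            a[i, i] -= k
            a[j, i] += k
        for row, t in enumerate(self._trackers):
            a[n + row, idx[t.compartment]] = self.rate_coefficient(
                t.compartment, t.driving
            )
        return a

    def dose_vector(self, target: str) -> np.ndarray:
        """Unit input vector (mg into ``target``) over the full state space."""
        if target not in self._compartments:
            raise BuildError(f"dose target {target!r} is not a compartment")
        v = np.zeros(self.n_states)
        v[self.index(target)] = 1.0
        return v

    # -- algebraic AUC ------------------------------------------------
    def auc_infinity(self, dose_amounts: dict[str, float]) -> dict[str, float]:
        """Exact time-integrals of all compartment amounts over [0, inf).

        Solves the time-integrated mass balance ``A_cc a = -d`` restricted
        to non-sink compartments, where ``d`` holds the total dosed amount
        per compartment.  Valid because the system is linear, time-invariant
        and fully eliminating (all mass ends in sinks).  Returns amount-time
        integrals (mg*h) keyed by compartment name.
        """
        names = self.names
        keep = [i for i, c in enumerate(self.compartments) if c.phase != "sink"]
        a_full = self.matrices()[: len(names), : len(names)]
        a_cc = a_full[np.ix_(keep, keep)]
        d = np.zeros(len(keep))
        for name, amount in dose_amounts.items():
            d[keep.index(self.index(name))] += amount
        try:
            integral = np.linalg.solve(a_cc, -d)
        except np.linalg.LinAlgError as exc:
            raise BuildError("singular integrated mass balance; system is not "
                             "fully eliminating") from exc
        return {names[i]: integral[k] for k, i in enumerate(keep)}

    def auc_infinity_concentration(
        self, dose_amounts: dict[str, float], compartment: str, driving: str = "total"
    ) -> float:
        """Exact concentration AUC over [0, inf) (mg*h/L)."""
        amounts = self.auc_infinity(dose_amounts)
        return amounts[compartment] * self.rate_coefficient(compartment, driving)

    # -- audit --------------------------------------------------------
    def edge_table(self):
        """Edge list (from, to, clearance_L_h, driving, mechanism) for audit."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "from": t.source,
                    "to": t.target,
                    "clearance_L_h": t.clearance,
                    "driving": t.driving,
                    "mechanism": t.mechanism,
                }
                for t in self._transfers
            ]
        )
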